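# ffpshg

Fast Fourier analysis of polarization-resolved second harmonic generation
(PSHG) microscopy image stacks.

Fibrillar collagen is a strong source of second harmonic generation, and the
way its SHG intensity varies with the linear polarization angle of the
excitation laser encodes molecular-scale structure. `ffpshg` turns a stack of
SHG images acquired at rotating input polarization (0°–180° in 20° steps)
into per-pixel maps of collagen structure and fit quality, plus local
dispersion (texture) maps of the structural parameters. It is aimed at
microscopists and image-analysis developers working with PSHG collections of
tissue sections (breast, skin, thyroid and similar), and at anyone who needs
a reproducible phantom generator to benchmark PSHG processing.

## The model

Each pixel's intensity-vs-polarization curve is described by the single-axis
molecule model for collagen, assuming cylindrical symmetry about the fibril
axis and a fibril lying in the image plane:

```
I(α) = I₀ · [ sin² 2(φ−α) + ( (χ₃₁/χ₁₅) sin²(φ−α) + (χ₃₃/χ₁₅) cos²(φ−α) )² ]
```

where α is the excitation polarization angle, φ the in-plane fibril
orientation, and χ₁₅, χ₃₁, χ₃₃ the nonzero elements of the second-order
susceptibility tensor. The signal is 180°-periodic and its harmonic content
stops at cos 4(φ−α), so the whole curve is captured by three Fourier
coefficients:

```
I(α) = I₀ · [ c₀ + c₁ cos 2(φ−α) + c₂ cos 4(φ−α) ]
```

The pipeline averages the replicate 0°/180° frames, takes the 9-point DFT of
each pixel's series, reads φ off the phase of the first harmonic and inverts
the three signed amplitudes in closed form (a quadratic in I₀) to recover
χ₃₁/χ₁₅, χ₃₃/χ₁₅ and χ₃₃/χ₃₁. The helical pitch angle of the collagen
triple helix follows from θₑ = arccos √(r/(2+r)) with r = χ₃₃/χ₁₅ (so
r = 2 ↦ 45°). Three quality estimators accompany the five structural maps:
R² of the fit over the 10 measured samples, the spectral error ratio ERR
(non-model over model harmonic amplitudes; ≈0 for clean signal, ≈1 for
noise), and a DFT-domain SNR in dB.

Per stack the pipeline writes 8 maps (`CHI3115, CHI3315, CHI3331, FI, THETA,
R2, SNR, ERR`) and 90 local-dispersion maps: entropy, standard deviation and
median absolute deviation of the five structural maps over square and
"circular" windows of side/diameter 3, 7 and 15 pixels.

## Worked example

Simulate a noisy 8-bit phantom with known parameters and recover them:

```python
import numpy as np
from ffpshg import (CollagenParams, PhantomRegion, PhantomSpec,
                    generate_stack, fit_stack, theta_from_ratio)

region = np.zeros((32, 32), dtype=bool)
region[4:28, 4:28] = True
spec = PhantomSpec(
    height=32, width=32,
    regions=[PhantomRegion(region, CollagenParams(i0=30.0, b=1.0, c=1.8, phi=40.0))],
    background_level=2.0, noise_model="gaussian", noise_sigma=2.0,
    bit_depth=8, seed=42,
)
stack = generate_stack(spec)          # (10, 32, 32), angles 0..180 deg
maps = fit_stack(stack)               # the eight parameter/quality maps

inside = region
print(f"chi31/chi15  median = {np.nanmedian(maps['CHI3115'][inside]):.3f}")
print(f"chi33/chi15  median = {np.nanmedian(maps['CHI3315'][inside]):.3f}")
print(f"phi          median = {np.nanmedian(maps['FI'][inside]):.1f} deg")
print(f"theta_e      median = {np.nanmedian(maps['THETA'][inside]):.1f} deg")
print(f"R2           median = {np.nanmedian(maps['R2'][inside]):.3f}")
print(f"good-fit fraction (R2 >= 0.8) = {np.nanmean(maps['R2'][inside] >= 0.8):.2f}")
```

prints

```
chi31/chi15  median = 1.003
chi33/chi15  median = 1.801
phi          median = 40.1 deg
theta_e      median = 46.5 deg
R2           median = 0.996
good-fit fraction (R2 >= 0.8) = 1.00
```

Despite 8-bit quantization and Gaussian detector noise, the tensor-element
ratios (true values 1.0 and 1.8), the fibril orientation (40°) and the pitch
angle (θₑ(1.8) = 46.5°) come back to within a few percent, and nearly every
collagen pixel clears the customary R² ≥ 0.8 good-fit threshold.

The same pipeline is available from a shell:

```sh
ffpshg simulate --output coll --rois 2 --size 64 --noise gaussian --seed 1
ffpshg fit --input coll --r2-threshold 0.8
ffpshg dispersion --input coll --windows 3,7,15
ffpshg validate --input coll --report coll-manifest
```

`validate` checks a collection tree (ROI folders, FSHG/BSHG stacks of 10
frames, `Results` folders with 8 + 90 maps, TPEF context images) against the
expected layout and counts, and exits nonzero on any discrepancy.

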