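# Methods

## The forward model and its harmonic form

A pixel's SHG response to linearly polarized excitation at angle α is modeled
by the single-axis molecule model for collagen with cylindrical symmetry
about the fibril axis and the fibril lying in the image plane:

I(α) = I₀ [ sin² 2Δ + (b sin² Δ + c cos² Δ)² ],  Δ = φ − α,

with b = χ₃₁/χ₁₅, c = χ₃₃/χ₁₅. Expanding in harmonics of 2Δ with u = c − b,
v = c + b gives exactly

I(α) = I₀ [ c₀ + c₁ cos 2Δ + c₂ cos 4Δ ],
c₀ = ½ + v²/4 + u²/8,  c₁ = uv/2,  c₂ = u²/8 − ½.

The signal is 180°-periodic and band-limited to the second harmonic of 2Δ;
everything above it in a measured series is noise by construction. Angles are
measured in degrees counterclockwise from the image +x axis; φ is defined
modulo 180°.

The pitch angle of the collagen triple helix is derived from the c ratio as
θₑ = arccos √(c/(2+c)), equivalently tan² θₑ = 2/c. The printed form of this
relation in the source literature is dimensionless; the arccos reading is the
only one consistent with the reported degree values (c = 1.79 ↦ 46.6°,
c = 2 ↦ 45° exactly), so it is adopted here.

## Acquisition geometry and endpoint averaging

Stacks hold 10 frames at α = 0°, 20°, …, 180°. Since the response is
180°-periodic, the endpoint frames are replicate measurements; their mean
replaces the first frame, and processing uses the resulting 9 frames at
0°–160°. Averaging is done in floating point on the stored (possibly 8-bit)
values.

## Spectral fitting

For each pixel the 9-sample series is transformed with the forward DFT
G_k = Σₙ xₙ e^(−2πikn/9). With αₙ = 20°·n, the cos 2Δ term lands in bin 1
with phase −2φ and the cos 4Δ term in bin 2 with phase −4φ, so

- φ = −arg(G₁)/2 mod 180°;
- signed amplitudes M₀ = Re(G₀)/9, M₁ = (2/9) Re(G₁e^(2iφ)),
  M₂ = (2/9) Re(G₂e^(4iφ)).

Substituting the coefficient expressions yields a quadratic in I₀:

I₀² + I₀(3M₂ − M₀) + (M₁²/4 − 2M₀M₂ + 2M₂²) = 0,

after which u² = 8(M₂ + I₀/2)/I₀ and v² = 4(M₀ − M₂ − I₀)/I₀ recover
b = (v−u)/2, c = (v+u)/2, with sign(u) = sign(M₁) and v ≥ 0. Among real
roots with I₀ > 0, u² ≥ 0, v² ≥ 0 and b ≥ 0, the root with b closest to 1 is
preferred: Kleinman symmetry makes χ₃₁/χ₁₅ ≈ 1 in practice, and this prior
resolves the rare case where both roots are admissible. Negative u² or v²
within 10⁻⁹ (relative) of zero is clamped to zero as rounding.

**Identifiability.** The model is exactly degenerate under
(b, c, φ) ↔ (c, b, φ+90°): both parameterizations produce identical pixel
data. The inversion always reports the branch with c ≥ b (equivalently
M₁ ≥ 0), which matches the values typical of fibrillar collagen
(χ₃₃/χ₁₅ ≈ 2 > χ₃₁/χ₁₅ ≈ 1). Recovery tests compare against ground truth
folded onto the same branch. When b = c the first harmonic vanishes and the
signal is 90°-periodic; φ is then taken from the phase of G₂ (with M₂ < 0,
which holds identically on this branch) and is defined modulo 90°.

Degenerate (flat or non-finite) pixels yield all-NaN parameters. NaN — not
0 — marks undefined pixels throughout, since 0 is a legal parameter value.

## Quality estimators

- **R²** = 1 − SSR/SST over the original 10 samples, with predictions from
  the recovered parameters evaluated at all 10 acquisition angles; NaN when
  the series is constant (SST = 0).
- **ERR** = mean(ĉ₃, ĉ₄) / mean(ĉ₀, ĉ₁, ĉ₂) on the folded amplitudes
  ĉ₀ = |G₀|/9, ĉₖ = 2|Gₖ|/9. With 9 samples only folded harmonics 0–4
  exist; harmonics 3–4 equal the two-sided bins 3–6, so this is the mean of
  all non-model spectral content over the mean of the model content. Clean
  model data gives ERR ≈ 0; noise-only pixels give ERR near unity.
- **SNR(dB)** = 10 log₁₀ [(|G₁|² + |G₂|²) / (|G₃|² + |G₄|² + |G₅|² + |G₆|²)];
  bins 5 and 6 are conjugates of 4 and 3, bins 7–8 of 2–1 and therefore
  excluded from the signal sum. Values are capped at +99 dB: a noiseless
  pixel's noise bins carry only float rounding power (~10⁻²⁸ of the signal),
  and the cap reports such pixels at a single sentinel value instead of a
  rounding-determined number. NaN when signal and noise bins are all zero.

DFT bins are indexed 0-based by frequency; this is the only indexing for
which clean model data concentrates in "signal" bins {1, 2} and yields
high SNR with ERR ≈ 0.

## Local dispersion maps

Entropy (ENT), population standard deviation (SD, divisor n) and median
absolute deviation (MAD, median |x − median x|) are computed in sliding
windows centered on each pixel: square windows of side 3/7/15 and "circular"
windows keeping offsets with dx² + dy² ≤ r², r = (size−1)/2, which contain
5/29/149 pixels. Applied to the five structural maps this yields
5 × 3 × 6 = 90 maps per stack, named `[parameter]_[estimator]_[shape]_[size]`.

Entropy needs discrete symbols, so values are quantized to 256 bins
(configurable) over fixed per-parameter ranges — FI: [0, 180); THETA:
[0, 90]; tensor ratios: [0, 5], clipped. Fixed ranges keep entropy
comparable across an image; window-local ranges would make it scale-free.
Windows are clipped at image borders (no padding is invented). A center
pixel is NaN when fewer than `min_valid_fraction` (default 0.5) of its
*in-bounds* window pixels are finite; clipping alone therefore never
produces NaN, only NaN inputs do.

Orientation (FI) is dispersed as plain degrees by default, matching the
linear SD/MAD usage established for such maps; values straddling the 0/180°
seam then read as far apart, inflating SD/MAD for fibers near 0°. An opt-in
axial mode (`circular_phi`) computes deviations from the circular mean of
the doubled angle, removing the seam bias. The exact pixel membership of the
"circular" windows and the entropy bin count are isolated behind
`make_window_mask` and `entropy_bins` so they can be matched to other
implementations.

## Synthetic phantoms

The phantom generator emulates the acquisition: disjoint regions of uniform
(I₀, b, c, φ) following the forward model exactly, a polarization-
independent background (constant mean plus noise) emulating SHG-inactive
tissue, Gaussian or Poisson noise (the detector statistics of real systems
vary, so both are exposed; Gaussian σ = 2 counts on a background mean of 2
is the default working point), independent noise draws in the 0° and 180°
frames, and optional 8-bit quantization that linearly maps the stack maximum
to 255 before rounding, mimicking detector export. Defaults: I₀ = 40,
b = 1.0, c = 2.0 (the Kleinman-symmetric, collagen-typical working point),
512-to-64-pixel frames depending on context.

What phantoms do not emulate: spatially continuous fiber bundles, optical
blur and pixel cross-talk, out-of-plane fibril tilt, birefringence or
diattenuation of the sample, stage drift between frames, and trigonal-
symmetry deviations from the cylindrical model. Passing recovery tests on
phantoms therefore demonstrates the correctness of the spectral inversion
and estimators, not the adequacy of the single-axis model for any given
tissue.

## Collection layout and validation

Collections follow the published tree: per-ROI folders named
`[tissue][_HE]_[roi]` with FSHG/BSHG subfolders of 10 8-bit TIFF frames
(`[tissue]_[HE]_[roi]_[detection]_[angle].tif`), one TPEF context image per
ROI, and a `Results` subfolder per detection with the 8 analysis maps and
90 dispersion maps as 32-bit float TIFFs. Unstained names omit the HE token
entirely; thyroid sections are H&E-stained but their published IDs carry no
HE token, so the class lookup keys on the name format. TPEF images are
inventory items only — no pixel processing. The validator derives expected
per-ROI file lists from the layout, reports missing/extra files, and ignores
`GroundTruth` sidecar folders written by the phantom generator.

Counts per ROI: 2 stacks × 10 SHG frames, 1 TPEF, 2 × 8 analysis maps,
2 × 90 dispersion maps. For the published group totals (48, 47, 53, 53, 40)
this gives 241 ROIs, 482 stacks, 4,820 SHG images, 3,856 analysis maps,
43,380 dispersion maps — 52,297 images in all.

## Problem sizes and numerical choices

Recovery and cross-check tests run on 64×64 noiseless phantoms (45-condition
parameter sweep) and 100 random clean pixels against a multi-start nonlinear
least-squares oracle (12 orientation starts, tolerances 10⁻¹⁵); agreement is
asserted at 10⁻⁶. Noise behaviour uses 1,000 noise-only pixels and 8×16
two-region phantoms at peak signal 100 with σ ∈ {0, 2, 8, 32}. These sizes
make the full suite and the acceptance script each complete in well under a
minute on one core while exercising every code path; the per-pixel math is
vectorized, so larger frames scale linearly.

## Known limitations

- The c ≥ b branch convention silently swaps genuinely b > c pixels (with
  φ shifted 90°); such tissue would need prior knowledge to disambiguate.
- Linear FI dispersion is biased at the 0/180° seam unless `circular_phi`
  is enabled.
- The single-axis cylindrical model is the only one implemented; trigonal
  symmetry and generic-model fits are out of scope.
- Entropy values depend on the chosen bin count and fixed ranges; compare
  maps only across images processed with identical settings.
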