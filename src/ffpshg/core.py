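"""Per-pixel Fourier analysis of polarization-resolved SHG stacks.

The pipeline per pixel:

1. average the 0- and 180-degree frames (the signal is 180-degree periodic,
   so they are replicate measurements), leaving 9 samples at 0..160 degrees;
2. take the 9-point DFT of the intensity-vs-polarization series; the
   single-axis collagen model has content only in the DC bin and harmonics
   1 and 2 (cos 2(phi-alpha) and cos 4(phi-alpha));
3. invert the three signed harmonic amplitudes in closed form to the model
   parameters (I0, chi31/chi15, chi33/chi15, phi), deriving chi33/chi31 and
   the helical pitch angle theta_e;
4. score the fit with R^2 (on the original 10 samples), the spectral error
   ratio ERR, and a DFT-domain SNR in dB.

All functions are vectorized: a "series" argument may have any leading shape
with the sample axis last, and `fit_stack` processes a whole (10, H, W) stack
at once.

Sign conventions.  The forward DFT ``G_k = sum_n x_n exp(-2*pi*i*k*n/9)`` with
``alpha_n = 20 deg * n`` puts the cos(2(phi-alpha)) harmonic at bin 1 with
phase -2*phi, hence ``phi = -arg(G1)/2 mod 180``.  The model cannot
distinguish (b, c, phi) from (c, b, phi+90); the inversion adopts the branch
with the cos(2 delta) amplitude positive, i.e. chi33/chi15 >= chi31/chi15,
which matches the values typical of fibrillar collagen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    DEFAULT_GRID,
    PROCESSING_GRID,
    PolarizationGrid,
)

__all__ = [
    "HarmonicSpectrum",
    "CollagenFit",
    "QualityMetrics",
    "ParameterMapSet",
    "MAP_KEYS",
    "STRUCTURAL_KEYS",
    "SNR_CAP_DB",
    "average_endpoint_frames",
    "pixel_dft",
    "invert_spectrum",
    "compute_r2",
    "compute_err",
    "compute_snr",
    "fit_stack",
]

#: The eight planar maps produced per stack, in canonical order.
MAP_KEYS = ("CHI3115", "CHI3315", "CHI3331", "FI", "THETA", "R2", "SNR", "ERR")
#: The five maps carrying collagen structural information.
STRUCTURAL_KEYS = ("CHI3115", "CHI3315", "CHI3331", "FI", "THETA")
#: SNR ceiling reported when the noise bins are (numerically) empty.
SNR_CAP_DB = 99.0

_N = 9  # samples per processing series


@dataclass(frozen=True)
class HarmonicSpectrum:
    """DFT content of 9-sample polarization series (vectorized over pixels).

    Attributes
    ----------
    g : complex ndarray, shape (..., 9)
        Raw DFT bins G0..G8 (forward convention, 0-based frequency).
    chat : ndarray, shape (..., 5)
        Folded real amplitudes: chat[0] = |G0|/9, chat[k] = 2|Gk|/9, k=1..4.
    phase1, phase2 : ndarray, shape (...)
        Arguments of G1 and G2 (radians).
    """

    g: np.ndarray
    chat: np.ndarray
    phase1: np.ndarray
    phase2: np.ndarray


@dataclass(frozen=True)
class CollagenFit:
    """Recovered model parameters (arrays broadcast over pixels, NaN = undefined)."""

    i0: np.ndarray
    chi3115: np.ndarray
    chi3315: np.ndarray
    chi3331: np.ndarray
    phi: np.ndarray
    theta_e: np.ndarray


@dataclass(frozen=True)
class QualityMetrics:
    """Fit-quality estimators per pixel."""

    r2: np.ndarray
    err: np.ndarray
    snr_db: np.ndarray


@dataclass(frozen=True)
class ParameterMapSet:
    """The eight planar 32-bit float maps written per stack."""

    maps: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = set(MAP_KEYS) - set(self.maps)
        if missing:
            raise ValueError(f"missing maps: {sorted(missing)}")
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent map shapes: {shapes}")

    def __getitem__(self, key: str) -> np.ndarray:
        return self.maps[key]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.maps.values())).shape


def average_endpoint_frames(stack10: np.ndarray) -> np.ndarray:
    """Average the 0- and 180-degree frames of a 10-frame stack.

    The two endpoint frames sample the same polarization state (the signal is
    180-degree periodic) and differ only by noise and drift; their mean
    replaces the first frame, yielding the 9-frame processing stack at
    0..160 degrees.  Works on any array whose first axis has length 10.
    """
    stack10 = np.asarray(stack10, dtype=float)
    if stack10.shape[0] != 10:
        raise ValueError(f"expected 10 frames, got {stack10.shape[0]}")
    out = stack10[:9].copy()
    out[0] = 0.5 * (stack10[0] + stack10[9])
    return out


def pixel_dft(series9: np.ndarray) -> HarmonicSpectrum:
    """9-point DFT of polarization series (sample axis last).

    Uses the forward convention ``G_k = sum_n x_n exp(-2*pi*i*k*n/9)``.
    Non-finite samples poison the pixel: its bins become NaN and it is
    reported as undefined downstream.
    """
    x = np.asarray(series9, dtype=float)
    if x.shape[-1] != _N:
        raise ValueError(f"expected {_N} samples, got {x.shape[-1]}")
    bad = ~np.all(np.isfinite(x), axis=-1)
    if np.any(bad):
        x = np.where(bad[..., None], np.nan, x)
    g = np.fft.fft(x, axis=-1)
    absg = np.abs(g)
    chat = np.concatenate(
        [absg[..., :1] / _N, 2.0 * absg[..., 1:5] / _N], axis=-1
    )
    return HarmonicSpectrum(
        g=g,
        chat=chat,
        phase1=np.angle(g[..., 1]),
        phase2=np.angle(g[..., 2]),
    )


def _solve_quadratic_roots(m0, m1, m2):
    """Real roots of I0^2 + I0(3 m2 - m0) + (m1^2/4 - 2 m0 m2 + 2 m2^2) = 0."""
    bq = 3.0 * m2 - m0
    cq = m1 * m1 / 4.0 - 2.0 * m0 * m2 + 2.0 * m2 * m2
    disc = bq * bq - 4.0 * cq
    with np.errstate(invalid="ignore"):
        sq = np.sqrt(np.where(disc >= 0, disc, np.nan))
    return (-bq - sq) / 2.0, (-bq + sq) / 2.0


def invert_spectrum(spec: HarmonicSpectrum, rel_tol: float = 1e-9) -> CollagenFit:
    """Closed-form inversion of the harmonic spectrum to collagen parameters.

    The in-plane orientation comes from the phase of the first harmonic
    (``phi = -arg(G1)/2 mod 180``); when that harmonic vanishes (b = c, a
    90-degree-periodic signal) the second harmonic's phase is used instead,
    leaving phi defined modulo 90.  Signed amplitudes M0, M1, M2 then satisfy

        M0 = I0 (1/2 + v^2/4 + u^2/8),  M1 = I0 u v / 2,  M2 = I0 (u^2/8 - 1/2)

    with u = c - b, v = c + b, giving a quadratic in I0.  Among real roots
    with I0 > 0, u^2 >= 0, v^2 >= 0 and b >= 0, the root with b closest to 1
    is preferred (Kleinman symmetry makes chi31/chi15 ~ 1 in practice).
    Pixels with no admissible root, or a degenerate (flat) spectrum, come
    back all-NaN.
    """
    g = spec.g
    chat = spec.chat
    shape = chat.shape[:-1]

    m0 = np.real(g[..., 0]) / _N
    scale = np.maximum(np.abs(m0), np.max(chat, axis=-1))
    tol = rel_tol * np.maximum(scale, 1e-300)
    c1hat, c2hat = chat[..., 1], chat[..., 2]

    has_h1 = c1hat > tol
    has_h2 = c2hat > tol
    degenerate = ~(has_h1 | has_h2) | ~np.isfinite(m0)

    # phi from phase of G1; fall back to G2 (with M2 < 0 assumed) when b = c.
    phi_h1 = np.mod(-np.degrees(spec.phase1) / 2.0, 180.0)
    phi_h2 = np.mod((180.0 - np.degrees(spec.phase2)) / 4.0, 180.0)
    phi = np.where(has_h1, phi_h1, phi_h2)

    # signed amplitudes consistent with phi: M1 >= 0 by the branch convention,
    # M2's sign read off the second harmonic's phase.
    phi_rad = np.radians(phi)
    m1 = np.where(has_h1, (2.0 / _N) * np.real(g[..., 1] * np.exp(2j * phi_rad)), 0.0)
    m2 = (2.0 / _N) * np.real(g[..., 2] * np.exp(4j * phi_rad))

    r_lo, r_hi = _solve_quadratic_roots(m0, m1, m2)

    best = {
        "i0": np.full(shape, np.nan),
        "b": np.full(shape, np.nan),
        "c": np.full(shape, np.nan),
        "score": np.full(shape, np.inf),
    }
    for i0_root in (r_lo, r_hi):
        with np.errstate(invalid="ignore", divide="ignore"):
            u2 = 8.0 * (m2 + i0_root / 2.0) / i0_root
            v2 = 4.0 * (m0 - m2 - i0_root) / i0_root
            # tiny negatives are rounding, not physics
            u2 = np.where((u2 < 0) & (u2 > -rel_tol), 0.0, u2)
            v2 = np.where((v2 < 0) & (v2 > -rel_tol), 0.0, v2)
            u = np.sign(m1) * np.sqrt(np.abs(u2))
            u = np.where(m1 == 0, np.sqrt(np.abs(u2)), u)  # b=c branch: c >= b
            v = np.sqrt(np.abs(v2))
            b = (v - u) / 2.0
            c = (v + u) / 2.0
        ok = (
            np.isfinite(i0_root)
            & (i0_root > 0)
            & (u2 >= 0)
            & (v2 >= 0)
            & (b >= -rel_tol)
            & ~degenerate
        )
        b = np.where((b < 0) & ok, 0.0, b)
        score = np.abs(b - 1.0)
        take = ok & (score < best["score"])
        best["i0"] = np.where(take, i0_root, best["i0"])
        best["b"] = np.where(take, b, best["b"])
        best["c"] = np.where(take, c, best["c"])
        best["score"] = np.where(take, score, best["score"])

    i0, b, c = best["i0"], best["b"], best["c"]
    solved = np.isfinite(i0)
    phi = np.where(solved, phi, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi3331 = np.where(solved & (b != 0), c / b, np.nan)
        ratio = np.where(solved & (c > 0), c, np.nan)
        theta = np.degrees(np.arccos(np.sqrt(ratio / (2.0 + ratio))))
    return CollagenFit(
        i0=i0, chi3115=b, chi3315=c, chi3331=chi3331, phi=phi, theta_e=theta
    )


def _predict_series(fit: CollagenFit, angles_deg: np.ndarray) -> np.ndarray:
    """Model intensities at ``angles_deg`` for vectorized fits, shape (..., n)."""
    d = np.radians(fit.phi[..., None] - angles_deg)
    s2, c2 = np.sin(d) ** 2, np.cos(d) ** 2
    amp = fit.chi3115[..., None] * s2 + fit.chi3315[..., None] * c2
    return fit.i0[..., None] * (np.sin(2 * d) ** 2 + amp**2)


def compute_r2(
    series10: np.ndarray,
    fit: CollagenFit,
    grid: PolarizationGrid = DEFAULT_GRID,
) -> np.ndarray:
    """Coefficient of determination of the fit on the original 10 samples.

    R^2 = 1 - SSR/SST with SSR the sum of squared residuals against the model
    prediction at all 10 acquisition angles and SST the total sum of squares
    about the series mean.  NaN where the fit is undefined or SST = 0.
    """
    x = np.asarray(series10, dtype=float)
    if x.shape[-1] != len(grid):
        raise ValueError(f"expected {len(grid)} samples, got {x.shape[-1]}")
    y = _predict_series(fit, grid.as_array())
    ssr = np.sum((x - y) ** 2, axis=-1)
    sst = np.sum((x - np.mean(x, axis=-1, keepdims=True)) ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, 1.0 - ssr / sst, np.nan)
    return r2


def compute_err(spec: HarmonicSpectrum) -> np.ndarray:
    """Spectral error ratio: mean non-model amplitude over mean model amplitude.

    The model occupies folded harmonics 0-2 only; harmonics 3-4 (equivalently
    the two-sided bins 3..6) are pure noise.  ERR is ~0 for clean model
    signal and ~1 for noise-only pixels.  NaN when the model amplitudes
    average to zero.
    """
    chat = spec.chat
    noise = 0.5 * (chat[..., 3] + chat[..., 4])
    sig = (chat[..., 0] + chat[..., 1] + chat[..., 2]) / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sig > 0, noise / sig, np.nan)


def compute_snr(spec: HarmonicSpectrum) -> np.ndarray:
    """DFT-domain signal-to-noise ratio in dB, capped at +99.

    Signal power sits in bins 1 and 2 (the model harmonics); noise power in
    bins 3..6 (bins 5 and 6 being the conjugates of 4 and 3).  NaN when both
    sums vanish.
    """
    p = np.abs(spec.g) ** 2
    sig = p[..., 1] + p[..., 2]
    noise = p[..., 3] + p[..., 4] + p[..., 5] + p[..., 6]
    with np.errstate(invalid="ignore", divide="ignore"):
        snr = 10.0 * np.log10(sig / noise)
    snr = np.where((noise == 0) & (sig > 0), np.inf, snr)
    snr = np.where((noise == 0) & (sig == 0), np.nan, snr)
    return np.minimum(snr, SNR_CAP_DB)


def fit_stack(stack10: np.ndarray, grid: PolarizationGrid = DEFAULT_GRID) -> ParameterMapSet:
    """Run the full per-pixel analysis on a (10, H, W) stack.

    Returns the eight parameter/quality maps (CHI3115, CHI3315, CHI3331, FI,
    THETA, R2, SNR, ERR) as float planes the shape of one frame, NaN where
    undefined (they are cast to 32-bit only when written to disk).
    Deterministic.
    """
    stack10 = np.asarray(stack10, dtype=float)
    if stack10.ndim != 3 or stack10.shape[0] != 10:
        raise ValueError(f"expected a (10, H, W) stack, got shape {stack10.shape}")
    stack9 = average_endpoint_frames(stack10)
    series9 = np.moveaxis(stack9, 0, -1)  # (H, W, 9)
    series10 = np.moveaxis(stack10, 0, -1)
    spec = pixel_dft(series9)
    fit = invert_spectrum(spec)
    r2 = compute_r2(series10, fit, grid)
    maps = {
        "CHI3115": fit.chi3115,
        "CHI3315": fit.chi3315,
        "CHI3331": fit.chi3331,
        "FI": fit.phi,
        "THETA": fit.theta_e,
        "R2": r2,
        "SNR": compute_snr(spec),
        "ERR": compute_err(spec),
    }
    return ParameterMapSet({k: np.asarray(v, dtype=float) for k, v in maps.items()})
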