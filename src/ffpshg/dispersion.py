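"""Local dispersion maps of the collagen structural parameter images.

Three estimators — Shannon entropy (ENT), population standard deviation (SD)
and median absolute deviation (MAD) — are evaluated in sliding windows
centered on each pixel, with two window shapes (square and "circular") and
three sizes (side/diameter 3, 7, 15).  Each of the five structural parameter
maps (CHI3115, CHI3315, CHI3331, FI, THETA) times 3 estimators times 6
windows yields the 90 dispersion maps per stack.

Windows are clipped at image borders (no padding) and NaN pixels are
excluded; a center pixel whose window retains fewer than ``min_valid_fraction``
of the full mask is reported as NaN.

Entropy treats the continuous parameter values as discrete symbols by
quantizing them into a fixed number of bins over a fixed per-parameter range
(FI: [0, 180); THETA: [0, 90]; ratios: [0, 5], clipped).  Using fixed rather
than window-local ranges keeps entropy values comparable across an image.

Orientation (FI) values are dispersed as plain degrees by default; the
0/180 wraparound seam then inflates SD/MAD for fibers oriented near 0
degrees.  An opt-in circular-statistics mode treats FI as an axial quantity
(period 180 degrees) for SD and MAD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import STRUCTURAL_KEYS, ParameterMapSet

__all__ = [
    "WindowSpec",
    "DispersionJob",
    "ESTIMATORS",
    "WINDOW_SIZES",
    "PARAMETER_RANGES",
    "make_window_mask",
    "local_entropy",
    "local_sd",
    "local_mad",
    "local_dispersion",
    "generate_all_dispersion",
    "dispersion_map_name",
]

ESTIMATORS = ("ENT", "SD", "MAD")
WINDOW_SIZES = (3, 7, 15)
WINDOW_SHAPES = ("square", "circular")

#: Fixed quantization ranges for entropy, per structural parameter.
PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "CHI3115": (0.0, 5.0),
    "CHI3315": (0.0, 5.0),
    "CHI3331": (0.0, 5.0),
    "FI": (0.0, 180.0),
    "THETA": (0.0, 90.0),
}


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: shape in {square, circular}, odd size."""

    shape: str
    size: int

    def __post_init__(self) -> None:
        if self.shape not in WINDOW_SHAPES:
            raise ValueError(f"unknown window shape {self.shape!r}")
        if self.size not in WINDOW_SIZES:
            raise ValueError(f"unsupported window size {self.size}; use 3, 7 or 15")


@dataclass(frozen=True)
class DispersionJob:
    """One dispersion computation: parameter, estimator, window, options."""

    parameter: str
    estimator: str
    window: WindowSpec
    entropy_bins: int = 256
    min_valid_fraction: float = 0.5
    circular_phi: bool = False

    def __post_init__(self) -> None:
        if self.parameter not in STRUCTURAL_KEYS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if not 0 < self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must be in (0, 1]")


def make_window_mask(w: WindowSpec) -> np.ndarray:
    """Boolean offset mask of shape (size, size), centered.

    Square masks are the full block; circular masks keep offsets with
    dx^2 + dy^2 <= ((size-1)/2)^2, giving 5/29/149 pixels for sizes 3/7/15.
    """
    r = (w.size - 1) // 2
    if w.shape == "square":
        return np.ones((w.size, w.size), dtype=bool)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return dx * dx + dy * dy <= r * r


def _window_offsets(w: WindowSpec) -> np.ndarray:
    mask = make_window_mask(w)
    r = (w.size - 1) // 2
    ys, xs = np.nonzero(mask)
    return np.stack([ys - r, xs - r], axis=1)  # (K, 2) of (dy, dx)


def _stacked_windows(image: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Gather window values per pixel: (K, H, W) with NaN outside the image."""
    h, w = image.shape
    r = int(np.max(np.abs(offsets)))
    padded = np.full((h + 2 * r, w + 2 * r), np.nan)
    padded[r : r + h, r : r + w] = image
    out = np.empty((len(offsets), h, w))
    for k, (dy, dx) in enumerate(offsets):
        out[k] = padded[r + dy : r + dy + h, r + dx : r + dx + w]
    return out


def _valid_mask(stacked: np.ndarray, image_shape, offsets, min_frac: float):
    """Valid-fraction rule on the border-clipped window.

    The denominator is the number of window offsets that fall inside the
    image (windows are clipped, not padded); NaN input pixels inside the
    window then reduce the numerator.
    """
    n_valid = np.sum(np.isfinite(stacked), axis=0)
    inb = _stacked_windows(np.zeros(image_shape), offsets)
    n_inbounds = np.sum(np.isfinite(inb), axis=0)
    ok = (n_inbounds > 0) & (n_valid >= min_frac * n_inbounds)
    return ok, n_valid


def local_entropy(image: np.ndarray, job: DispersionJob) -> np.ndarray:
    """Local Shannon entropy map in bits.

    Window values are quantized to ``job.entropy_bins`` levels over the
    parameter's fixed range; the entropy of the within-window occurrence-rate
    histogram, ``-sum p_i log2 p_i``, is assigned to the center pixel.
    Constant windows give 0; under-filled windows give NaN.
    """
    if job.estimator != "ENT":
        raise ValueError("job.estimator must be ENT")
    image = np.asarray(image, dtype=float)
    lo, hi = PARAMETER_RANGES[job.parameter]
    nbins = job.entropy_bins
    finite = np.isfinite(image)
    scaled = np.clip((image - lo) / (hi - lo), 0.0, 1.0 - 1e-12)
    codes = np.where(finite, np.floor(scaled * nbins), -1).astype(np.int64)

    offsets = _window_offsets(job.window)
    stacked_f = _stacked_windows(np.where(finite, codes, np.nan).astype(float), offsets)
    ok, n_valid = _valid_mask(stacked_f, image.shape, offsets, job.min_valid_fraction)

    h, w = image.shape
    counts = np.zeros((nbins, h, w), dtype=np.int32)
    rows = np.arange(h)[:, None] * np.ones(w, dtype=int)
    cols = np.ones(h, dtype=int)[:, None] * np.arange(w)
    for k in range(len(offsets)):
        plane = stacked_f[k]
        m = np.isfinite(plane)
        np.add.at(counts, (plane[m].astype(np.int64), rows[m], cols[m]), 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / np.maximum(n_valid, 1)
        plogp = np.where(counts > 0, p * np.log2(p), 0.0)
        ent = -np.sum(plogp, axis=0)
    return np.where(ok & (n_valid > 0), ent, np.nan)


def _axial_residuals(stacked: np.ndarray, period: float = 180.0) -> np.ndarray:
    """Deviations from the axial circular mean, mapped to (-period/2, period/2]."""
    ang = stacked * (2.0 * np.pi / period)
    with np.errstate(invalid="ignore"):
        mean_ang = np.arctan2(np.nansum(np.sin(ang), axis=0), np.nansum(np.cos(ang), axis=0))
    dev = np.mod(stacked - mean_ang * (period / (2.0 * np.pi)) + period / 2.0, period) - period / 2.0
    return dev


def _local_moment(image: np.ndarray, job: DispersionJob, kind: str) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    offsets = _window_offsets(job.window)
    stacked = _stacked_windows(image, offsets)
    ok, n_valid = _valid_mask(stacked, image.shape, offsets, job.min_valid_fraction)
    use_axial = job.circular_phi and job.parameter == "FI"
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if kind == "SD":
            if use_axial:
                dev = _axial_residuals(stacked)
                out = np.sqrt(np.nanmean(dev * dev, axis=0))
            else:
                mean = np.nanmean(stacked, axis=0)
                out = np.sqrt(np.nanmean((stacked - mean) ** 2, axis=0))
        else:  # MAD
            if use_axial:
                dev = np.abs(_axial_residuals(stacked))
                out = np.nanmedian(dev, axis=0)
            else:
                med = np.nanmedian(stacked, axis=0)
                out = np.nanmedian(np.abs(stacked - med), axis=0)
    return np.where(ok & (n_valid > 0), out, np.nan)


def local_sd(image: np.ndarray, job: DispersionJob) -> np.ndarray:
    """Local population standard deviation map (divisor n, not n-1)."""
    if job.estimator != "SD":
        raise ValueError("job.estimator must be SD")
    return _local_moment(image, job, "SD")


def local_mad(image: np.ndarray, job: DispersionJob) -> np.ndarray:
    """Local median-absolute-deviation map: median(|x - median(x)|) per window."""
    if job.estimator != "MAD":
        raise ValueError("job.estimator must be MAD")
    return _local_moment(image, job, "MAD")


def local_dispersion(image: np.ndarray, job: DispersionJob) -> np.ndarray:
    """Dispatch to the estimator named by ``job.estimator``."""
    if job.estimator == "ENT":
        return local_entropy(image, job)
    if job.estimator == "SD":
        return local_sd(image, job)
    return local_mad(image, job)


def dispersion_map_name(parameter: str, estimator: str, window: WindowSpec) -> str:
    """Canonical map name: ``[parameter]_[estimator]_[shape]_[size]``."""
    return f"{parameter}_{estimator}_{window.shape}_{window.size}"


def generate_all_dispersion(
    maps: ParameterMapSet,
    entropy_bins: int = 256,
    min_valid_fraction: float = 0.5,
    circular_phi: bool = False,
    sizes: tuple[int, ...] = WINDOW_SIZES,
) -> dict[str, np.ndarray]:
    """All 90 dispersion maps of a parameter map set.

    5 structural parameters x 3 estimators x (2 shapes x 3 sizes) windows,
    keyed by :func:`dispersion_map_name`.  All-NaN inputs propagate to
    all-NaN outputs.
    """
    out: dict[str, np.ndarray] = {}
    for param in STRUCTURAL_KEYS:
        image = np.asarray(maps[param], dtype=float)
        for est in ESTIMATORS:
            for shape in WINDOW_SHAPES:
                for size in sizes:
                    win = WindowSpec(shape, size)
                    job = DispersionJob(
                        parameter=param,
                        estimator=est,
                        window=win,
                        entropy_bins=entropy_bins,
                        min_valid_fraction=min_valid_fraction,
                        circular_phi=circular_phi,
                    )
                    out[dispersion_map_name(param, est, win)] = local_dispersion(
                        image, job
                    ).astype(np.float32)
    return out
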