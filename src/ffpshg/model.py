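"""Single-axis collagen model for polarization-resolved SHG and phantom stacks.

The model describes the SHG intensity of a collagen fibril lying in the image
plane, with cylindrical symmetry about the fibril axis, as a function of the
linear excitation polarization angle ``alpha``:

    I(alpha) = I0 * [ sin^2(2(phi - alpha))
                      + (b * sin^2(phi - alpha) + c * cos^2(phi - alpha))^2 ]

where ``b = chi31/chi15`` and ``c = chi33/chi15`` are ratios of the nonzero
second-order susceptibility tensor elements and ``phi`` is the in-plane fibril
orientation (degrees, modulo 180).  The signal is exactly 180-degree periodic
and its harmonic content stops at cos(4(phi - alpha)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "CollagenParams",
    "PolarizationGrid",
    "PhantomRegion",
    "PhantomSpec",
    "shg_intensity",
    "fourier_coeffs_from_params",
    "theta_from_ratio",
    "generate_stack",
    "write_phantom_roi",
    "DEFAULT_GRID",
    "PROCESSING_GRID",
]


@dataclass(frozen=True)
class CollagenParams:
    """Per-pixel collagen model parameters.

    Attributes
    ----------
    i0 : float
        Intensity scale (arbitrary units, > 0).
    b : float
        chi31/chi15 tensor-element ratio (dimensionless).
    c : float
        chi33/chi15 tensor-element ratio (dimensionless).
    phi : float
        In-plane fibril orientation in degrees, normalized to [0, 180).
    """

    i0: float
    b: float
    c: float
    phi: float

    def __post_init__(self) -> None:
        if not self.i0 > 0:
            raise ValueError(f"i0 must be positive, got {self.i0}")
        object.__setattr__(self, "phi", float(self.phi) % 180.0)

    @property
    def chi3331(self) -> float:
        """Derived chi33/chi31 ratio (c / b)."""
        if self.b == 0:
            return float("nan")
        return self.c / self.b


@dataclass(frozen=True)
class PolarizationGrid:
    """Ordered excitation polarization angles in degrees, within [0, 180]."""

    angles: tuple[float, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        if a.ndim != 1 or len(a) < 2:
            raise ValueError("grid needs at least two angles")
        if np.any(np.diff(a) <= 0):
            raise ValueError("angles must be strictly increasing")
        if a[0] < 0 or a[-1] > 180:
            raise ValueError("angles must lie within [0, 180]")
        object.__setattr__(self, "angles", tuple(float(x) for x in a))

    def __len__(self) -> int:
        return len(self.angles)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.angles, dtype=float)


#: Acquisition grid: 0..180 deg in 20-deg steps (10 frames).
DEFAULT_GRID = PolarizationGrid(tuple(float(a) for a in range(0, 181, 20)))
#: Processing grid after endpoint averaging: 0..160 deg (9 frames).
PROCESSING_GRID = PolarizationGrid(tuple(float(a) for a in range(0, 161, 20)))


def shg_intensity(params: CollagenParams, alpha) -> np.ndarray | float:
    """SHG intensity of the single-axis model at polarization angle ``alpha``.

    ``alpha`` may be a scalar or array of degrees; the result is >= 0 and
    180-degree periodic in ``alpha``.
    """
    a = np.deg2rad(np.asarray(alpha, dtype=float))
    d = np.deg2rad(params.phi) - a
    s2, c2 = np.sin(d) ** 2, np.cos(d) ** 2
    out = params.i0 * (np.sin(2 * d) ** 2 + (params.b * s2 + params.c * c2) ** 2)
    return float(out) if np.isscalar(alpha) else out


def fourier_coeffs_from_params(params: CollagenParams) -> tuple[float, float, float]:
    """Exact harmonic decomposition of the model intensity.

    Returns (c0, c1, c2) such that
    ``I(alpha) = c0 + c1*cos(2(phi-alpha)) + c2*cos(4(phi-alpha))``
    with all coefficients scaled by ``i0``.  With u = c - b and v = c + b:
    c0 = 1/2 + v^2/4 + u^2/8, c1 = (c^2 - b^2)/2, c2 = u^2/8 - 1/2.
    """
    u = params.c - params.b
    v = params.c + params.b
    c0 = 0.5 + v * v / 4.0 + u * u / 8.0
    c1 = u * v / 2.0
    c2 = u * u / 8.0 - 0.5
    return (params.i0 * c0, params.i0 * c1, params.i0 * c2)


def theta_from_ratio(r) -> np.ndarray | float:
    """Helical pitch angle (degrees) from the chi33/chi15 ratio.

    theta_e = arccos(sqrt(r / (2 + r))), equivalently arctan(sqrt(2 / r)):
    strictly decreasing in r, with theta_from_ratio(2) = 45 degrees exactly.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.isscalar(r) and r_arr <= 0:
        raise ValueError(f"ratio must be positive, got {r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.degrees(np.arccos(np.sqrt(r_arr / (2.0 + r_arr))))
        theta = np.where(r_arr > 0, theta, np.nan)
    return float(theta) if np.isscalar(r) else theta


@dataclass(frozen=True)
class PhantomRegion:
    """A rectangular or masked phantom region with uniform collagen params."""

    mask: np.ndarray  # boolean (H, W)
    params: CollagenParams


@dataclass
class PhantomSpec:
    """Specification of a synthetic phantom stack.

    Collagen pixels follow the single-axis model exactly; pixels outside all
    region masks are polarization-independent background (constant mean plus
    noise), emulating SHG-inactive tissue.  ``noise_model`` is one of
    ``"none"``, ``"gaussian"`` (with ``noise_sigma`` counts) or ``"poisson"``
    (with ``poisson_gain`` counts per model unit).  ``bit_depth=8`` linearly
    rescales the stack maximum to 255 and rounds, mimicking the 8-bit export
    of the real data; ``bit_depth=None`` keeps exact float intensities.
    """

    height: int
    width: int
    regions: Sequence[PhantomRegion] = field(default_factory=list)
    background_level: float = 2.0
    noise_model: str = "none"
    noise_sigma: float = 2.0
    poisson_gain: float = 1.0
    bit_depth: int | None = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.bit_depth not in (8, None):
            raise ValueError("bit_depth must be 8 or None")
        covered = np.zeros((self.height, self.width), dtype=int)
        for reg in self.regions:
            if reg.mask.shape != (self.height, self.width):
                raise ValueError(
                    f"region mask shape {reg.mask.shape} does not match "
                    f"phantom shape {(self.height, self.width)}"
                )
            covered += reg.mask.astype(int)
        if np.any(covered > 1):
            raise ValueError("region masks overlap")

    def ground_truth(self) -> dict[str, np.ndarray]:
        """Per-pixel true parameter maps (NaN on background pixels)."""
        shape = (self.height, self.width)
        maps = {k: np.full(shape, np.nan) for k in
                ("I0", "CHI3115", "CHI3315", "CHI3331", "FI", "THETA")}
        for reg in self.regions:
            p = reg.params
            maps["I0"][reg.mask] = p.i0
            maps["CHI3115"][reg.mask] = p.b
            maps["CHI3315"][reg.mask] = p.c
            maps["CHI3331"][reg.mask] = p.chi3331
            maps["FI"][reg.mask] = p.phi
            maps["THETA"][reg.mask] = theta_from_ratio(p.c) if p.c > 0 else np.nan
        return maps


def generate_stack(spec: PhantomSpec, grid: PolarizationGrid = DEFAULT_GRID) -> np.ndarray:
    """Simulate a phantom stack: one frame per grid angle, shape (n, H, W).

    Deterministic given ``spec.seed``.  The 0- and 180-degree frames carry
    identical model signal but independent noise draws, so endpoint averaging
    remains meaningful under noise.
    """
    if len(grid) != 10 or grid.angles != DEFAULT_GRID.angles:
        raise ValueError("phantom stacks use the default 10-angle grid")
    rng = np.random.default_rng(spec.seed)
    angles = grid.as_array()
    stack = np.full((len(grid), spec.height, spec.width), float(spec.background_level))
    for reg in spec.regions:
        vals = shg_intensity(reg.params, angles)  # (n,)
        stack[:, reg.mask] = vals[:, None]
    if spec.noise_model == "gaussian":
        stack = stack + rng.normal(0.0, spec.noise_sigma, stack.shape)
    elif spec.noise_model == "poisson":
        stack = rng.poisson(np.clip(stack * spec.poisson_gain, 0, None)).astype(float)
        stack /= spec.poisson_gain
    if spec.bit_depth == 8:
        peak = stack.max()
        if peak > 0:
            stack = stack * (255.0 / peak)
        stack = np.clip(np.rint(stack), 0, 255)
    return stack


def write_phantom_roi(
    folder: str | Path,
    spec: PhantomSpec,
    roi: int,
    detection: str = "FSHG",
    grid: PolarizationGrid = DEFAULT_GRID,
) -> np.ndarray:
    """Write one phantom detection folder of 10 TIFF frames plus ground truth.

    Frames are named ``phantom_[roi]_[detection]_[angle].tif``; the true
    parameter maps go to a ``GroundTruth`` sibling folder as 32-bit float
    TIFFs.  Returns the generated stack.
    """
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    stack = generate_stack(spec, grid)
    dtype = np.uint8 if spec.bit_depth == 8 else np.float32
    for ang, frame in zip(grid.angles, stack):
        name = f"phantom_{roi}_{detection}_{int(ang)}.tif"
        tifffile.imwrite(folder / name, frame.astype(dtype))
    gt_dir = folder.parent / "GroundTruth"
    gt_dir.mkdir(exist_ok=True)
    for key, arr in spec.ground_truth().items():
        tifffile.imwrite(gt_dir / f"{key}_{detection}_true.tif", arr.astype(np.float32))
    return stack
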