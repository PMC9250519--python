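"""Readers, writers and manifest validation for PSHG-TISS-layout collections.

Collection layout (all images plain TIFF):

    <root>/
      <tissue>[_HE]_<roi>/              one folder per imaged ROI
        <tissue>[_HE]_<roi>_TPEF.tif    two-photon fluorescence context image
        FSHG/                           forward-detected SHG stack
          <tissue>[_HE]_<roi>_FSHG_<angle>.tif   angle in 0..180 step 20
          Results/                      computed maps (32-bit float)
            CHI3115.tif ... ERR.tif     the 8 analysis maps
            FI_ENT_circular_15.tif ...  the 90 dispersion maps
        BSHG/                           backward-detected SHG stack (same)

File names follow ``[tissue]_[HE]_[roi]_[detection]_[angle]``; unstained
sections omit the HE token entirely.  Thyroid sections are H&E-stained but
their published IDs carry no HE token, so the class table keys on the name
format actually used.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .core import MAP_KEYS, STRUCTURAL_KEYS, ParameterMapSet
from .dispersion import (
    ESTIMATORS,
    WINDOW_SHAPES,
    WINDOW_SIZES,
    WindowSpec,
    dispersion_map_name,
)
from .model import DEFAULT_GRID

__all__ = [
    "ParsedName",
    "RoiRecord",
    "CollectionManifest",
    "FilenameError",
    "TISSUE_CLASS_TABLE",
    "PUBLISHED_ROI_TOTALS",
    "parse_filename",
    "format_filename",
    "roi_class",
    "expected_counts",
    "read_stack",
    "write_maps",
    "write_dispersion_maps",
    "validate_collection",
    "expected_roi_files",
]

TISSUES = ("breast", "skin", "thyroid", "phantom")
DETECTIONS = ("FSHG", "BSHG")
ANGLES = tuple(int(a) for a in DEFAULT_GRID.angles)

#: Class label per (tissue, he_in_name) -> list of (lo, hi, label), inclusive.
TISSUE_CLASS_TABLE: dict[tuple[str, bool], list[tuple[int, int, str]]] = {
    ("breast", False): [
        (1, 18, "normal TDLU"),
        (19, 30, "ductal carcinoma in situ"),
        (31, 48, "invasive carcinoma"),
    ],
    ("breast", True): [
        (1, 18, "normal TDLU"),
        (19, 30, "ductal carcinoma in situ"),  # printed as "in-situ carcinoma"
        (31, 47, "invasive carcinoma"),
    ],
    ("skin", False): [
        (1, 10, "papillary dermis"),
        (11, 32, "reticular dermis"),
        (33, 53, "subcutaneous tissue"),
    ],
    ("skin", True): [
        (1, 10, "papillary dermis"),
        (11, 32, "reticular dermis"),
        (33, 53, "subcutaneous tissue"),
    ],
    # thyroid sections are H&E-stained but the IDs omit the HE token
    ("thyroid", False): [
        (1, 20, "papillary thyroid carcinoma"),
        (21, 40, "follicular adenoma"),
    ],
}

#: ROI totals per (tissue, he_in_name) group as published for the collection.
PUBLISHED_ROI_TOTALS: dict[tuple[str, bool], int] = {
    ("breast", False): 48,
    ("breast", True): 47,
    ("skin", False): 53,
    ("skin", True): 53,
    ("thyroid", False): 40,
}


class FilenameError(ValueError):
    """A file name does not follow the collection nomenclature."""


@dataclass(frozen=True)
class ParsedName:
    """Decomposed collection file name."""

    tissue: str
    stained: bool  # HE token present in the name
    roi: int
    detection: str  # FSHG, BSHG or TPEF
    angle: int | None  # None for TPEF images

    @property
    def class_label(self) -> str | None:
        return roi_class(self.tissue, self.stained, self.roi)


@dataclass(frozen=True)
class RoiRecord:
    """One imaged region of interest and its histological class."""

    tissue: str
    stained: bool
    roi_index: int

    def __post_init__(self) -> None:
        if self.roi_index < 1:
            raise ValueError("roi_index must be a positive integer")

    @property
    def name(self) -> str:
        he = "_HE" if self.stained else ""
        return f"{self.tissue}{he}_{self.roi_index}"

    @property
    def class_label(self) -> str | None:
        return roi_class(self.tissue, self.stained, self.roi_index)


def roi_class(tissue: str, stained: bool, roi: int) -> str | None:
    """Histological class of an ROI from the published ranges; None if unknown."""
    ranges = TISSUE_CLASS_TABLE.get((tissue, stained))
    if ranges is None:
        return None
    for lo, hi, label in ranges:
        if lo <= roi <= hi:
            return label
    return None


_NAME_RE = re.compile(
    r"^(?P<tissue>[a-z]+)(?:_(?P<he>HE))?_(?P<roi>\d+)_"
    r"(?:(?P<det>FSHG|BSHG)_(?P<angle>\d+)|TPEF)$"
)


def parse_filename(name: str) -> ParsedName:
    """Parse a collection file name (extension optional).

    Accepts ``[tissue]_[HE]_[roi]_[FSHG|BSHG]_[angle]`` and
    ``[tissue]_[HE]_[roi]_TPEF``; raises :class:`FilenameError` naming the
    offending token otherwise.
    """
    stem = Path(name).name
    for ext in (".tiff", ".tif"):
        if stem.lower().endswith(ext):
            stem = stem[: -len(ext)]
            break
    m = _NAME_RE.match(stem)
    if not m:
        tokens = stem.split("_")
        if tokens[0] not in TISSUES:
            raise FilenameError(f"unknown tissue token {tokens[0]!r} in {name!r}")
        raise FilenameError(f"malformed name {name!r}: cannot parse {stem!r}")
    tissue = m.group("tissue")
    if tissue not in TISSUES:
        raise FilenameError(f"unknown tissue token {tissue!r} in {name!r}")
    if m.group("det"):
        angle = int(m.group("angle"))
        if angle not in ANGLES:
            raise FilenameError(f"invalid angle token {m.group('angle')!r} in {name!r}")
        detection = m.group("det")
    else:
        angle = None
        detection = "TPEF"
    return ParsedName(
        tissue=tissue,
        stained=m.group("he") is not None,
        roi=int(m.group("roi")),
        detection=detection,
        angle=angle,
    )


def format_filename(
    tissue: str, stained: bool, roi: int, detection: str, angle: int | None = None
) -> str:
    """Inverse of :func:`parse_filename` (without extension)."""
    if tissue not in TISSUES:
        raise FilenameError(f"unknown tissue {tissue!r}")
    he = "_HE" if stained else ""
    if detection == "TPEF":
        return f"{tissue}{he}_{roi}_TPEF"
    if detection not in DETECTIONS:
        raise FilenameError(f"unknown detection {detection!r}")
    if angle not in ANGLES:
        raise FilenameError(f"invalid angle {angle!r}")
    return f"{tissue}{he}_{roi}_{detection}_{angle}"


# per-stack and per-ROI multiplicities of the collection layout
SHG_PER_STACK = 10
MAPS_PER_STACK = 8
DISPERSION_PER_STACK = 90
STACKS_PER_ROI = 2  # FSHG + BSHG
TPEF_PER_ROI = 1


def expected_counts(roi_totals) -> dict[str, int]:
    """Image inventory implied by per-group ROI totals.

    ``roi_totals`` is a mapping or sequence of per-group ROI counts.  The
    published totals (48, 47, 53, 53, 40) give 241 ROIs, 482 stacks, 4,820
    SHG images, 241 TPEF images, 3,856 analysis maps, 43,380 dispersion maps
    and 52,297 images in total.
    """
    if isinstance(roi_totals, dict):
        totals = list(roi_totals.values())
    else:
        totals = list(roi_totals)
    if any(t < 0 for t in totals):
        raise ValueError("ROI totals must be non-negative")
    rois = int(sum(totals))
    stacks = rois * STACKS_PER_ROI
    shg = stacks * SHG_PER_STACK
    tpef = rois * TPEF_PER_ROI
    maps = stacks * MAPS_PER_STACK
    dispersion = stacks * DISPERSION_PER_STACK
    return {
        "rois": rois,
        "stacks": stacks,
        "shg_images": shg,
        "tpef_images": tpef,
        "ffpshg_maps": maps,
        "dispersion_maps": dispersion,
        "total_images": shg + tpef + maps + dispersion,
    }


def read_stack(folder: str | Path) -> np.ndarray:
    """Read one detection folder into a (10, H, W) float stack ordered by angle.

    Raises ValueError listing the offending files on missing or duplicate
    angles or on frame-shape mismatch.
    """
    folder = Path(folder)
    frames: dict[int, Path] = {}
    for path in sorted(folder.iterdir()):
        if not path.is_file() or not path.suffix.lower() in (".tif", ".tiff"):
            continue
        try:
            parsed = parse_filename(path.name)
        except FilenameError:
            continue
        if parsed.detection == "TPEF":
            continue
        if parsed.angle in frames:
            raise ValueError(
                f"duplicate angle {parsed.angle} in {folder}: "
                f"{frames[parsed.angle].name}, {path.name}"
            )
        frames[parsed.angle] = path
    missing = [a for a in ANGLES if a not in frames]
    if missing:
        raise ValueError(
            f"missing angle(s) {', '.join(str(a) for a in missing)} in {folder}"
        )
    images = [tifffile.imread(frames[a]).astype(float) for a in ANGLES]
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes in {folder}: {shapes}")
    return np.stack(images)


def write_maps(folder: str | Path, maps: ParameterMapSet) -> Path:
    """Write the eight analysis maps as 32-bit float TIFFs in ``Results``.

    Returns the ``Results`` folder path.
    """
    results = Path(folder) / "Results"
    results.mkdir(parents=True, exist_ok=True)
    for key in MAP_KEYS:
        tifffile.imwrite(results / f"{key}.tif", np.asarray(maps[key], dtype=np.float32))
    return results


def write_dispersion_maps(folder: str | Path, maps: dict[str, np.ndarray]) -> Path:
    """Write dispersion maps as 32-bit float TIFFs in ``Results``."""
    results = Path(folder) / "Results"
    results.mkdir(parents=True, exist_ok=True)
    for name, arr in maps.items():
        tifffile.imwrite(results / f"{name}.tif", np.asarray(arr, dtype=np.float32))
    return results


def expected_roi_files(roi_folder_name: str) -> dict[str, list[str]]:
    """Relative paths expected inside one ROI folder, keyed by category."""
    parsed = parse_filename(f"{roi_folder_name}_TPEF")
    shg, maps, disp = [], [], []
    for det in DETECTIONS:
        for ang in ANGLES:
            shg.append(
                f"{det}/{format_filename(parsed.tissue, parsed.stained, parsed.roi, det, ang)}.tif"
            )
        for key in MAP_KEYS:
            maps.append(f"{det}/Results/{key}.tif")
        for param in STRUCTURAL_KEYS:
            for est in ESTIMATORS:
                for shape in WINDOW_SHAPES:
                    for size in WINDOW_SIZES:
                        disp.append(
                            f"{det}/Results/"
                            f"{dispersion_map_name(param, est, WindowSpec(shape, size))}.tif"
                        )
    return {
        "tpef": [f"{roi_folder_name}_TPEF.tif"],
        "shg": shg,
        "ffpshg_maps": maps,
        "dispersion_maps": disp,
    }


@dataclass
class CollectionManifest:
    """Validation report for a collection tree."""

    root: Path
    rois: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)  # root-relative paths
    extra: list[str] = field(default_factory=list)
    expected: dict[str, int] = field(default_factory=dict)
    observed: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.missing and not self.extra

    def to_json(self, path: str | Path) -> None:
        payload = {
            "root": str(self.root),
            "ok": self.ok,
            "rois": self.rois,
            "expected": self.expected,
            "observed": self.observed,
            "missing": self.missing,
            "extra": self.extra,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["status", "path"])
            for p in self.missing:
                w.writerow(["missing", p])
            for p in self.extra:
                w.writerow(["extra", p])
            for key in self.expected:
                w.writerow([f"count:{key}", f"{self.observed.get(key, 0)}/{self.expected[key]}"])


def validate_collection(root: str | Path) -> CollectionManifest:
    """Compare a collection tree against the layout it should contain.

    Every first-level directory whose name parses as ``[tissue][_HE]_[roi]``
    is treated as an ROI folder and must hold the full complement: 1 TPEF
    image, 2 detection folders of 10 SHG frames each, and per detection a
    ``Results`` folder with the 8 analysis maps and 90 dispersion maps.
    ``GroundTruth`` folders (phantom sidecars) are ignored.
    """
    root = Path(root)
    if not root.is_dir():
        raise ValueError(f"collection root {root} is not a readable directory")
    manifest = CollectionManifest(root=root)
    categories = ("tpef", "shg", "ffpshg_maps", "dispersion_maps")
    expected_counter = {k: 0 for k in categories}
    observed_counter = {k: 0 for k in categories}

    for roi_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        try:
            parse_filename(f"{roi_dir.name}_TPEF")
        except FilenameError:
            continue
        manifest.rois.append(roi_dir.name)
        expected = expected_roi_files(roi_dir.name)
        expected_flat = {p for group in expected.values() for p in group}
        for cat in categories:
            expected_counter[cat] += len(expected[cat])
        observed = set()
        for path in roi_dir.rglob("*"):
            if not path.is_file():
                continue
            if "GroundTruth" in path.parts:
                continue
            rel = path.relative_to(roi_dir).as_posix()
            observed.add(rel)
        for cat in categories:
            observed_counter[cat] += sum(1 for p in expected[cat] if p in observed)
        for p in sorted(expected_flat - observed):
            manifest.missing.append(f"{roi_dir.name}/{p}")
        for p in sorted(observed - expected_flat):
            if p.lower().endswith((".tif", ".tiff")):
                manifest.extra.append(f"{roi_dir.name}/{p}")

    manifest.expected = dict(expected_counter)
    manifest.observed = dict(observed_counter)
    return manifest
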