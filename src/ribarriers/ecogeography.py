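"""Ecogeographic isolation from habitat-suitability grids.

Pipeline: per-ecotype habitat-suitability surfaces (e.g. from a species
distribution model) are binarized at an equal-training-sensitivity-and-
specificity (ETSS) threshold, a pollen-dispersal buffer (default 500 m) is
dilated around suitable pixels, pixels are classified as focal-only /
other-only / shared, and ecogeographic RI is the RI4C index on the shared vs
focal-only counts.

Rasters are read and written as single-band ESRI ASCII grids (a plain-text
format: a 6-line header followed by whitespace-separated rows).  Grids are
row-major with the origin at the top-left pixel corner; occurrence points map
to pixels through half-open intervals:
row = floor((y0 - y)/pixel), col = floor((x - x0)/pixel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .ri_core import CooccurrenceCounts, ri_cooccurrence

__all__ = [
    "SuitabilityGrid",
    "OccurrenceSet",
    "BinaryHabitatMap",
    "OverlapClassification",
    "read_ascii_grid",
    "write_ascii_grid",
    "etss_threshold",
    "binarize",
    "dilate",
    "classify_overlap",
    "ri_ecogeographic",
]


@dataclass(frozen=True)
class SuitabilityGrid:
    """A rectangular grid of habitat-suitability scores in [0, 1].

    ``values`` holds NaN for missing cells; ``pixel_size`` is meters per pixel
    side (250 m in the motivating study); ``origin`` is the projected (x, y)
    of the top-left pixel corner.
    """

    values: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("suitability grid must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("suitability scores must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the pixel containing projected point (x, y)."""
        x0, y0 = self.origin
        col = math.floor((x - x0) / self.pixel_size)
        row = math.floor((y0 - y) / self.pixel_size)
        nr, nc = self.shape
        if not (0 <= row < nr and 0 <= col < nc):
            raise ValueError(f"point ({x}, {y}) falls outside the grid extent")
        return row, col

    def scores_at(self, points: pd.DataFrame) -> np.ndarray:
        """Suitability scores at the pixels containing each (x, y) point."""
        idx = [self.pixel_of(p.x, p.y) for p in points.itertuples()]
        rows, cols = zip(*idx)
        return self.values[list(rows), list(cols)]


@dataclass(frozen=True)
class OccurrenceSet:
    """Occurrence points (projected x, y) labelled by ecotype."""

    points: pd.DataFrame  # columns: x, y, ecotype

    def __post_init__(self) -> None:
        missing = {"x", "y", "ecotype"} - set(self.points.columns)
        if missing:
            raise ValueError(f"occurrence table lacks columns {sorted(missing)}")
        if self.points.empty:
            raise ValueError("occurrence set is empty")

    def for_ecotype(self, ecotype: str) -> pd.DataFrame:
        sub = self.points[self.points["ecotype"] == ecotype]
        if sub.empty:
            raise ValueError(f"no occurrences for ecotype {ecotype!r}")
        return sub


@dataclass(frozen=True)
class BinaryHabitatMap:
    """Boolean suitable/unsuitable map aligned to a source grid."""

    suitable: np.ndarray
    threshold: float
    ecotype: str
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        s = np.asarray(self.suitable, dtype=bool)
        if s.ndim != 2:
            raise ValueError("habitat map must be 2-D")
        object.__setattr__(self, "suitable", s)

    def aligned_with(self, other: "BinaryHabitatMap") -> bool:
        return (
            self.suitable.shape == other.suitable.shape
            and self.pixel_size == other.pixel_size
            and self.origin == other.origin
        )


@dataclass(frozen=True)
class OverlapClassification:
    """Pixel counts from overlaying two (buffered) binary habitat maps.

    ``shared_from_model`` counts pixels suitable for both ecotypes before
    buffering; ``shared_from_buffer`` counts pixels reclassified as shared by
    the dispersal boundary.
    """

    focal_only: int
    other_only: int
    shared: int
    shared_from_model: int
    shared_from_buffer: int

    def __post_init__(self) -> None:
        for name in ("focal_only", "other_only", "shared", "shared_from_model", "shared_from_buffer"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.shared != self.shared_from_model + self.shared_from_buffer:
            raise ValueError("shared must equal shared_from_model + shared_from_buffer")

    @property
    def union(self) -> int:
        """Pixels suitable for at least one ecotype."""
        return self.focal_only + self.other_only + self.shared

    def swapped(self) -> "OverlapClassification":
        return OverlapClassification(
            self.other_only, self.focal_only, self.shared, self.shared_from_model, self.shared_from_buffer
        )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def read_ascii_grid(path: str | Path, crs_label: str = "") -> SuitabilityGrid:
    """Read a single-band ESRI ASCII (.asc) raster into a SuitabilityGrid."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: ESRI ASCII header lacks {key}")
    values = np.loadtxt(lines[i:], dtype=float)
    values = values.reshape(int(header["nrows"]), int(header["ncols"]))
    if "nodata_value" in header:
        values = np.where(values == header["nodata_value"], np.nan, values)
    origin = (header["xllcorner"], header["yllcorner"] + header["nrows"] * header["cellsize"])
    return SuitabilityGrid(values, header["cellsize"], origin, crs_label)


def write_ascii_grid(grid: SuitabilityGrid | BinaryHabitatMap, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a grid (float scores or 0/1 habitat map) as ESRI ASCII."""
    if isinstance(grid, BinaryHabitatMap):
        values = grid.suitable.astype(float)
    else:
        values = grid.values
    nrows, ncols = values.shape
    x0, y0 = grid.origin
    out = np.where(np.isfinite(values), values, nodata)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {x0}\n"
        f"yllcorner {y0 - nrows * grid.pixel_size}\n"
        f"cellsize {grid.pixel_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def etss_threshold(presence_scores, background_scores) -> float:
    """Equal-training-sensitivity-and-specificity binarization threshold.

    Scans the sorted unique pooled scores as candidate thresholds t and
    returns the one minimizing |sensitivity(t) - specificity(t)| where
    sensitivity is the fraction of presence scores >= t and specificity the
    fraction of background scores < t.  Ties resolve to the smallest t.
    """
    pres = np.asarray(presence_scores, dtype=float)
    back = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or back.size == 0:
        raise ValueError("presence and background scores must be non-empty")
    candidates = np.unique(np.concatenate([pres, back]))
    # vectorized scan: counts of scores >= t via searchsorted on sorted arrays
    pres_sorted = np.sort(pres)
    back_sorted = np.sort(back)
    sens = 1.0 - np.searchsorted(pres_sorted, candidates, side="left") / pres.size
    spec = np.searchsorted(back_sorted, candidates, side="left") / back.size
    gap = np.abs(sens - spec)
    # ties (within float rounding of the count ratios) resolve to smallest t
    near_min = np.flatnonzero(gap <= gap.min() + 1e-12)
    return float(candidates[near_min[0]])


def binarize(grid: SuitabilityGrid, threshold: float, ecotype: str) -> BinaryHabitatMap:
    """Threshold a suitability grid: suitable where score >= threshold.

    Missing cells are always unsuitable.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    with np.errstate(invalid="ignore"):
        suitable = np.where(np.isfinite(grid.values), grid.values >= threshold, False)
    return BinaryHabitatMap(suitable, threshold, ecotype, grid.pixel_size, grid.origin)


def _structuring_element(radius_px: int, structure: str) -> np.ndarray:
    size = 2 * radius_px + 1
    if structure == "square":
        return np.ones((size, size), dtype=bool)
    if structure == "disk":
        dy, dx = np.ogrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
        return dx * dx + dy * dy <= radius_px * radius_px
    raise ValueError(f"unknown structuring element {structure!r}; use 'square' or 'disk'")


def dilate(habitat: BinaryHabitatMap, radius_m: float, structure: str = "square") -> BinaryHabitatMap:
    """Grow suitable habitat by a dispersal radius.

    The radius in pixels is ceil(radius_m / pixel_size); under the default
    square (Chebyshev) structuring element a pixel becomes suitable if any
    source pixel lies within that many rows *and* columns.  radius 0 is the
    identity.
    """
    if radius_m < 0:
        raise ValueError("radius_m must be non-negative")
    radius_px = math.ceil(radius_m / habitat.pixel_size)
    if radius_px == 0:
        return habitat
    out = ndimage.binary_dilation(habitat.suitable, structure=_structuring_element(radius_px, structure))
    return BinaryHabitatMap(out, habitat.threshold, habitat.ecotype, habitat.pixel_size, habitat.origin)


def classify_overlap(
    map_focal: BinaryHabitatMap,
    map_other: BinaryHabitatMap,
    radius_m: float,
    structure: str = "square",
) -> OverlapClassification:
    """Classify pixels as focal-only / other-only / shared.

    A pixel is shared if it is model-suitable for both ecotypes, or if the
    dispersal buffer of one ecotype reaches a pixel model-suitable for the
    other: shared = (F & O) | (dilate(F) & O) | (F & dilate(O)).
    """
    if not map_focal.aligned_with(map_other):
        raise ValueError("habitat maps are not aligned (shape, origin or pixel size differ)")
    F = map_focal.suitable
    O = map_other.suitable
    dF = dilate(map_focal, radius_m, structure).suitable
    dO = dilate(map_other, radius_m, structure).suitable
    model_shared = F & O
    shared = model_shared | (dF & O) | (F & dO)
    focal_only = F & ~shared
    other_only = O & ~shared
    n_model = int(model_shared.sum())
    n_shared = int(shared.sum())
    return OverlapClassification(
        focal_only=int(focal_only.sum()),
        other_only=int(other_only.sum()),
        shared=n_shared,
        shared_from_model=n_model,
        shared_from_buffer=n_shared - n_model,
    )


def ri_ecogeographic(classification: OverlapClassification) -> float:
    """Ecogeographic RI4C: shared pixels are S, focal-only pixels are U."""
    return ri_cooccurrence(CooccurrenceCounts(S=classification.shared, U=classification.focal_only))


def classified_raster(
    map_focal: BinaryHabitatMap,
    map_other: BinaryHabitatMap,
    radius_m: float,
    structure: str = "square",
) -> np.ndarray:
    """Per-pixel classification codes: 0 none, 1 focal-only, 2 other-only, 3 shared."""
    if not map_focal.aligned_with(map_other):
        raise ValueError("habitat maps are not aligned")
    F = map_focal.suitable
    O = map_other.suitable
    dF = dilate(map_focal, radius_m, structure).suitable
    dO = dilate(map_other, radius_m, structure).suitable
    shared = (F & O) | (dF & O) | (F & dO)
    out = np.zeros(F.shape, dtype=np.int8)
    out[F & ~shared] = 1
    out[O & ~shared] = 2
    out[shared] = 3
    return out
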