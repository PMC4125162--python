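"""Circular landscape buffers, height classification, patch labeling and
depth-weighted edge tables.

The segmentation pipeline is pixel-based: heights are classified with a set
of global thresholds, same-class cells are grouped into patches by
contiguity (8-neighbor by default, the FRAGSTATS convention) and the faces
between 4-adjacent cells of different classes become "vertical edges" whose
contrast weight ("depth") encodes the height difference between the two
sides.  Faces on the window boundary or touching nodata are never edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import HeightRaster

#: Default class boundaries in meters for vegetated heights; the vegetation
#: cutoff is 0 m (any positive height is vegetated).  Yields 5 vegetated
#: classes: (0,5], (5,10], (10,15], (15,25], (25, inf).
DEFAULT_THRESHOLDS: tuple[float, ...] = (5.0, 10.0, 15.0, 25.0)

_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class LandscapeWindow:
    """A clipped grid restricted to a circular buffer.

    ``values`` holds heights (m); ``valid`` is True for cells inside the
    buffer and not nodata.  Values outside ``valid`` are zeroed.
    """

    values: np.ndarray
    valid: np.ndarray
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid mask shapes differ")
        self.values = np.where(self.valid, self.values, 0.0)

    @property
    def area_m2(self) -> float:
        """Landscape area: area of valid (non-nodata, in-buffer) cells."""
        return float(self.valid.sum()) * self.cell_size**2

    @classmethod
    def from_raster(cls, raster: HeightRaster) -> "LandscapeWindow":
        """Treat a whole raster as one landscape window."""
        return cls(raster.values, raster.valid, raster.cell_size)


@dataclass
class HeightClassMap:
    """Integer class grid: 0 = non-vegetated, 1..m = ascending height classes."""

    classes: np.ndarray
    valid: np.ndarray
    thresholds: tuple[float, ...]
    cell_size: float

    @property
    def n_classes(self) -> int:
        """Number of vegetated classes."""
        return len(self.thresholds) + 1

    @property
    def midpoints(self) -> np.ndarray:
        return class_midpoints(self.thresholds)


@dataclass
class PatchMap:
    """Labeled patches of a class map.

    ``labels`` is 0 for background/nodata and 1..n for patches.  ``patches``
    has one row per patch: patch_id, class_index, area_m2, perimeter_m.
    Patch perimeter counts every 4-face not shared with a cell of the same
    patch (window boundary and nodata faces included, as for an isolated
    square patch).
    """

    labels: np.ndarray
    patches: pd.DataFrame
    classes: np.ndarray
    valid: np.ndarray
    cell_size: float

    @property
    def n_patches(self) -> int:
        return len(self.patches)


@dataclass
class EdgeTable:
    """Class-pair edge lengths with contrast depths.

    ``table`` columns: class_i, class_j (i < j), length_m, depth.  The
    contrast matrix used to assign depths is kept for downstream per-patch
    contrast indices.
    """

    table: pd.DataFrame
    contrast: np.ndarray
    cell_size: float
    include_background: bool = True

    @property
    def total_length(self) -> float:
        return float(self.table["length_m"].sum())

    @property
    def weighted_length(self) -> float:
        return float((self.table["length_m"] * self.table["depth"]).sum())


# ----------------------------------------------------------------------
def extract_buffer(
    raster: HeightRaster, center: tuple[float, float], radius: float
) -> LandscapeWindow:
    """Clip a circular buffer from a raster.

    A cell is retained iff its *center* lies within ``radius`` of
    ``center``; everything else becomes invalid.  The returned window is
    cropped to the bounding box of retained cells.

    Raises
    ------
    ValueError
        If no cell center falls inside the buffer ("buffer outside raster").
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    xs, ys = raster.cell_centers()
    cx, cy = center
    d2 = (ys - cy)[:, None] ** 2 + (xs - cx)[None, :] ** 2
    inside = d2 <= radius**2
    if not inside.any():
        raise ValueError("buffer outside raster")
    rows = np.flatnonzero(inside.any(axis=1))
    cols = np.flatnonzero(inside.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    valid = inside[sl] & raster.valid[sl]
    return LandscapeWindow(raster.values[sl], valid, raster.cell_size)


def class_midpoints(thresholds: tuple[float, ...]) -> np.ndarray:
    """Representative heights for each vegetated class.

    Bounded classes use the interval midpoint; the open-topped class uses
    top threshold + half the previous class width.  With no thresholds
    (binary vegetation map) a single nominal midpoint of 1.0 is returned.
    """
    t = np.asarray(thresholds, dtype=float)
    if t.size == 0:
        return np.array([1.0])
    edges = np.concatenate([[0.0], t])
    mids = (edges[:-1] + edges[1:]) / 2.0
    prev_width = t[-1] - (t[-2] if t.size > 1 else 0.0)
    top = t[-1] + prev_width / 2.0
    return np.concatenate([mids, [top]])


def default_contrast_matrix(thresholds: tuple[float, ...]) -> np.ndarray:
    """Depth weights d in [0, 1] for every class pair, background included.

    Index 0 is the non-vegetated background; vegetated classes are 1..m.
    Between vegetated classes, d = |midpoint_i - midpoint_j| scaled by the
    midpoint span; any vegetated/background pair has maximal contrast 1.
    Symmetric with zero diagonal.
    """
    mids = class_midpoints(thresholds)
    m = mids.size
    d = np.zeros((m + 1, m + 1))
    span = mids.max() - mids.min()
    if span > 0:
        diff = np.abs(mids[:, None] - mids[None, :]) / span
        d[1:, 1:] = diff
    d[0, 1:] = 1.0
    d[1:, 0] = 1.0
    return d


def classify_height(
    window: LandscapeWindow, thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
) -> HeightClassMap:
    """Assign each cell a height class.

    Height 0 (the vegetation cutoff) maps to class 0; a positive height h
    maps to class j iff t_{j-1} < h <= t_j, with t_0 = 0 and t_m = inf.
    Invalid cells keep class 0 but remain flagged via the valid mask.
    """
    t = tuple(float(x) for x in thresholds)
    if len(t) > 0:
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly ascending")
        if t[0] <= 0:
            raise ValueError("first threshold must exceed the 0 m cutoff")
    arr = np.asarray(t)
    veg = window.valid & (window.values > 0)
    cls = np.zeros(window.values.shape, dtype=np.int32)
    cls[veg] = np.searchsorted(arr, window.values[veg], side="left") + 1
    return HeightClassMap(cls, window.valid.copy(), t, window.cell_size)


def binary_class_map(window: LandscapeWindow) -> HeightClassMap:
    """Vegetated / non-vegetated classification (substrate of metric set B)."""
    return classify_height(window, thresholds=())


def label_patches(class_map: HeightClassMap, connectivity: int = 8) -> PatchMap:
    """Group contiguous same-class vegetated cells into patches.

    Labels are dense positive integers; class-0 (background) and invalid
    cells stay unlabeled (0).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    cls = class_map.classes
    labels = np.zeros(cls.shape, dtype=np.int32)
    patch_class: list[int] = []
    offset = 0
    for c in range(1, class_map.n_classes + 1):
        mask = (cls == c) & class_map.valid
        lab, n = ndimage.label(mask, structure=structure)
        if n:
            labels[mask] = lab[mask] + offset
            patch_class.extend([c] * n)
            offset += n
    cell = class_map.cell_size
    counts = np.bincount(labels.ravel(), minlength=offset + 1)[1:]
    perim = _patch_perimeters(labels, offset) * cell
    patches = pd.DataFrame(
        {
            "patch_id": np.arange(1, offset + 1, dtype=np.int64),
            "class_index": np.asarray(patch_class, dtype=np.int64),
            "area_m2": counts.astype(np.float64) * cell**2,
            "perimeter_m": perim,
        }
    )
    return PatchMap(labels, patches, cls.copy(), class_map.valid.copy(), cell)


def _patch_perimeters(labels: np.ndarray, n_patches: int) -> np.ndarray:
    """Exposed 4-face counts per patch (label != neighbor, or grid edge)."""
    per = np.zeros(n_patches + 1, dtype=np.float64)
    padded = np.pad(labels, 1, constant_values=0)
    core = padded[1:-1, 1:-1]
    for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        nb = padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        sel = (core > 0) & (core != nb)
        np.add.at(per, core[sel], 1.0)
    return per[1:]


def build_edge_table(
    patch_map: PatchMap,
    contrast: np.ndarray | None = None,
    include_background_edges: bool = True,
) -> EdgeTable:
    """Accumulate shared-face lengths for every 4-adjacent differing-class
    cell pair.

    Each shared face contributes ``cell_size`` meters to the class pair's
    edge length.  Window-boundary and nodata faces accrue nothing.  Depths
    are read from ``contrast`` (default: the midpoint-difference matrix).
    """
    cls = patch_map.classes
    valid = patch_map.valid
    n_cls = int(cls.max()) if cls.size else 0
    if contrast is None:
        contrast = default_contrast_matrix(_thresholds_of(patch_map))
    contrast = np.asarray(contrast, dtype=float)
    if contrast.shape[0] <= n_cls:
        raise ValueError(
            f"contrast matrix of size {contrast.shape[0]} cannot cover class {n_cls}"
        )
    m = contrast.shape[0]
    counts = np.zeros((m, m), dtype=np.int64)
    for axis in (0, 1):
        a = cls[:, :-1] if axis else cls[:-1, :]
        b = cls[:, 1:] if axis else cls[1:, :]
        va = valid[:, :-1] if axis else valid[:-1, :]
        vb = valid[:, 1:] if axis else valid[1:, :]
        sel = va & vb & (a != b)
        if sel.any():
            np.add.at(counts, (a[sel], b[sel]), 1)
    counts = counts + counts.T  # unordered faces; each face counted once overall
    rows = []
    for i in range(m):
        for j in range(i + 1, m):
            if counts[i, j] == 0:
                continue
            if not include_background_edges and (i == 0 or j == 0):
                continue
            rows.append((i, j, counts[i, j] * patch_map.cell_size, contrast[i, j]))
    table = pd.DataFrame(rows, columns=["class_i", "class_j", "length_m", "depth"])
    return EdgeTable(table, contrast, patch_map.cell_size, include_background_edges)


def _thresholds_of(patch_map: PatchMap) -> tuple[float, ...]:
    # PatchMap does not carry thresholds; reconstruct a nominal ladder so a
    # default contrast matrix of the right size can be built.
    n = int(patch_map.classes.max())
    return tuple(float(5 * k) for k in range(1, n)) if n > 1 else ()
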