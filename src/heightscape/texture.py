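"""Second-order (co-occurrence) texture metrics on quantized height grids.

One whole-window grey-level co-occurrence matrix (GLCM) is computed per
landscape, pooling the four 1-pixel offsets (0deg, 45deg, 90deg, 135deg)
symmetrically.  Pairs touching nodata or the window boundary are skipped,
so circular buffers inside square arrays contribute only interior pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import LandscapeWindow

#: 1-pixel displacements at 0, 45, 90 and 135 degrees.
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

#: Default number of grey levels for min-max height quantization.
DEFAULT_LEVELS = 32


@dataclass
class GLCM:
    """Normalized grey-level co-occurrence matrix.

    ``P`` is g x g with non-negative entries summing to 1; ``symmetric``
    means each pixel pair was counted in both orders, so P equals its
    transpose.
    """

    P: np.ndarray
    levels: int
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool


def quantize_heights(window: LandscapeWindow, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Linearly bin heights into ``levels`` grey levels over the window's
    observed min-max range.

    Returns an integer grid in [0, levels-1] with -1 marking invalid
    (nodata / outside-buffer) cells.  A constant window maps to all level 0.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    valid = window.valid
    if not valid.any():
        raise ValueError("empty window: no valid cells to quantize")
    v = window.values
    vmin = v[valid].min()
    vmax = v[valid].max()
    out = np.full(v.shape, -1, dtype=np.int32)
    if vmax == vmin:
        out[valid] = 0
        return out
    q = np.floor((v[valid] - vmin) / (vmax - vmin) * levels).astype(np.int32)
    out[valid] = np.minimum(q, levels - 1)
    return out


def compute_glcm(
    grid: np.ndarray,
    levels: int | None = None,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    symmetric: bool = True,
) -> GLCM:
    """Build a pooled co-occurrence matrix from a quantized grid.

    Counts are accumulated over every in-bounds pair of valid cells
    (value >= 0) for each offset; offsets are pooled by summing counts
    before normalizing.  Symmetric mode counts each pair in both orders.

    Raises
    ------
    ValueError
        If no offset yields a single valid pair.
    """
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    g = int(levels) if levels is not None else int(grid.max()) + 1
    if g < 1:
        raise ValueError("grid holds no valid levels")
    counts = np.zeros((g, g), dtype=np.float64)
    nr, nc = grid.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = grid[r0:r1, c0:c1]
        b = grid[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        sel = (a >= 0) & (b >= 0)
        if not sel.any():
            continue
        flat = a[sel].astype(np.int64) * g + b[sel]
        counts += np.bincount(flat, minlength=g * g).reshape(g, g)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs for any offset")
    return GLCM(counts / total, g, tuple(offsets), symmetric)


def texture_stats(glcm: GLCM) -> dict[str, float]:
    """The five co-occurrence statistics of metric set D.

    entropy = -sum P ln P (0 ln 0 := 0); contrast = sum (i-j)^2 P;
    ASM = sum P^2; homogeneity = sum P / (1 + (i-j)^2);
    dissimilarity = sum |i-j| P.
    """
    P = glcm.P
    if not np.isclose(P.sum(), 1.0, atol=1e-9):
        raise ValueError("GLCM is not normalized")
    i, j = np.indices(P.shape)
    diff = (i - j).astype(np.float64)
    nz = P > 0
    entropy = float(-(P[nz] * np.log(P[nz])).sum())
    return {
        "entropy": entropy,
        "contrast": float((diff**2 * P).sum()),
        "ASM": float((P**2).sum()),
        "homogeneity": float((P / (1.0 + diff**2)).sum()),
        "dissimilarity": float((np.abs(diff) * P).sum()),
    }
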