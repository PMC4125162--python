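"""Habitat metric sets for one landscape window.

Four families, 26 metrics total:

* **A** — summary height statistics over vegetated cells.
* **B** — traditional patch metrics on the binary vegetated / non-vegetated
  map.
* **C** — the same patch framework applied to height-class patches, plus
  contrast-weighted edge density, per-patch edge contrast and Shannon class
  diversity.
* **D** — co-occurrence texture statistics (see :mod:`heightscape.texture`).

Definitions follow the FRAGSTATS conventions: population (not sample)
standard deviations, patch areas in hectares, edge densities in m/ha and
FRAC = 2 ln(0.25 P) / ln(A) with perimeter P in meters and area A in m^2
(exactly 1 for a square patch).  The landscape area used by densities is
the area of valid (non-nodata) cells in the buffer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segmentation import (
    DEFAULT_THRESHOLDS,
    EdgeTable,
    LandscapeWindow,
    PatchMap,
    binary_class_map,
    build_edge_table,
    classify_height,
    default_contrast_matrix,
    label_patches,
)
from .texture import DEFAULT_LEVELS, DEFAULT_OFFSETS, compute_glcm, quantize_heights, texture_stats

SET_A: tuple[str, ...] = ("MEAN", "SD", "MIN", "MAX")
SET_B: tuple[str, ...] = (
    "B.NP", "B.AREA.MN", "B.AREA.SD", "B.ED", "B.TE", "B.FRAC.MN", "B.FRAC.SD",
)
SET_C: tuple[str, ...] = (
    "C.NP", "C.AREA.MN", "C.AREA.SD", "C.TE", "C.FRAC.MN", "C.FRAC.SD",
    "C.CWED", "C.ECON.MN", "C.ECON.SD", "C.SHDI",
)
SET_D: tuple[str, ...] = ("entropy", "contrast", "ASM", "homogeneity", "dissimilarity")

#: All 26 metric names in canonical order.
METRIC_NAMES: tuple[str, ...] = SET_A + SET_B + SET_C + SET_D

METRIC_SETS: dict[str, tuple[str, ...]] = {
    "A": SET_A, "B": SET_B, "C": SET_C, "D": SET_D,
}


def summary_stats(window: LandscapeWindow) -> dict[str, float]:
    """Set A: mean, population SD, min and max height over vegetated cells.

    Vegetated means height > 0 and valid; with no vegetated cell all four
    come back NaN (flagged missing).
    """
    veg = window.valid & (window.values > 0)
    if not veg.any():
        return {k: float("nan") for k in SET_A}
    h = window.values[veg]
    return {
        "MEAN": float(h.mean()),
        "SD": float(h.std()),  # population SD
        "MIN": float(h.min()),
        "MAX": float(h.max()),
    }


def _frac(perimeter_m: np.ndarray, area_m2: np.ndarray) -> np.ndarray:
    return 2.0 * np.log(0.25 * perimeter_m) / np.log(area_m2)


def _mn_sd(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x))


def _background_edge_length(patch_map: PatchMap) -> float:
    """Total length of faces between vegetated and background valid cells."""
    cls = patch_map.classes
    valid = patch_map.valid
    total = 0
    for axis in (0, 1):
        a = cls[:, :-1] if axis else cls[:-1, :]
        b = cls[:, 1:] if axis else cls[1:, :]
        va = valid[:, :-1] if axis else valid[:-1, :]
        vb = valid[:, 1:] if axis else valid[1:, :]
        total += int((va & vb & ((a > 0) != (b > 0))).sum())
    return total * patch_map.cell_size


def patch_metrics_2d(binary_patch_map: PatchMap) -> dict[str, float]:
    """Set B on the binary vegetation patch map.

    B.TE is the total vegetated/background edge; window-boundary and nodata
    faces are not edges, so a fully vegetated window has B.TE = 0.
    """
    pm = binary_patch_map
    n = pm.n_patches
    out = {k: float("nan") for k in SET_B}
    out["B.NP"] = float(n)
    if n == 0:
        return out
    area_ha = pm.patches["area_m2"].to_numpy() / 1e4
    out["B.AREA.MN"], out["B.AREA.SD"] = _mn_sd(area_ha)
    te = _background_edge_length(pm)
    out["B.TE"] = te
    landscape_ha = pm.valid.sum() * pm.cell_size**2 / 1e4
    out["B.ED"] = te / landscape_ha if landscape_ha > 0 else float("nan")
    frac = _frac(pm.patches["perimeter_m"].to_numpy(), pm.patches["area_m2"].to_numpy())
    out["B.FRAC.MN"], out["B.FRAC.SD"] = _mn_sd(frac)
    return out


def _patch_edge_contrast(patch_map: PatchMap, contrast: np.ndarray) -> np.ndarray:
    """Length-weighted mean depth of each patch's boundary edges (ECON).

    Boundary = faces to a valid cell of a different class (background faces
    carry depth from the contrast matrix, 1.0 by default).  Patches whose
    perimeter is entirely window boundary / nodata have no edge and return
    NaN.
    """
    labels = patch_map.labels
    cls = patch_map.classes
    valid = patch_map.valid
    n = patch_map.n_patches
    length = np.zeros(n + 1)
    weighted = np.zeros(n + 1)
    for axis in (0, 1):
        la = labels[:, :-1] if axis else labels[:-1, :]
        lb = labels[:, 1:] if axis else labels[1:, :]
        ca = cls[:, :-1] if axis else cls[:-1, :]
        cb = cls[:, 1:] if axis else cls[1:, :]
        va = valid[:, :-1] if axis else valid[:-1, :]
        vb = valid[:, 1:] if axis else valid[1:, :]
        sel = va & vb & (ca != cb)
        if not sel.any():
            continue
        d = contrast[ca[sel], cb[sel]]
        for side_lab in (la[sel], lb[sel]):
            keep = side_lab > 0
            np.add.at(length, side_lab[keep], 1.0)
            np.add.at(weighted, side_lab[keep], d[keep])
    with np.errstate(invalid="ignore", divide="ignore"):
        econ = weighted[1:] / length[1:]
    econ[length[1:] == 0] = np.nan
    return econ


def patch_metrics_height(
    patch_map: PatchMap,
    edges: EdgeTable,
    landscape_area_m2: float | None = None,
) -> dict[str, float]:
    """Set C on the height-class patch map.

    C.CWED = (sum over edge types of length x depth) / landscape area,
    scaled to m/ha.  C.SHDI uses vegetated-class area proportions only.
    ECON statistics skip edge-less patches.
    """
    pm = patch_map
    if landscape_area_m2 is None:
        landscape_area_m2 = float(pm.valid.sum()) * pm.cell_size**2
    n = pm.n_patches
    out = {k: float("nan") for k in SET_C}
    out["C.NP"] = float(n)
    if n == 0:
        return out
    area_m2 = pm.patches["area_m2"].to_numpy()
    out["C.AREA.MN"], out["C.AREA.SD"] = _mn_sd(area_m2 / 1e4)
    out["C.TE"] = edges.total_length
    frac = _frac(pm.patches["perimeter_m"].to_numpy(), area_m2)
    out["C.FRAC.MN"], out["C.FRAC.SD"] = _mn_sd(frac)
    out["C.CWED"] = edges.weighted_length / landscape_area_m2 * 1e4
    econ = _patch_edge_contrast(pm, edges.contrast)
    econ = econ[~np.isnan(econ)]
    if econ.size:
        out["C.ECON.MN"], out["C.ECON.SD"] = _mn_sd(econ)
    veg_area = pm.patches.groupby("class_index")["area_m2"].sum().to_numpy()
    p = veg_area / veg_area.sum()
    out["C.SHDI"] = float(-(p * np.log(p)).sum())
    return out


def compute_all_metrics(
    window: LandscapeWindow,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    contrast: np.ndarray | None = None,
    connectivity: int = 8,
    glcm_levels: int = DEFAULT_LEVELS,
    glcm_offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
) -> dict[str, float]:
    """Compute the full 26-metric vector for one landscape window."""
    out: dict[str, float] = {}
    out.update(summary_stats(window))

    bin_pm = label_patches(binary_class_map(window), connectivity)
    out.update(patch_metrics_2d(bin_pm))

    hcm = classify_height(window, thresholds)
    if contrast is None:
        contrast = default_contrast_matrix(hcm.thresholds)
    pm = label_patches(hcm, connectivity)
    edges = build_edge_table(pm, contrast, include_background_edges=True)
    out.update(patch_metrics_height(pm, edges, window.area_m2))

    if window.valid.any():
        grid = quantize_heights(window, glcm_levels)
        try:
            glcm = compute_glcm(grid, glcm_levels, glcm_offsets, symmetric=True)
            out.update(texture_stats(glcm))
        except ValueError:
            out.update({k: float("nan") for k in SET_D})
    else:
        out.update({k: float("nan") for k in SET_D})

    assert set(out) == set(METRIC_NAMES) and len(out) == 26
    return {k: out[k] for k in METRIC_NAMES}


def metrics_frame(rows: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Stack per-route metric dicts into a route_id-indexed DataFrame."""
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "route_id"
    return df[list(METRIC_NAMES)]
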