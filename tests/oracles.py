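"""Independent brute-force reference implementations used by the tests.

Everything here is written as naive per-cell loops, deliberately sharing no
code with the package, so the two routes can disagree.
"""

from __future__ import annotations

import math

import numpy as np


def flood_fill_label(classes: np.ndarray, valid: np.ndarray, connectivity: int = 8):
    """Connected components of same-class vegetated cells via BFS flood fill.

    Returns (labels, n) with labels 0 for background/invalid.
    """
    nr, nc = classes.shape
    labels = np.zeros((nr, nc), dtype=int)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    nxt = 0
    for r in range(nr):
        for c in range(nc):
            if labels[r, c] or classes[r, c] == 0 or not valid[r, c]:
                continue
            nxt += 1
            stack = [(r, c)]
            labels[r, c] = nxt
            while stack:
                rr, cc = stack.pop()
                for dr, dc in nbrs:
                    r2, c2 = rr + dr, cc + dc
                    if 0 <= r2 < nr and 0 <= c2 < nc and not labels[r2, c2]:
                        if valid[r2, c2] and classes[r2, c2] == classes[rr, cc]:
                            labels[r2, c2] = nxt
                            stack.append((r2, c2))
    return labels, nxt


def enumerate_edges(classes: np.ndarray, valid: np.ndarray, cell: float):
    """Dict {(i, j): length} over unordered differing-class valid 4-adjacent
    pairs (i < j)."""
    nr, nc = classes.shape
    out: dict[tuple[int, int], float] = {}
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c]:
                continue
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 >= nr or c2 >= nc or not valid[r2, c2]:
                    continue
                a, b = classes[r, c], classes[r2, c2]
                if a == b:
                    continue
                key = (min(a, b), max(a, b))
                out[key] = out.get(key, 0.0) + cell
    return out


def patch_perimeter(labels: np.ndarray, pid: int, cell: float) -> float:
    """Exposed faces of one patch, counting grid boundary and any
    different-label neighbor."""
    nr, nc = labels.shape
    total = 0
    for r in range(nr):
        for c in range(nc):
            if labels[r, c] != pid:
                continue
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < nr and 0 <= c2 < nc) or labels[r2, c2] != pid:
                    total += 1
    return total * cell


def brute_patch_metrics(classes, valid, cell, prefix, contrast=None):
    """Naive recomputation of the shared patch statistics (NP, AREA, TE,
    FRAC, plus CWED/ECON/SHDI when a contrast matrix is given)."""
    labels, n = flood_fill_label(classes, valid, connectivity=8)
    out = {f"{prefix}.NP": float(n)}
    if n == 0:
        return out
    areas, perims, pclass = [], [], []
    for pid in range(1, n + 1):
        cells = int((labels == pid).sum())
        areas.append(cells * cell * cell)
        perims.append(patch_perimeter(labels, pid, cell))
        pclass.append(int(classes[labels == pid][0]))
    areas = np.array(areas)
    perims = np.array(perims)
    out[f"{prefix}.AREA.MN"] = float(np.mean(areas / 1e4))
    out[f"{prefix}.AREA.SD"] = float(np.std(areas / 1e4))
    fracs = 2 * np.log(0.25 * perims) / np.log(areas)
    out[f"{prefix}.FRAC.MN"] = float(np.mean(fracs))
    out[f"{prefix}.FRAC.SD"] = float(np.std(fracs))
    edges = enumerate_edges(classes, valid, cell)
    if prefix == "B":
        te = sum(v for (i, j), v in edges.items() if i == 0 or j == 0)
        out["B.TE"] = te
        out["B.ED"] = te / (valid.sum() * cell * cell / 1e4)
    else:
        out["C.TE"] = sum(edges.values())
        if contrast is not None:
            area = valid.sum() * cell * cell
            out["C.CWED"] = (
                sum(v * contrast[i, j] for (i, j), v in edges.items()) / area * 1e4
            )
            # per-patch length-weighted mean boundary depth
            econs = []
            nr, nc = classes.shape
            for pid in range(1, n + 1):
                ln = wt = 0.0
                for r in range(nr):
                    for c in range(nc):
                        if labels[r, c] != pid:
                            continue
                        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                            r2, c2 = r + dr, c + dc
                            if not (0 <= r2 < nr and 0 <= c2 < nc):
                                continue
                            if not valid[r2, c2]:
                                continue
                            if classes[r2, c2] != classes[r, c]:
                                ln += cell
                                wt += cell * contrast[classes[r, c], classes[r2, c2]]
                if ln > 0:
                    econs.append(wt / ln)
            if econs:
                out["C.ECON.MN"] = float(np.mean(econs))
                out["C.ECON.SD"] = float(np.std(econs))
        class_area: dict[int, float] = {}
        for a, pc in zip(areas, pclass):
            class_area[pc] = class_area.get(pc, 0.0) + a
        tot = sum(class_area.values())
        out["C.SHDI"] = -sum(
            (a / tot) * math.log(a / tot) for a in class_area.values()
        )
    return out


def brute_glcm(grid: np.ndarray, levels: int, offsets, symmetric: bool) -> np.ndarray:
    """Exhaustive double-loop co-occurrence counting."""
    nr, nc = grid.shape
    counts = np.zeros((levels, levels))
    for dr, dc in offsets:
        for r in range(nr):
            for c in range(nc):
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < nr and 0 <= c2 < nc):
                    continue
                a, b = grid[r, c], grid[r2, c2]
                if a < 0 or b < 0:
                    continue
                counts[a, b] += 1
                if symmetric:
                    counts[b, a] += 1
    return counts / counts.sum()


def brute_texture(P: np.ndarray) -> dict[str, float]:
    g = P.shape[0]
    ent = con = asm = hom = dis = 0.0
    for i in range(g):
        for j in range(g):
            p = P[i, j]
            if p > 0:
                ent -= p * math.log(p)
            con += (i - j) ** 2 * p
            asm += p * p
            hom += p / (1 + (i - j) ** 2)
            dis += abs(i - j) * p
    return {
        "entropy": ent, "contrast": con, "ASM": asm,
        "homogeneity": hom, "dissimilarity": dis,
    }


def morans_i(values: np.ndarray) -> float:
    """Moran's I with rook (4-neighbor) binary weights, direct formula."""
    x = values.astype(float)
    n = x.size
    xbar = x.mean()
    dev = x - xbar
    num = 0.0
    w = 0
    nr, nc = x.shape
    for r in range(nr):
        for c in range(nc):
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 < nr and c2 < nc:
                    num += 2 * dev[r, c] * dev[r2, c2]
                    w += 2
    den = (dev**2).sum()
    return (n / w) * (num / den)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Covariance-formula correlation, no numpy.corrcoef."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xd = x - x.mean()
    yd = y - y.mean()
    return float((xd * yd).sum() / math.sqrt((xd**2).sum() * (yd**2).sum()))
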