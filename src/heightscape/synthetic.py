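"""Synthetic height rasters and stop-level survey detections.

The generators mirror the statistical structure the downstream analysis
assumes: height fields with controllable spatial autocorrelation and
clustering of tall pixels, and route-level detection tables whose true
richness is a linear function of standardized habitat metrics with
species-specific per-occasion detection probabilities.

The height field is built as a thresholded, rescaled Gaussian random field
(convolution method); clustering is imposed by rank-reordering the drawn
heights onto a second smoothed field, which changes the spatial arrangement
of tall pixels while leaving the marginal height distribution untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .habitat_metrics import METRIC_NAMES
from .raster import HeightRaster

GUILDS: tuple[str, ...] = ("woodland", "forest_edge", "interior_forest")


@dataclass
class SyntheticLandscapeConfig:
    grid_rows: int = 64
    grid_cols: int = 64
    cell_size: float = 30.0
    veg_fraction: float = 0.6
    height_mean: float = 15.0
    height_sd: float = 5.0
    autocorr_range: float = 90.0
    clustering: float = 2.0
    nodata_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ValueError("grid dimensions must be >= 8")
        for name in ("veg_fraction", "nodata_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.veg_fraction + self.nodata_fraction > 1.0:
            raise ValueError("veg_fraction + nodata_fraction must be <= 1")
        if self.autocorr_range < 0:
            raise ValueError("autocorr_range must be >= 0")
        if self.clustering < 0:
            raise ValueError("clustering must be >= 0")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")


@dataclass
class SyntheticSurveyConfig:
    n_routes: int = 50
    n_stops: int = 50
    n_species_pool: int = 120
    years: tuple[int, ...] = (1998, 1999, 2000, 2001, 2002)
    detect_prob_range: tuple[float, float] = (0.3, 0.9)
    route_detect_range: tuple[float, float] = (1.0, 1.0)
    effect_metrics: tuple[str, ...] = ()
    effect_sizes: tuple[float, ...] = ()
    noise_sd: float = 2.0
    richness_intercept: float | None = None
    first_year_observer_rate: float = 0.1
    unacceptable_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stops < 2:
            raise ValueError("n_stops must be >= 2")
        unknown = set(self.effect_metrics) - set(METRIC_NAMES)
        if unknown:
            raise ValueError(f"unknown effect metrics: {sorted(unknown)}")
        if len(self.effect_metrics) != len(self.effect_sizes):
            raise ValueError("effect_metrics and effect_sizes lengths differ")
        lo, hi = self.detect_prob_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("detect_prob_range must lie within (0, 1]")
        rlo, rhi = self.route_detect_range
        if not (0.0 < rlo <= rhi <= 1.0):
            raise ValueError("route_detect_range must lie within (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("first_year_observer_rate", "unacceptable_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SurveyData:
    """Bundle returned by :func:`gen_survey_table`.

    ``table`` holds one row per detection event (route_id, year,
    observer_id, first_year_flag, acceptable_flag, species_id,
    occasion_index, detected); ``true_richness`` and ``detect_probs`` carry
    the generating truth for parameter-recovery tests; ``guilds`` maps
    species to overlapping guild pools.
    """

    table: pd.DataFrame
    true_richness: pd.DataFrame
    detect_probs: pd.Series
    guilds: pd.DataFrame


def gen_height_raster(config: SyntheticLandscapeConfig) -> HeightRaster:
    """Generate one synthetic canopy-height raster.

    Deterministic under a fixed config (seed included): two calls yield
    bitwise-identical rasters.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_rows, config.grid_cols)
    n = shape[0] * shape[1]

    sigma = config.autocorr_range / config.cell_size
    base = rng.standard_normal(shape)
    fld = ndimage.gaussian_filter(base, sigma, mode="wrap") if sigma > 0 else base

    n_veg = int(round(config.veg_fraction * n))
    order = np.argsort(fld, axis=None)  # ascending; veg = top-ranked cells
    veg_flat = np.zeros(n, dtype=bool)
    if n_veg:
        veg_flat[order[-n_veg:]] = True

    heights = np.zeros(n)
    if n_veg:
        draws = rng.normal(config.height_mean, config.height_sd, size=n_veg)
        draws = np.clip(draws, 0.5, None)
        if config.clustering > 0:
            cfield = ndimage.gaussian_filter(
                rng.standard_normal(shape), config.clustering, mode="wrap"
            ).ravel()[veg_flat]
            rank = np.argsort(np.argsort(cfield))
            heights[veg_flat] = np.sort(draws)[rank]
        else:
            heights[veg_flat] = rng.permutation(draws)

    nodata_flat = np.zeros(n, dtype=bool)
    n_nodata = int(round(config.nodata_fraction * n))
    if n_nodata:
        candidates = np.flatnonzero(~veg_flat)
        pick = rng.choice(candidates, size=min(n_nodata, candidates.size), replace=False)
        nodata_flat[pick] = True

    return HeightRaster(
        values=heights.reshape(shape),
        nodata_mask=nodata_flat.reshape(shape),
        cell_size=config.cell_size,
        origin=(0.0, 0.0),
    )


def gen_route_landscapes(
    n_routes: int,
    base: SyntheticLandscapeConfig | None = None,
    seed: int = 0,
) -> list[HeightRaster]:
    """Generate one raster per route with jittered landscape parameters.

    Vegetation fraction, height spread, autocorrelation and clustering all
    vary between routes so the 26 metrics have real between-route variance
    to drive richness models.
    """
    if base is None:
        base = SyntheticLandscapeConfig()
    rng = np.random.default_rng(seed)
    rasters = []
    for i in range(n_routes):
        veg = float(rng.uniform(0.25, 0.9))
        # variable nodata emulates buffers clipped at raster borders, which
        # also keeps edge density and total edge from being collinear
        nodata = float(rng.uniform(0.0, min(0.1, 1.0 - veg)))
        cfg = SyntheticLandscapeConfig(
            grid_rows=base.grid_rows,
            grid_cols=base.grid_cols,
            cell_size=base.cell_size,
            veg_fraction=veg,
            height_mean=float(rng.uniform(8.0, 25.0)),
            height_sd=float(rng.uniform(1.0, 8.0)),
            autocorr_range=float(rng.uniform(0.0, 5.0)) * base.cell_size,
            clustering=float(rng.uniform(0.0, 6.0)),
            nodata_fraction=nodata,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rasters.append(gen_height_raster(cfg))
    return rasters


def guild_assignments(n_species_pool: int) -> pd.DataFrame:
    """Three overlapping species pools (long table species_id, guild).

    The broad woodland pool covers every species; the forest-edge and
    interior pools are overlapping subsets, mirroring guilds with different
    habitat sensitivity.
    """
    sp = np.arange(n_species_pool)
    rows = [(int(s), "woodland") for s in sp]
    rows += [(int(s), "forest_edge") for s in sp[: int(0.45 * n_species_pool)]]
    rows += [
        (int(s), "interior_forest")
        for s in sp[int(0.35 * n_species_pool) : int(0.70 * n_species_pool)]
    ]
    return pd.DataFrame(rows, columns=["species_id", "guild"])


def gen_survey_table(
    config: SyntheticSurveyConfig, metrics_per_route: pd.DataFrame
) -> SurveyData:
    """Simulate stop-level detections for every route in the metrics table.

    True richness per route is ``round(intercept + sum(effect_size *
    standardized metric) + Normal(0, noise_sd))`` clipped to [1, pool size];
    the route's species set is fixed across years.  Each present species is
    detected at each occasion with its species-specific probability, scaled
    by an optional route-year detectability factor drawn from
    ``route_detect_range`` (observer skill / survey conditions); the
    first-year-observer and unacceptable flags are independent Bernoulli
    per route-year.  Only detection events are materialized as rows.
    """
    for m in config.effect_metrics:
        if m not in metrics_per_route.columns:
            raise ValueError(f"metric {m!r} missing from metrics table")
    rng = np.random.default_rng(config.seed)
    routes = metrics_per_route.index.to_numpy()
    n_routes = len(routes)

    z = np.zeros(n_routes)
    for name, beta in zip(config.effect_metrics, config.effect_sizes):
        col = metrics_per_route[name].to_numpy(dtype=float)
        sd = col.std()
        if sd > 0:
            z = z + beta * (col - col.mean()) / sd
    intercept = (
        config.richness_intercept
        if config.richness_intercept is not None
        else config.n_species_pool / 3.0
    )
    mu = intercept + z + rng.normal(0.0, config.noise_sd, size=n_routes)
    true_rich = np.clip(np.round(mu), 1, config.n_species_pool).astype(int)

    p_lo, p_hi = config.detect_prob_range
    detect_p = pd.Series(
        rng.uniform(p_lo, p_hi, size=config.n_species_pool),
        index=pd.RangeIndex(config.n_species_pool, name="species_id"),
        name="detect_prob",
    )

    frames = []
    for r_idx, route in enumerate(routes):
        present = rng.choice(config.n_species_pool, size=true_rich[r_idx], replace=False)
        p = detect_p.to_numpy()[present]
        for year in config.years:
            observer = f"obs-{route}-{year}"
            first = bool(rng.random() < config.first_year_observer_rate)
            acceptable = bool(rng.random() >= config.unacceptable_rate)
            # route-year detectability factor (observer skill, conditions)
            factor = rng.uniform(*config.route_detect_range)
            det = rng.random((present.size, config.n_stops)) < (p * factor)[:, None]
            sp_i, occ_i = np.nonzero(det)
            if sp_i.size == 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "route_id": route,
                        "year": year,
                        "observer_id": observer,
                        "first_year_flag": first,
                        "acceptable_flag": acceptable,
                        "species_id": present[sp_i],
                        "occasion_index": occ_i + 1,
                        "detected": True,
                    }
                )
            )
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "route_id", "year", "observer_id", "first_year_flag",
                "acceptable_flag", "species_id", "occasion_index", "detected",
            ]
        )
    )
    truth = pd.DataFrame({"route_id": routes, "true_richness": true_rich})
    return SurveyData(table, truth, detect_p, guild_assignments(config.n_species_pool))
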