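"""Survey filtering and first-order jackknife species richness.

The estimator treats a route-year as a closed community sampled on k
occasions (the survey stops, k = 50 by default):

    S_jack1 = S_obs + f1 * (k - 1) / k

with f1 the number of species detected in exactly one occasion.  Route
richness is the arithmetic mean of the available yearly estimates inside a
year window (1998-2002 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_YEARS: tuple[int, ...] = (1998, 1999, 2000, 2001, 2002)
DEFAULT_K = 50


@dataclass
class RichnessEstimate:
    route_id: object
    year: int
    s_obs: int
    f1: int
    k: int
    s_jack1: float
    guild: str = "all"


def filter_surveys(table: pd.DataFrame) -> pd.DataFrame:
    """Drop rows that are unacceptable or surveyed by a first-year observer."""
    keep = table["acceptable_flag"].astype(bool) & ~table["first_year_flag"].astype(bool)
    return table.loc[keep].copy()


def jackknife1(detections: np.ndarray, guild: str = "all",
               route_id: object = None, year: int = 0) -> RichnessEstimate:
    """First-order jackknife richness from a species x occasion boolean matrix.

    Raises
    ------
    ValueError
        If fewer than 2 occasions are available ("insufficient occasions").
    """
    det = np.asarray(detections, dtype=bool)
    if det.ndim != 2 or det.shape[1] < 2:
        raise ValueError("insufficient occasions: need a species x k matrix, k >= 2")
    k = det.shape[1]
    occ = det.sum(axis=1)
    s_obs = int((occ > 0).sum())
    f1 = int((occ == 1).sum())
    s_jack1 = s_obs + f1 * (k - 1) / k
    return RichnessEstimate(route_id, year, s_obs, f1, k, s_jack1, guild)


def estimate_richness(
    table: pd.DataFrame,
    k: int = DEFAULT_K,
    guilds: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per route-year (and guild) jackknife estimates from a detection table.

    ``table`` holds detection events (already filtered); ``guilds`` is an
    optional long table (species_id, guild) restricting the species set
    before estimation.  Rows: route_id, year, guild, s_obs, f1, k, s_jack1.
    """
    if k < 2:
        raise ValueError("insufficient occasions: k must be >= 2")
    det = table.loc[table["detected"].astype(bool)]
    if guilds is None:
        groups = [("all", det)]
    else:
        groups = [
            (g, det.merge(sub[["species_id"]], on="species_id"))
            for g, sub in guilds.groupby("guild")
        ]
    rows = []
    for guild, sub in groups:
        if sub.empty:
            continue
        occ = (
            sub.groupby(["route_id", "year", "species_id"])["occasion_index"]
            .nunique()
            .rename("n_occ")
            .reset_index()
        )
        agg = occ.groupby(["route_id", "year"]).agg(
            s_obs=("n_occ", "size"), f1=("n_occ", lambda s: int((s == 1).sum()))
        )
        for (route, year), rec in agg.iterrows():
            rows.append(
                {
                    "route_id": route,
                    "year": int(year),
                    "guild": guild,
                    "s_obs": int(rec["s_obs"]),
                    "f1": int(rec["f1"]),
                    "k": k,
                    "s_jack1": rec["s_obs"] + rec["f1"] * (k - 1) / k,
                }
            )
    return pd.DataFrame(rows)


def mean_richness(
    estimates: pd.DataFrame, years: tuple[int, ...] = DEFAULT_YEARS
) -> pd.DataFrame:
    """Average available yearly jackknife estimates per route and guild.

    Routes with no estimate inside the window are dropped with a warning.
    Returns route_id, guild, mean_richness, n_years.
    """
    sel = estimates.loc[estimates["year"].isin(years)]
    dropped = set(estimates["route_id"]) - set(sel["route_id"])
    if dropped:
        log.warning("dropping %d route(s) with no usable year", len(dropped))
    out = (
        sel.groupby(["route_id", "guild"])["s_jack1"]
        .agg(mean_richness="mean", n_years="size")
        .reset_index()
    )
    return out


def route_richness(
    table: pd.DataFrame,
    k: int = DEFAULT_K,
    years: tuple[int, ...] = DEFAULT_YEARS,
    guilds: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Filter, estimate and average: the full richness stage in one call."""
    filtered = filter_surveys(table)
    estimates = estimate_richness(filtered, k=k, guilds=guilds)
    if estimates.empty:
        return pd.DataFrame(columns=["route_id", "guild", "mean_richness", "n_years"])
    return mean_richness(estimates, years=years)
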