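"""Pipeline orchestration: simulate -> buffers -> metrics -> richness -> models.

Every stage writes CSV outputs plus a provenance JSON (config hash, seed,
library versions) into the run directory, and is skipped on re-run when its
outputs already exist (set ``force=True`` to recompute).  With a fixed seed
a run is idempotent: outputs are byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .habitat_metrics import compute_all_metrics, metrics_frame
from .raster import HeightRaster
from .richness import DEFAULT_K, DEFAULT_YEARS, route_richness
from .segmentation import DEFAULT_THRESHOLDS, LandscapeWindow, extract_buffer
from .synthetic import (
    SyntheticLandscapeConfig,
    SyntheticSurveyConfig,
    gen_route_landscapes,
    gen_survey_table,
)
from .modeling import DEFAULT_N_BOOT, DEFAULT_N_TREES, run_model_suite

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run settings; defaults follow the survey/analysis protocol constants
    (19 km buffers, 50 stops, years 1998-2002, 3000 bootstrap replicates,
    2000 trees)."""

    output_dir: str = "runs/demo"
    raster_dir: str | None = None
    survey_csv: str | None = None
    centroids_csv: str | None = None
    simulate: bool = True
    n_routes: int = 60
    buffer_radius: float = 19_000.0
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    glcm_levels: int = 32
    jackknife_k: int = DEFAULT_K
    years: tuple[int, ...] = DEFAULT_YEARS
    n_boot: int = DEFAULT_N_BOOT
    n_trees: int = DEFAULT_N_TREES
    seed: int = 0
    landscape: SyntheticLandscapeConfig = field(default_factory=SyntheticLandscapeConfig)
    survey: SyntheticSurveyConfig = field(default_factory=SyntheticSurveyConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "landscape" in kwargs and isinstance(kwargs["landscape"], dict):
            kwargs["landscape"] = SyntheticLandscapeConfig(**kwargs["landscape"])
        if "survey" in kwargs and isinstance(kwargs["survey"], dict):
            kwargs["survey"] = SyntheticSurveyConfig(**kwargs["survey"])
        for key in ("thresholds", "years"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_provenance(path: Path, cfg: PipelineConfig, stage: str) -> None:
    import sklearn

    prov = {
        "stage": stage,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "versions": {
            "heightscape": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "protocol": {
            "buffer_radius_m": cfg.buffer_radius,
            "n_boot": cfg.n_boot,
            "n_trees": cfg.n_trees,
            "years": list(cfg.years),
            "jackknife_k": cfg.jackknife_k,
        },
    }
    path.write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")


# ----------------------------------------------------------------------
def simulate_stage(cfg: PipelineConfig, outdir: Path, force: bool = False) -> None:
    """Generate per-route rasters, centroids CSV (placeholder, simulated
    rasters are analyzed whole) and later the survey table."""
    rdir = outdir / "rasters"
    if rdir.exists() and not force:
        log.info("simulate: cached")
        return
    rdir.mkdir(parents=True, exist_ok=True)
    rasters = gen_route_landscapes(cfg.n_routes, cfg.landscape, seed=cfg.seed)
    rows = []
    for i, r in enumerate(rasters):
        route = f"route-{i:04d}"
        r.to_ascii(rdir / f"{route}.asc")
        cx, cy = r.center()
        rows.append({"route_id": route, "x": cx, "y": cy})
    pd.DataFrame(rows).to_csv(outdir / "centroids.csv", index=False)
    _write_provenance(outdir / "simulate.provenance.json", cfg, "simulate")


def metrics_stage(cfg: PipelineConfig, outdir: Path, force: bool = False) -> pd.DataFrame:
    """Extract buffers around each centroid and compute the 26 metrics."""
    out_csv = outdir / "metrics.csv"
    if out_csv.exists() and not force:
        log.info("metrics: cached")
        return pd.read_csv(out_csv, index_col="route_id")
    rdir = Path(cfg.raster_dir) if cfg.raster_dir else outdir / "rasters"
    cen_csv = Path(cfg.centroids_csv) if cfg.centroids_csv else outdir / "centroids.csv"
    centroids = pd.read_csv(cen_csv)
    rows: dict[str, dict[str, float]] = {}
    for rec in centroids.itertuples(index=False):
        raster = HeightRaster.from_ascii(rdir / f"{rec.route_id}.asc")
        try:
            window = extract_buffer(raster, (rec.x, rec.y), cfg.buffer_radius)
        except ValueError:
            log.warning("route %s: buffer outside raster, skipped", rec.route_id)
            continue
        rows[rec.route_id] = compute_all_metrics(
            window, thresholds=cfg.thresholds, glcm_levels=cfg.glcm_levels
        )
    df = metrics_frame(rows)
    df.to_csv(out_csv, float_format="%.10g")
    _write_provenance(outdir / "metrics.provenance.json", cfg, "metrics")
    # return the persisted representation so cached and cold runs feed
    # downstream stages identical inputs
    return pd.read_csv(out_csv, index_col="route_id")


def survey_stage(cfg: PipelineConfig, outdir: Path, metrics: pd.DataFrame,
                 force: bool = False) -> pd.DataFrame:
    """Simulate the stop-level survey table driven by the computed metrics."""
    out_csv = outdir / "survey.csv"
    if out_csv.exists() and not force:
        log.info("survey: cached")
        return pd.read_csv(out_csv)
    survey_cfg = dataclasses.replace(
        cfg.survey, n_routes=len(metrics), n_stops=cfg.jackknife_k,
        years=cfg.years, seed=cfg.seed + 1,
    )
    data = gen_survey_table(survey_cfg, metrics)
    data.table.to_csv(out_csv, index=False)
    data.true_richness.to_csv(outdir / "true_richness.csv", index=False)
    data.guilds.to_csv(outdir / "guilds.csv", index=False)
    _write_provenance(outdir / "survey.provenance.json", cfg, "survey")
    return pd.read_csv(out_csv)


def richness_stage(cfg: PipelineConfig, outdir: Path, survey: pd.DataFrame,
                   force: bool = False) -> pd.DataFrame:
    out_csv = outdir / "richness.csv"
    if out_csv.exists() and not force:
        log.info("richness: cached")
        return pd.read_csv(out_csv)
    guilds_csv = outdir / "guilds.csv"
    guilds = pd.read_csv(guilds_csv) if guilds_csv.exists() else None
    rich = route_richness(survey, k=cfg.jackknife_k, years=cfg.years, guilds=guilds)
    rich.to_csv(out_csv, index=False)
    _write_provenance(outdir / "richness.provenance.json", cfg, "richness")
    return pd.read_csv(out_csv)


def model_stage(cfg: PipelineConfig, outdir: Path, metrics: pd.DataFrame,
                rich: pd.DataFrame, force: bool = False) -> pd.DataFrame:
    out_csv = outdir / "models.csv"
    if out_csv.exists() and not force:
        log.info("models: cached")
        return pd.read_csv(out_csv)
    suite = run_model_suite(metrics, rich, n_boot=cfg.n_boot, n_trees=cfg.n_trees, seed=cfg.seed)
    suite.results.to_csv(out_csv, index=False, float_format="%.10g")
    suite.correlations.to_csv(outdir / "correlations.csv", float_format="%.10g")
    imp_rows = []
    for (guild, set_name), imp in suite.importances.items():
        for metric, val in imp.items():
            imp_rows.append(
                {"guild": guild, "predictor_set": set_name, "metric": metric,
                 "pct_inc_mse": val}
            )
    pd.DataFrame(imp_rows).to_csv(outdir / "importance.csv", index=False, float_format="%.10g")
    (outdir / "bphm.json").write_text(json.dumps({"bphm": suite.bphm}, indent=2) + "\n")
    _write_provenance(outdir / "models.provenance.json", cfg, "models")
    return suite.results


def run_pipeline(cfg: PipelineConfig, force: bool = False) -> Path:
    """Execute all stages in order; returns the run directory."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.simulate:
        simulate_stage(cfg, outdir, force)
    metrics = metrics_stage(cfg, outdir, force)
    if cfg.simulate:
        survey = survey_stage(cfg, outdir, metrics, force)
    else:
        if cfg.survey_csv is None:
            raise ValueError("survey_csv required when simulate is off")
        survey = pd.read_csv(cfg.survey_csv)
    rich = richness_stage(cfg, outdir, survey, force)
    model_stage(cfg, outdir, metrics, rich, force)
    return outdir
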