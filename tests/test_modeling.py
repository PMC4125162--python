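import numpy as np
import pandas as pd
import pytest

from heightscape.habitat_metrics import METRIC_NAMES, SET_C, SET_D
from heightscape.modeling import (
    LINEAR_SETS,
    RF_SETS,
    bootstrap_bca,
    correlate,
    fit_linear,
    fit_rf,
    predictor_names,
    run_model_suite,
    select_bphm,
)

from .oracles import pearson


def metric_table(rng, n):
    df = pd.DataFrame(
        rng.normal(0, 1, (n, len(METRIC_NAMES))), columns=METRIC_NAMES
    )
    df.index = [f"r{i}" for i in range(n)]
    df.index.name = "route_id"
    return df


def richness_table(routes, values, guild="woodland"):
    return pd.DataFrame(
        {"route_id": routes, "guild": guild, "mean_richness": values}
    )


# ----------------------------------------------------------- correlation
def test_perfect_linearity_r_one(rng):
    m = metric_table(rng, 50)
    rich = richness_table(m.index, 2 * m["MEAN"].to_numpy())
    corr = correlate(m, rich)
    assert corr.loc["MEAN", "woodland"] == pytest.approx(1.0)


def test_correlation_matches_covariance_oracle(rng):
    m = metric_table(rng, 80)
    rich = richness_table(m.index, rng.normal(0, 1, 80))
    corr = correlate(m, rich)
    y = rich.set_index("route_id").loc[m.index, "mean_richness"].to_numpy()
    for name in ("SD", "C.CWED", "entropy"):
        assert corr.loc[name, "woodland"] == pytest.approx(
            pearson(m[name].to_numpy(), y)
        )


def test_null_metric_correlation_inside_null_band(rng):
    n = 500
    m = metric_table(rng, n)
    rich = richness_table(m.index, rng.normal(0, 1, n))
    corr = correlate(m, rich)
    # |r| < 3/sqrt(n) holds for ~99% of independent draws
    assert (corr["woodland"].abs() < 3 / np.sqrt(n)).mean() > 0.9


def test_zero_variance_metric_flagged_missing(rng):
    m = metric_table(rng, 30)
    m["MIN"] = 1.0
    rich = richness_table(m.index, rng.normal(0, 1, 30))
    assert np.isnan(correlate(m, rich).loc["MIN", "woodland"])


# ----------------------------------------------------------- BPHM
def _corr_frame(values):
    idx = list(SET_C) + list(SET_D)
    return pd.DataFrame(
        {g: [values.get(m, 0.1) for m in idx] for g in ("a", "b", "c")}, index=idx
    )


def test_bphm_selects_dominant_metrics():
    corr = _corr_frame({"C.TE": 0.9, "C.CWED": -0.8, "entropy": 0.85, "ASM": -0.7})
    assert set(select_bphm(corr)) == {"C.TE", "C.CWED", "entropy", "ASM"}


def test_bphm_tie_breaks_alphabetically(caplog):
    corr = _corr_frame({})  # everything equal
    import logging

    with caplog.at_level(logging.WARNING):
        picks = select_bphm(corr)
    c_sorted = sorted(SET_C)[:2]
    d_sorted = sorted(SET_D)[:2]
    assert picks == c_sorted + d_sorted
    assert any("tie" in r.message for r in caplog.records)


def test_bphm_invariant_to_guild_column_order():
    corr = _corr_frame({"C.TE": 0.9, "C.SHDI": 0.5, "entropy": 0.6, "contrast": 0.4})
    assert select_bphm(corr) == select_bphm(corr[["c", "a", "b"]])


def test_predictor_names_expansion():
    bphm = ["C.TE", "C.CWED", "entropy", "ASM"]
    assert predictor_names("A", bphm) == ["MEAN", "SD", "MIN", "MAX"]
    assert len(predictor_names("A+BPHM", bphm)) == 8
    assert len(predictor_names("ALL")) == 26
    # a BPHM already inside the base set is not duplicated
    assert predictor_names("C+BPHM", bphm).count("C.TE") == 1


# ----------------------------------------------------------- linear fits
def test_adj_r2_closed_form():
    # engineered fit with known R^2 = 0.5, n = 11, p = 1
    rng = np.random.default_rng(0)
    n = 11
    x = np.linspace(0, 1, n)
    fit = None
    # construct y with exactly R^2 = 0.5: signal + orthogonal residual scaled
    xc = x - x.mean()
    resid = rng.normal(0, 1, n)
    resid -= resid.mean()
    resid -= xc * (resid @ xc) / (xc @ xc)
    y = xc + resid * np.sqrt((xc @ xc) / (resid @ resid))
    data = pd.DataFrame({"x": x, "mean_richness": y})
    fit = fit_linear(data, ["x"])
    assert fit.r2 == pytest.approx(0.5)
    assert fit.adj_r2 == pytest.approx(1 - 0.5 * 10 / 9)


def test_aic_formula(rng):
    n = 40
    x = rng.normal(0, 1, n)
    y = 2 * x + rng.normal(0, 1, n)
    data = pd.DataFrame({"x": x, "mean_richness": y})
    fit = fit_linear(data, ["x"])
    design = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(((y - design @ beta) ** 2).sum())
    assert fit.aic == pytest.approx(n * np.log(rss / n) + 2 * 3)


def test_perfect_fit_rejected(rng):
    y = rng.normal(0, 1, 30)
    data = pd.DataFrame({"x": y, "mean_richness": y})
    with pytest.raises(ValueError, match="perfect fit"):
        fit_linear(data, ["x"])


def test_collinear_design_named(rng):
    x = rng.normal(0, 1, 30)
    data = pd.DataFrame(
        {"a": x, "b": 2 * x, "mean_richness": rng.normal(0, 1, 30)}
    )
    with pytest.raises(ValueError, match="collinear.*'a'.*'b'"):
        fit_linear(data, ["a", "b"])


def test_coefficient_recovery(rng):
    n = 500
    X = rng.normal(0, 1, (n, 3))
    beta = np.array([1.5, -2.0, 0.5])
    y = 4.0 + X @ beta + rng.normal(0, 1, n)
    data = pd.DataFrame(X, columns=["a", "b", "c"])
    data["mean_richness"] = y
    fit = fit_linear(data, ["a", "b", "c"])
    se = 1 / np.sqrt(n)
    assert np.allclose(fit.coefs[1:], beta, atol=3 * se)


def test_nested_fits_r2_monotone_adj_r2_not_necessarily(rng):
    n = 60
    X = rng.normal(0, 1, (n, 5))
    y = X[:, 0] + rng.normal(0, 1, n)
    data = pd.DataFrame(X, columns=list("abcde"))
    data["mean_richness"] = y
    small = fit_linear(data, ["a"])
    big = fit_linear(data, list("abcde"))
    assert big.r2 >= small.r2  # raw R^2 never drops with added predictors


# ----------------------------------------------------------- BCa bootstrap
def _mean_stat(frame):
    return {"m": float(frame["x"].mean())}


def test_constant_statistic_zero_width_interval(rng):
    data = pd.DataFrame({"x": np.full(25, 3.0)})
    ci = bootstrap_bca(data, _mean_stat, n_boot=200, seed=1)["m"]
    assert ci == (3.0, 3.0)


def test_bootstrap_deterministic_under_seed(rng):
    data = pd.DataFrame({"x": rng.normal(0, 1, 40)})
    a = bootstrap_bca(data, _mean_stat, n_boot=300, seed=5)
    b = bootstrap_bca(data, _mean_stat, n_boot=300, seed=5)
    assert a == b


def test_symmetric_case_close_to_percentile(rng):
    x = rng.normal(0, 1, 200)
    data = pd.DataFrame({"x": x})
    ci = bootstrap_bca(data, _mean_stat, n_boot=2000, seed=2)["m"]
    # plain percentile endpoints computed directly
    boots = np.array(
        [x[np.random.default_rng(100 + b).integers(0, 200, 200)].mean() for b in range(2000)]
    )
    lo, hi = np.quantile(boots, [0.025, 0.975])
    tol = 3 * x.std() / np.sqrt(200) * 0.2
    assert ci[0] == pytest.approx(lo, abs=tol)
    assert ci[1] == pytest.approx(hi, abs=tol)


def test_bca_matches_scipy_reference(rng):
    from scipy.stats import bootstrap as scipy_bootstrap

    x = rng.lognormal(0, 1, 60)
    data = pd.DataFrame({"x": x})
    ci = bootstrap_bca(data, _mean_stat, n_boot=4000, seed=3)["m"]
    ref = scipy_bootstrap(
        (x,), np.mean, n_resamples=4000, confidence_level=0.95,
        method="BCa", random_state=np.random.default_rng(4),
    ).confidence_interval
    mc_tol = 4 * x.std() / np.sqrt(60) * 0.15
    assert ci[0] == pytest.approx(ref.low, abs=mc_tol)
    assert ci[1] == pytest.approx(ref.high, abs=mc_tol)


def test_small_n_rejected(rng):
    with pytest.raises(ValueError):
        bootstrap_bca(pd.DataFrame({"x": np.arange(5.0)}), _mean_stat)


# ----------------------------------------------------------- random forest
def test_rf_pure_noise_explains_nothing(rng):
    n = 500
    data = metric_table(rng, n)
    data["mean_richness"] = rng.normal(0, 1, n)
    ff = fit_rf(data, list(METRIC_NAMES), n_trees=300, seed=1, compute_importance=False)
    assert ff.var_explained <= 0.05


def test_rf_planted_signal_tops_importance(rng):
    n = 300
    data = metric_table(rng, n)
    data["mean_richness"] = (
        3.0 * data["entropy"] + 2.0 * data["C.CWED"]
    )  # deterministic in 2 of 26 metrics
    ff = fit_rf(data, list(METRIC_NAMES), n_trees=300, seed=2)
    assert set(ff.importance.index[:2]) == {"entropy", "C.CWED"}
    assert ff.var_explained > 0.5


def test_rf_stability_across_seeds(rng):
    n = 500
    data = metric_table(rng, n)
    data["mean_richness"] = data["MEAN"] + rng.normal(0, 0.5, n)
    a = fit_rf(data, list(METRIC_NAMES), n_trees=2000, seed=1, compute_importance=False)
    b = fit_rf(data, list(METRIC_NAMES), n_trees=2000, seed=2, compute_importance=False)
    assert abs(a.var_explained - b.var_explained) < 0.03


def test_rf_warns_on_few_trees(rng):
    data = metric_table(rng, 50)
    data["mean_richness"] = rng.normal(0, 1, 50)
    with pytest.warns(RuntimeWarning, match="n_trees"):
        fit_rf(data, ["MEAN"], n_trees=50, seed=0, compute_importance=False)


# ----------------------------------------------------------- the suite
def test_suite_emits_6_linear_and_7_rf_rows_per_guild(rng):
    n = 60
    m = metric_table(rng, n)
    rich = pd.concat(
        [
            richness_table(m.index, m["MEAN"] + rng.normal(0, 1, n), "woodland"),
            richness_table(m.index, m["SD"] + rng.normal(0, 1, n), "forest_edge"),
        ]
    )
    suite = run_model_suite(m, rich, n_boot=100, n_trees=120, seed=0)
    counts = suite.results.groupby(["guild", "model"]).size()
    for g in ("woodland", "forest_edge"):
        assert counts[(g, "linear")] == len(LINEAR_SETS) == 6
        assert counts[(g, "rf")] == len(RF_SETS) == 7
    assert len(suite.bphm) == 4
    assert suite.correlations.shape == (26, 2)


def test_suite_reproducible_under_seed(rng):
    n = 40
    m = metric_table(rng, n)
    rich = richness_table(m.index, m["MEAN"] + rng.normal(0, 1, n))
    a = run_model_suite(m, rich, n_boot=80, n_trees=120, seed=9)
    b = run_model_suite(m, rich, n_boot=80, n_trees=120, seed=9)
    pd.testing.assert_frame_equal(a.results, b.results)


def test_suite_no_false_improvement_when_signal_is_set_a(rng):
    n = 150
    m = metric_table(rng, n)
    rich = richness_table(m.index, 3 * m["MEAN"] + rng.normal(0, 1, n))
    suite = run_model_suite(m, rich, n_boot=200, n_trees=120, seed=3)
    res = suite.results.set_index(["model", "predictor_set"])
    delta = (
        res.loc[("linear", "A+BPHM"), "adj_r2"] - res.loc[("linear", "A"), "adj_r2"]
    )
    width = res.loc[("linear", "A"), "adj_r2_hi"] - res.loc[("linear", "A"), "adj_r2_lo"]
    assert delta < width  # no improvement beyond CI width
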