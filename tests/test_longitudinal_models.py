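import logging

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from airway_turnover.core_data import SubjectSeries, build_subject_series
from airway_turnover.longitudinal_models import (
    JoinPointSpec,
    _ModelData,
    betabinom_logpmf,
    fit_betabin_joinpoint,
    fit_gee_lognormal,
    marginal_loglik_trapezoid,
    select_knot,
    zero_inflation_check,
)
from airway_turnover.synthetic_cohort import SyntheticCohortConfig, generate_cohort


# ---------------------------------------------------------------------------
# beta-binomial primitives
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n", [1, 5, 20])
@pytest.mark.parametrize("mu", [0.05, 0.3, 0.7])
@pytest.mark.parametrize("phi", [1e-12, 0.05, 0.5, 2.0])
def test_betabinom_pmf_sums_to_one(n, mu, phi):
    y = np.arange(n + 1)
    total = np.exp(betabinom_logpmf(y, n, mu, phi)).sum()
    assert total == pytest.approx(1.0, abs=1e-10)


def test_betabinom_small_phi_is_binomial():
    from scipy.stats import binom

    y, n, mu = 3, 10, 0.4
    assert betabinom_logpmf(y, n, mu, 1e-12) == pytest.approx(
        binom.logpmf(y, n, mu), abs=1e-8
    )


# ---------------------------------------------------------------------------
# knot selection
# ---------------------------------------------------------------------------


def _cubic_logit_data(coefs_poly):
    """Counts whose pooled logit RA follows the given polynomial exactly."""
    t = np.arange(1.0, 23.0)
    z = np.polyval(coefs_poly, t)
    p = expit(z)
    totals = np.full_like(t, 1e6)
    return t, p * totals, totals


def test_select_knot_noiseless_cubic_is_exact():
    # stationary (double) root exactly at t=10
    coefs = np.array([0.002, -0.06, 0.6, -2.0])  # 0.002 (t-10)^3 - 0 expanded
    t, y, n = _cubic_logit_data(np.array([0.002, 3 * 0.002 * -10, 3 * 0.002 * 100, -2.0]))
    sel = select_knot(t, y, n)
    assert sel.knot_day == pytest.approx(10.0, abs=1e-6)
    assert not sel.fallback


def test_select_knot_tie_break_prefers_root_near_median_day():
    # derivative proportional to (t-8)(t-16): stationary points at 8 and 16
    c = 0.004
    poly = np.array([c / 3, -12 * c, 128 * c, 0.0])
    poly[3] = -np.polyval(poly, 12.0)  # centre the logit range
    t, y, n = _cubic_logit_data(poly)
    sel = select_knot(t, y, n)  # median day 11.5 -> nearer root is 8
    assert sel.knot_day == pytest.approx(8.0, abs=1e-4)
    assert sorted(round(r) for r in sel.roots) == [8, 16]


def test_select_knot_monotone_input_falls_back(caplog):
    # derivative (t-10)^2 + 25 has no real roots
    poly = np.array([1 / 3, -10.0, 125.0, 0.0]) * 0.002
    poly[3] = -np.polyval(poly, 12.0)
    t, y, n = _cubic_logit_data(poly)
    with caplog.at_level(logging.WARNING):
        sel = select_knot(t, y, n, default=10.0)
    assert sel.fallback and sel.knot_day == 10.0
    assert "falling back" in caplog.text


def test_select_knot_needs_four_distinct_days():
    with pytest.raises(ValueError, match="4 distinct"):
        select_knot([1, 1, 2, 3], [1, 1, 1, 1], [10, 10, 10, 10])


# ---------------------------------------------------------------------------
# mixed-model quadrature and fitting
# ---------------------------------------------------------------------------


def _random_series(rng, n_subjects=4, groups=("a", "b")):
    series = []
    for i in range(n_subjects):
        k = int(rng.integers(2, 5))
        days = np.sort(rng.choice(np.arange(1, 24), size=k, replace=False))
        y = rng.integers(0, 200, size=k)
        other = rng.integers(50, 400, size=k)
        counts = np.column_stack([y, other])
        series.append(
            SubjectSeries(f"s{i}", groups[i % len(groups)], days, counts, ["T", "rest"])
        )
    return series


def test_quadrature_matches_dense_trapezoid():
    rng = np.random.default_rng(0)
    spec = JoinPointSpec("T", 10.0, groups=("a", "b"))
    for _ in range(5):
        series = _random_series(rng)
        theta = np.concatenate(
            [rng.normal(0, 1, 6) * [1, 0.1, 0.1, 1, 0.1, 0.1], [rng.uniform(0.2, 1.2)],
             rng.uniform(0.02, 0.5, 2)]
        )
        data = _ModelData(series, spec)
        agh = float(data.loglik_subjects(theta).sum())
        trap = marginal_loglik_trapezoid(series, spec, theta, grid_points=4001, grid_width=12)
        assert agh == pytest.approx(trap, rel=1e-6)


def test_binomial_limit_matches_plain_logistic_joinpoint():
    """With no overdispersion and no random effect in the data, the mixed
    model collapses to an ordinary logistic join-point regression."""
    rng = np.random.default_rng(3)
    series = []
    coef = {"a": (-2.0, 0.25, -0.2), "b": (-1.0, 0.1, -0.1)}
    for g in coef:
        for i in range(15):
            days = np.sort(rng.choice(np.arange(1, 24), size=3, replace=False))
            rows = []
            for t in days:
                mu = expit(coef[g][0] + coef[g][1] * t + coef[g][2] * max(t - 10, 0))
                n = 5000
                y = rng.binomial(n, mu)
                rows.append([y, n - y])
            series.append(SubjectSeries(f"{g}{i}", g, days, np.array(rows), ["T", "o"]))
    fit = fit_betabin_joinpoint(series, JoinPointSpec("T", 10.0), n_restarts=1)
    assert fit.sigma_b < 0.02
    for g in coef:
        sub = [s for s in series if s.group == g]
        y = np.concatenate([s.counts[:, 0] for s in sub])
        n = np.concatenate([s.counts.sum(axis=1) for s in sub])
        t = np.concatenate([s.days for s in sub]).astype(float)
        X = np.column_stack([np.ones_like(t), t, np.clip(t - 10, 0, None)])
        glm = sm.GLM(np.column_stack([y, n - y]), X, family=sm.families.Binomial()).fit()
        assert np.allclose(fit.coef[g], glm.params, atol=0.02)


def test_day14_contrast_detects_generated_group_difference():
    """Mild is generated with a higher staph curve at day 14 than severe; the
    fitted population contrast should be positive and significant."""
    table, meta, _ = generate_cohort(SyntheticCohortConfig(seed=8))
    series = build_subject_series(table, meta)
    fit = fit_betabin_joinpoint(series, JoinPointSpec("Staphylococcus", 10.0), n_restarts=1)
    c = fit.contrast_at_day(14.0, "mild", "severe", scale="ra")
    assert c["estimate"] > 0
    assert c["p"] < 0.05


# ---------------------------------------------------------------------------
# log-normal GEE
# ---------------------------------------------------------------------------


def test_gee_singleton_clusters_reduce_to_ols():
    rng = np.random.default_rng(5)
    groups = np.repeat(["a", "b", "c"], 30)
    values = np.exp(rng.normal(0, 1, 90) + (groups == "b") * 0.5)
    subjects = [f"s{i}" for i in range(90)]
    gee = fit_gee_lognormal(values, subjects, groups)
    X = pd.DataFrame(
        {"intercept": 1.0, "group_b": groups == "b", "group_c": groups == "c"}
    ).astype(float)
    ols = sm.OLS(np.log(values), X).fit()
    assert np.allclose(gee.params.to_numpy(), ols.params.to_numpy(), atol=1e-10)
    assert "singleton" in gee.working_correlation


def test_gee_estimates_invariant_to_cluster_order():
    rng = np.random.default_rng(6)
    n = 120
    subjects = np.repeat([f"s{i}" for i in range(40)], 3)
    groups = np.repeat(["a", "b"], 60)
    values = np.exp(rng.normal(0, 0.5, n))
    fit1 = fit_gee_lognormal(values, subjects, groups)
    perm = rng.permutation(n)
    fit2 = fit_gee_lognormal(values[perm], subjects[perm], groups[perm])
    assert np.allclose(
        fit1.params.sort_index().to_numpy(), fit2.params.sort_index().to_numpy(), atol=1e-6
    )


def test_gee_rejects_nonpositive_values():
    with pytest.raises(ValueError, match="positive"):
        fit_gee_lognormal([1.0, 0.0], ["a", "b"], ["x", "y"])


def test_gee_holm_adjustment_is_monotone_and_conservative():
    rng = np.random.default_rng(13)
    groups = np.repeat(["a", "b", "c"], 20)
    values = np.exp(rng.normal(0, 1, 60))
    subjects = [f"s{i}" for i in range(60)]
    gee = fit_gee_lognormal(values, subjects, groups, adjust="holm")
    assert (gee.contrasts["p_adjusted"] >= gee.contrasts["p"] - 1e-12).all()
    assert (gee.contrasts["p_adjusted"] <= 1.0).all()


def test_gee_recovers_generated_load_slope():
    """Bacterial load is generated with a +1.05 log10/week trend; the GEE
    time slope should recover it within sampling error."""
    _, meta, _ = generate_cohort(SyntheticCohortConfig(seed=9))
    rows = meta.frame
    values = 10.0 ** rows["bacterial_load_log10"].to_numpy()
    weeks = rows["collection_day"].to_numpy() / 7.0
    gee = fit_gee_lognormal(values, rows["subject_id"], rows["group"], time=weeks)
    slope_log10 = gee.time_slope[0] / np.log(10)
    se_log10 = gee.time_slope[1] / np.log(10)
    assert slope_log10 == pytest.approx(1.05, abs=3 * se_log10 + 1e-9)


# ---------------------------------------------------------------------------
# zero-inflation diagnostic
# ---------------------------------------------------------------------------


def _simulate_from_fit(fit, rng, n_subjects=120):
    series = []
    for i in range(n_subjects):
        g = fit.groups[i % len(fit.groups)]
        b = rng.normal(0, fit.sigma_b)
        days = np.sort(rng.choice(np.arange(1, 24), size=3, replace=False))
        rows = []
        for t in days:
            b0, b1, b2 = fit.coef[g]
            mu = expit(b0 + b1 * t + b2 * max(t - fit.knot_day, 0) + b)
            n = 8000
            phi = fit.phi[g]
            p = rng.beta(mu / phi, (1 - mu) / phi) if phi > 0 else mu
            y = rng.binomial(n, p)
            rows.append([y, n - y])
        series.append(SubjectSeries(f"z{i}", g, days, np.array(rows), [fit.taxon_id, "o"]))
    return series


@pytest.fixture(scope="module")
def fitted_model():
    cfg = SyntheticCohortConfig(
        seed=4, n_subjects_per_group={"mild": 15, "severe": 15}
    )
    table, meta, _ = generate_cohort(cfg)
    series = build_subject_series(table, meta)
    fit = fit_betabin_joinpoint(series, JoinPointSpec("Staphylococcus", 10.0), n_restarts=1)
    return fit


def test_zero_inflation_self_consistency(fitted_model):
    rng = np.random.default_rng(10)
    sim = _simulate_from_fit(fitted_model, rng)
    report = zero_inflation_check(fitted_model, sim)
    checked = report[~report["skipped"]]
    assert len(checked) > 0
    assert not checked["flagged"].any()


def test_zero_inflation_detects_injected_zeros(fitted_model):
    rng = np.random.default_rng(11)
    sim = _simulate_from_fit(fitted_model, rng)
    for s in sim:  # structural zeros early in one group
        if s.group == "mild":
            mask = s.days < 10
            s.counts[mask, 1] += s.counts[mask, 0]
            s.counts[mask, 0] = 0
    report = zero_inflation_check(fitted_model, sim)
    flagged = report[report["flagged"]]
    assert (flagged["group"] == "mild").any()


def test_zero_inflation_reports_empty_bins(fitted_model):
    rng = np.random.default_rng(12)
    sim = _simulate_from_fit(fitted_model, rng)
    report = zero_inflation_check(fitted_model, sim, day_edges=(0, 7, 14, 30, 60))
    empty = report[report["skipped"]]
    assert (empty["day_bin"] == "[30,60)").all() and len(empty) == len(fitted_model.groups)
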