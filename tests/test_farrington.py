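"""The quasi-Poisson baseline: design, IRLS fit, residuals, bounds."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from excessmort.farrington import (
    BaselineMode,
    FarringtonConfig,
    InsufficientHistoryError,
    TrendMode,
    WeeklyEstimate,
    anscombe_residuals,
    build_reference_design,
    estimate_week,
    fit_quasipoisson,
    prediction_bounds,
    reweight_and_refit,
    season_levels,
)
from excessmort.weeks import Stratum, Place, WeeklyCountSeries, week_of
import datetime as dt


def _series(counts, first=dt.date(2014, 1, 6)):
    stratum = Stratum("SENILITY", Place.ALL, "JP")
    return WeeklyCountSeries(stratum, week_of(first), counts)


# ---------------------------------------------------------------------------
# design construction


def test_season_partition_w3_nine_periods():
    """Reference window holds 7 offsets; each of 9 blocks holds 5."""
    levels = season_levels(w=3, n_offseason_periods=9)
    ref = np.where(levels == 9)[0]
    assert sorted(ref) == [0, 1, 2, 3, 49, 50, 51]
    sizes = [int(np.sum(levels == lvl)) for lvl in range(9)]
    assert sizes == [5] * 9


def test_season_partition_degenerate_w0_one_period():
    levels = season_levels(w=0, n_offseason_periods=1)
    assert np.sum(levels == 1) == 1 and levels[0] == 1
    assert np.sum(levels == 0) == 51


def test_full_history_design_has_260_rows(long_null_series):
    series, _ = long_null_series
    cfg = FarringtonConfig(b=5, w=3)
    target = series.week_at(6 * 52)
    design = build_reference_design(series, target, cfg)
    assert len(design) == 260
    assert target.index not in set(design["week_index"])  # target excluded
    # rows within +/-w of the target's seasonal position carry the ref level
    ref_rows = design[design["season_level"] == 9]
    assert len(ref_rows) == 5 * 7
    deltas = (ref_rows["week_index"] - target.index) % 52
    assert set(deltas) == {0, 1, 2, 3, 49, 50, 51}


def test_window_only_design_keeps_reference_offsets(long_null_series):
    series, _ = long_null_series
    cfg = FarringtonConfig(b=5, w=3, baseline_mode=BaselineMode.WINDOW_ONLY)
    design = build_reference_design(series, series.week_at(6 * 52), cfg)
    assert len(design) == 5 * 7
    assert set(design["season_level"]) == {9}


def test_insufficient_history_error_names_spans(long_null_series):
    series, _ = long_null_series
    cfg = FarringtonConfig(b=5)
    with pytest.raises(InsufficientHistoryError, match="260"):
        build_reference_design(series, series.week_at(100), cfg)


# ---------------------------------------------------------------------------
# fitting


def _design_frame(t, level, y, weight=1.0):
    return pd.DataFrame(
        {"t": t, "season_level": level, "y": y, "weight": weight}
    )


def test_intercept_only_fit_recovers_sample_mean():
    """The Poisson MLE of an intercept-only model is the sample mean."""
    y = np.array([10.0, 12.0, 8.0, 10.0])
    design = _design_frame(np.zeros(4), np.zeros(4, dtype=int), y)
    fit = fit_quasipoisson(design, include_trend=False)
    assert np.allclose(fit.mu, 10.0)
    assert np.isclose(np.exp(fit.alpha_hat), 10.0)


def test_dispersion_near_one_for_poisson_counts_and_floored():
    """Equidispersed counts give Pearson X^2/(n-p) ~ 1, floored at 1."""
    rng = np.random.default_rng(5)
    n = 260
    t = np.arange(n, dtype=float) - n
    level = season_levels(3, 9)[np.arange(n) % 52]
    y = rng.poisson(100.0, size=n).astype(float)
    fit = fit_quasipoisson(_design_frame(t, level, y))
    assert 0.8 < fit.phi_raw < 1.2
    assert fit.phi >= 1.0


def _weighted_poisson_nll(beta, X, y, w):
    eta = X @ beta
    return -np.sum(w * (y * eta - np.exp(eta)))


def _weighted_poisson_grad(beta, X, y, w):
    return -(X.T @ (w * (y - np.exp(X @ beta))))


def maximize_likelihood(fit):
    """Generic-optimizer oracle for the same weighted Poisson likelihood."""
    res = optimize.minimize(
        _weighted_poisson_nll,
        np.zeros(fit.n_params),
        args=(fit.X, fit.y, fit.weights),
        jac=_weighted_poisson_grad,
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 5000},
    )
    return res.x


def test_irls_matches_generic_optimizer_on_small_fixture():
    """IRLS coefficients maximise the same weighted Poisson likelihood."""
    rng = np.random.default_rng(11)
    n = 30
    t = np.arange(n, dtype=float) - n
    level = rng.integers(0, 4, size=n)
    y = rng.poisson(50 * np.exp(0.002 * t), size=n).astype(float)
    w = rng.uniform(0.5, 1.5, size=n)
    design = _design_frame(t, level, y, weight=w)
    fit = fit_quasipoisson(design)
    ref = maximize_likelihood(fit)
    assert np.max(np.abs(ref - fit.params) / (np.abs(fit.params) + 1e-12)) < 1e-6


def test_empty_seasonal_level_is_dropped_with_warning(caplog):
    rng = np.random.default_rng(3)
    n = 60
    t = np.arange(n, dtype=float) - n
    level = np.where(np.arange(n) % 2 == 0, 9, 0)  # levels 1..8 empty
    y = rng.poisson(20.0, size=n).astype(float)
    with caplog.at_level("WARNING"):
        fit = fit_quasipoisson(_design_frame(t, level, y))
    assert fit.n_params == 3  # intercept, trend, one seasonal dummy
    assert any("empty" in rec.message for rec in caplog.records)


def test_conditional_trend_mode_drops_nonsignificant_trend():
    rng = np.random.default_rng(9)
    n = 156  # 3 years
    t = np.arange(n, dtype=float) - n
    level = season_levels(3, 9)[np.arange(n) % 52]
    y = rng.poisson(100.0, size=n).astype(float)  # no true trend
    fit = fit_quasipoisson(
        _design_frame(t, level, y), TrendMode.ORIGINAL_CONDITIONAL, b_years=3
    )
    assert not fit.has_trend
    fit2 = fit_quasipoisson(_design_frame(t, level, y), TrendMode.ALWAYS)
    assert fit2.has_trend


# ---------------------------------------------------------------------------
# residuals and reweighting


@pytest.fixture
def poisson_fit():
    rng = np.random.default_rng(2)
    n = 20
    t = np.arange(n, dtype=float) - n
    y = rng.poisson(30.0, size=n).astype(float)
    return fit_quasipoisson(_design_frame(t, np.zeros(n, dtype=int), y))


def test_anscombe_zero_when_observed_equals_fitted(poisson_fit):
    fit = poisson_fit
    fit.y = fit.mu.copy()
    assert np.allclose(anscombe_residuals(fit), 0.0)


def test_anscombe_matches_direct_formula(poisson_fit):
    """Independent elementwise evaluation of the residual formula."""
    fit = poisson_fit
    r = anscombe_residuals(fit)
    for i in range(len(fit.y)):
        expected = (
            1.5
            * (fit.y[i] ** (2 / 3) - fit.mu[i] ** (2 / 3))
            / (fit.phi**0.5 * fit.mu[i] ** (1 / 6) * (1 - fit.leverage[i]) ** 0.5)
        )
        assert np.isclose(r[i], expected, rtol=1e-12)


def test_anscombe_sign_monotone_in_y(poisson_fit):
    fit = poisson_fit
    r1 = anscombe_residuals(fit)
    fit.y = fit.y + 5.0
    r2 = anscombe_residuals(fit)
    assert np.all(r2 > r1)


def test_reweight_noop_when_no_residual_exceeds_threshold(poisson_fit):
    cfg = FarringtonConfig(reweight_threshold=1e9)
    refit = reweight_and_refit(poisson_fit, cfg)
    assert refit is poisson_fit


def test_reweight_downweights_aberrant_week_and_lowers_expectation():
    rng = np.random.default_rng(4)
    n = 60
    t = np.arange(n, dtype=float) - n
    y = rng.poisson(20.0, size=n).astype(float)
    y[10] = 200.0  # y ~ 10x the fitted mean
    cfg = FarringtonConfig()
    fit = fit_quasipoisson(
        _design_frame(t, np.zeros(n, dtype=int), y), include_trend=False
    )
    refit = reweight_and_refit(fit, cfg)
    assert refit.weights[10] < 1.0
    assert np.isclose(refit.weights.sum(), n)
    assert np.exp(refit.alpha_hat) < np.exp(fit.alpha_hat)


# ---------------------------------------------------------------------------
# prediction bounds


@pytest.mark.parametrize("mu0", [10.0, 100.0, 1000.0])
def test_upper_bound_tracks_exact_poisson_quantile(mu0):
    """With phi=1 and no estimation variance the upper bound is within one
    count of the exact Poisson 97.5% quantile (by pmf summation)."""
    _, upper = prediction_bounds(mu0, var_mu=0.0, phi=1.0, level=0.95)
    # cumulative pmf summation oracle
    ks = np.arange(0, int(mu0 + 20 * np.sqrt(mu0) + 20))
    cdf = np.cumsum(stats.poisson.pmf(ks, mu0))
    quantile = ks[np.searchsorted(cdf, 0.975)]
    assert abs(upper - quantile) <= 1.0


def test_interval_widens_monotonically_in_phi():
    uppers = [prediction_bounds(100.0, 0.0, phi, 0.95)[1] for phi in (1, 2, 5, 20)]
    lowers = [prediction_bounds(100.0, 0.0, phi, 0.95)[0] for phi in (1, 2, 5, 20)]
    assert np.all(np.diff(uppers) > 0)
    assert np.all(np.diff(lowers) < 0)


@pytest.mark.parametrize("mu0", [0.05, 0.5, 1.0, 3.0])
def test_lower_bound_floored_at_zero(mu0):
    lower, upper = prediction_bounds(mu0, var_mu=0.2, phi=3.0, level=0.95)
    assert 0.0 <= lower <= mu0 <= upper


def test_weekly_estimate_invariant_enforced():
    with pytest.raises(ValueError):
        WeeklyEstimate(week=None, expected=10.0, var_mu=0.0, phi=1.0,
                       lower=11.0, upper=12.0)


# ---------------------------------------------------------------------------
# end-to-end invariances


def test_translation_invariance(long_null_series):
    """Shifting the weekly axis origin leaves estimates unchanged."""
    series, _ = long_null_series
    cfg = FarringtonConfig()
    shifted = _series(series.counts, first=dt.date(2015, 1, 5))
    pos = 6 * 52 + 10
    a = estimate_week(series, series.week_at(pos), cfg)
    b = estimate_week(shifted, shifted.week_at(pos), cfg)
    assert np.isclose(a.expected, b.expected)
    assert np.isclose(a.upper, b.upper) and np.isclose(a.lower, b.lower)


def test_count_scaling_scales_expectation(long_null_series):
    series, _ = long_null_series
    cfg = FarringtonConfig()
    pos = 6 * 52 + 10
    scaled = _series(series.counts * 7)
    a = estimate_week(series, series.week_at(pos), cfg)
    b = estimate_week(scaled, scaled.week_at(pos), cfg)
    assert np.isclose(b.expected, 7 * a.expected, rtol=1e-6)
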