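"""Modified Farrington baseline: quasi-Poisson fit and prediction bounds.

For each target week *t* the algorithm fits an overdispersed Poisson
regression to historical counts and asks whether the observed count is
compatible with a two-sided prediction interval around the expected
count.  The mean model is log-linear in time with categorical
seasonality::

    log E[Y_t] = alpha + beta * t + gamma' f(t)

where ``f(t)`` is a factor with ``n_offseason_periods + 1`` levels: one
*reference* level covering the weeks whose seasonal position lies within
``w`` weeks of the target's position (circularly, modulo 52), and
``n_offseason_periods`` equal blocks partitioning the rest of the year.
Counts are assumed quasi-Poisson, ``Var[Y] = phi * mu`` with dispersion
``phi`` estimated from the weighted Pearson statistic and floored at 1.

Two historically motivated variants are switchable:

* ``baseline_mode`` — ``FULL_HISTORY`` (default) fits all ``b*52`` weeks
  preceding the target with the seasonal factor; ``WINDOW_ONLY`` keeps
  only the reference-window weeks of the ``b`` prior years and drops the
  seasonal terms (the original subset-style baseline).
* ``trend_mode`` — ``ALWAYS`` (default) always retains the linear trend;
  ``ORIGINAL_CONDITIONAL`` drops it when it is non-significant at 5%,
  when fewer than 3 years of history are used, or when the predicted
  value exceeds every historical observation.

Past aberrations are downweighted: after an initial unit-weight fit,
rows whose Anscombe residual exceeds ``reweight_threshold`` receive
weight proportional to the inverse squared residual (weights renormalised
to sum to *n*) and the model is refit.

Prediction bounds are computed on the 2/3-power scale, which symmetrises
the skewed count distribution::

    U/L = mu0 * (1 +/- z * (2/3) * sqrt(phi*mu0 + Var[mu0]) / mu0)^(3/2)

with the lower bound floored at 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .weeks import EpiWeek, WeeklyCountSeries

logger = logging.getLogger(__name__)

YEAR_WEEKS = 52  # seasonal cycle length; week 53 folds into week 52's level


class TrendMode(str, Enum):
    ALWAYS = "always"
    ORIGINAL_CONDITIONAL = "original_conditional"


class BaselineMode(str, Enum):
    FULL_HISTORY = "full_history"
    WINDOW_ONLY = "window_only"


class InsufficientHistoryError(ValueError):
    """Raised when a series is too short for the requested lookback."""


@dataclass(frozen=True)
class FarringtonConfig:
    """Tuning parameters of the baseline model.

    Parameters
    ----------
    b
        Years of history used (weeks ``t - b*52 .. t-1``).  Default 5;
        respiratory-disease series conventionally use 3.
    w
        Half-width, in weeks, of the seasonal reference window around
        the target's position.
    n_offseason_periods
        Number of equal seasonal blocks outside the reference window.
    interval_level
        Two-sided prediction-interval level (0.95 -> z = 1.959964).
    reweight_threshold
        Anscombe-residual cutoff above which a historical week is
        downweighted.
    max_reweight_iter
        Number of downweight-and-refit passes.
    """

    b: int = 5
    w: int = 3
    n_offseason_periods: int = 9
    interval_level: float = 0.95
    reweight_threshold: float = 2.58
    max_reweight_iter: int = 1
    trend_mode: TrendMode = TrendMode.ALWAYS
    baseline_mode: BaselineMode = BaselineMode.FULL_HISTORY

    def __post_init__(self):
        if self.b < 1:
            raise ValueError("b must be >= 1")
        if self.w < 0:
            raise ValueError("w must be >= 0")
        if not 0 < self.interval_level < 1:
            raise ValueError("interval_level must be in (0, 1)")
        if self.n_offseason_periods < 1:
            raise ValueError("n_offseason_periods must be >= 1")
        if 2 * self.w + 1 >= YEAR_WEEKS:
            raise ValueError("reference window covers the whole year")
        if self.n_offseason_periods > YEAR_WEEKS - (2 * self.w + 1):
            raise ValueError("more seasonal periods than off-season weeks")

    def with_overrides(self, **kwargs) -> "FarringtonConfig":
        return replace(self, **kwargs)


def season_levels(w: int, n_offseason_periods: int) -> np.ndarray:
    """Seasonal level for each circular week offset 0..51 from the target.

    Offsets within ``w`` of the target position (circularly) get the
    reference level ``n_offseason_periods``; the remaining offsets,
    traversed from ``w+1`` upward, are split into ``n_offseason_periods``
    consecutive blocks of equal length (first blocks take any remainder).
    """
    levels = np.empty(YEAR_WEEKS, dtype=np.int64)
    ref = np.r_[0 : w + 1, YEAR_WEEKS - w : YEAR_WEEKS] if w > 0 else np.array([0])
    levels[ref] = n_offseason_periods
    off = np.arange(w + 1, YEAR_WEEKS - w)
    for lvl, block in enumerate(np.array_split(off, n_offseason_periods)):
        levels[block] = lvl
    return levels


def _design_arrays(
    counts: np.ndarray, target_pos: int, cfg: FarringtonConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(positions, centred t, season level, y) for the lookback window."""
    need = cfg.b * YEAR_WEEKS
    if target_pos < need:
        raise InsufficientHistoryError(
            f"need {need} weeks of history before the target, "
            f"have {target_pos}"
        )
    if target_pos >= len(counts):
        raise InsufficientHistoryError("target week beyond end of series")
    pos = np.arange(target_pos - need, target_pos)
    delta = (pos - target_pos) % YEAR_WEEKS
    level = season_levels(cfg.w, cfg.n_offseason_periods)[delta]
    if cfg.baseline_mode is BaselineMode.WINDOW_ONLY:
        keep = level == cfg.n_offseason_periods
        pos, level = pos[keep], level[keep]
    t = (pos - target_pos).astype(np.float64)
    return pos, t, level, counts[pos].astype(np.float64)


def build_reference_design(
    series: WeeklyCountSeries, target: EpiWeek, cfg: FarringtonConfig
) -> pd.DataFrame:
    """Design rows for one target week.

    Returns a frame with columns ``week_index`` (absolute weekly axis),
    ``t`` (trend covariate, centred so the target week is 0),
    ``season_level`` (0..n_offseason; the maximum value is the reference
    level), ``y`` and ``weight``.  The target week itself is never
    included.
    """
    target_pos = series.position_of(target)
    pos, t, level, y = _design_arrays(series.counts, target_pos, cfg)
    return pd.DataFrame(
        {
            "week_index": series.first_week.index + pos,
            "t": t,
            "season_level": level,
            "y": y,
            "weight": 1.0,
        }
    )


# ---------------------------------------------------------------------------
# quasi-Poisson IRLS


@dataclass
class GLMFit:
    """A fitted weighted quasi-Poisson regression.

    ``params``/``cov`` are ordered as ``names``; ``cov`` is already
    scaled by the (floored) dispersion ``phi``.  ``mu`` are fitted means
    per design row, ``leverage`` the hat-matrix diagonal of the weighted
    fit.
    """

    params: np.ndarray
    names: list[str]
    cov: np.ndarray
    phi: float
    phi_raw: float
    mu: np.ndarray
    X: np.ndarray
    y: np.ndarray
    weights: np.ndarray
    leverage: np.ndarray
    converged: bool
    n_iter: int
    has_trend: bool

    @property
    def alpha_hat(self) -> float:
        return float(self.params[0])

    @property
    def beta_hat(self) -> float:
        """Trend coefficient per week (0 if the trend was dropped)."""
        return float(self.params[self.names.index("t")]) if self.has_trend else 0.0

    @property
    def gamma_hat(self) -> dict[str, float]:
        return {
            n: float(p)
            for n, p in zip(self.names, self.params)
            if n.startswith("season_")
        }

    @property
    def n_params(self) -> int:
        return len(self.params)


def _build_matrix(
    t: np.ndarray, level: np.ndarray, include_trend: bool
) -> tuple[np.ndarray, list[str]]:
    ref = int(level.max())
    cols = [np.ones_like(t)]
    names = ["intercept"]
    if include_trend:
        cols.append(t)
        names.append("t")
    present = sorted(set(int(v) for v in level) - {ref})
    for lvl in present:
        cols.append((level == lvl).astype(np.float64))
        names.append(f"season_{lvl}")
    expected = set(range(ref))
    missing = expected - set(present)
    if missing:
        logger.warning(
            "seasonal level(s) %s empty in design; dummies dropped",
            sorted(missing),
        )
    return np.column_stack(cols), names


def _irls(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, *, tol: float = 1e-9, maxit: int = 100
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool, int]:
    """Weighted Poisson IRLS. Returns (beta, mu, XtWX, converged, n_iter)."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(np.average(y, weights=w) + 0.1)
    XtWX = np.empty((p, p))
    converged = False
    it = 0
    for it in range(1, maxit + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        Ww = w * mu
        z = eta + (y - mu) / mu
        Xw = X * Ww[:, None]
        XtWX = Xw.T @ X
        XtWz = Xw.T @ z
        try:
            new = np.linalg.solve(XtWX, XtWz)
        except np.linalg.LinAlgError:
            new = np.linalg.lstsq(XtWX, XtWz, rcond=None)[0]
        delta = np.linalg.norm(new - beta) / (np.linalg.norm(beta) + 1e-12)
        beta = new
        if delta < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = np.exp(eta)
    Xw = X * (w * mu)[:, None]
    XtWX = Xw.T @ X
    return beta, mu, XtWX, converged, it


def _fit_matrix(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    names: list[str],
    has_trend: bool,
) -> GLMFit:
    n, p = X.shape
    beta, mu, XtWX, converged, it = _irls(X, y, weights)
    if not converged:
        logger.warning("IRLS did not converge in %d iterations", it)
    try:
        XtWX_inv = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        XtWX_inv = np.linalg.pinv(XtWX)
    pearson = float(np.sum(weights * (y - mu) ** 2 / mu))
    dof = max(n - p, 1)
    phi_raw = pearson / dof
    phi = max(1.0, phi_raw)
    cov = phi * XtWX_inv
    leverage = (weights * mu) * np.einsum("ij,jk,ik->i", X, XtWX_inv, X)
    return GLMFit(
        params=beta,
        names=names,
        cov=cov,
        phi=phi,
        phi_raw=phi_raw,
        mu=mu,
        X=X,
        y=y,
        weights=weights,
        leverage=leverage,
        converged=converged,
        n_iter=it,
        has_trend=has_trend,
    )


def fit_quasipoisson(
    design: pd.DataFrame,
    trend_mode: TrendMode = TrendMode.ALWAYS,
    *,
    b_years: int | None = None,
    include_seasonal: bool | None = None,
    include_trend: bool = True,
) -> GLMFit:
    """Fit the weighted quasi-Poisson model to a reference design.

    Coefficients maximise the weighted Poisson log-likelihood (IRLS to
    relative change < 1e-9 or 100 iterations); dispersion is the weighted
    Pearson statistic over residual degrees of freedom, floored at 1;
    the coefficient covariance is ``phi * (X'WX)^-1``.

    With ``trend_mode=ALWAYS`` the linear trend is always retained.
    With ``ORIGINAL_CONDITIONAL`` the trend is dropped (and the model
    refit) when any of the original algorithm's conditions fail:
    coefficient non-significant at 5%, fewer than 3 years of history
    (``b_years``), or predicted value above every historical count.
    """
    t = design["t"].to_numpy(dtype=np.float64)
    level = design["season_level"].to_numpy(dtype=np.int64)
    y = design["y"].to_numpy(dtype=np.float64)
    weights = design["weight"].to_numpy(dtype=np.float64)
    if include_seasonal is None:
        include_seasonal = len(set(level)) > 1
    lev = level if include_seasonal else np.zeros_like(level)

    X, names = _build_matrix(t, lev, include_trend=include_trend)
    if X.shape[0] < X.shape[1] + 1 or y.sum() <= 0:
        raise ValueError(
            f"need at least p+1={X.shape[1] + 1} rows with positive total "
            f"count; have n={X.shape[0]}, sum(y)={y.sum():g}"
        )
    fit = _fit_matrix(X, y, weights, names, has_trend=include_trend)

    if include_trend and trend_mode is TrendMode.ORIGINAL_CONDITIONAL:
        j = names.index("t")
        se = float(np.sqrt(max(fit.cov[j, j], 0.0)))
        pval = 2 * stats.norm.sf(abs(fit.params[j]) / se) if se > 0 else 1.0
        mu0 = float(np.exp(fit.params[0]))  # t is centred on the target
        years = b_years if b_years is not None else round(len(y) / YEAR_WEEKS)
        keep = pval < 0.05 and years >= 3 and mu0 <= float(y.max())
        if not keep:
            X0, names0 = _build_matrix(t, lev, include_trend=False)
            fit = _fit_matrix(X0, y, weights, names0, has_trend=False)
    return fit


def anscombe_residuals(fit: GLMFit) -> np.ndarray:
    """Variance-stabilised residuals of the weighted fit.

    ``r_i = 1.5 (y^(2/3) - mu^(2/3)) / (phi^0.5 mu^(1/6) (1-h)^0.5)``
    with ``h`` the leverage; used to spot aberrant historical weeks.
    """
    if np.any(fit.mu <= 0):
        raise ValueError("fitted means must be positive")
    h = np.clip(fit.leverage, 0.0, 1.0 - 1e-8)
    return (
        1.5
        * (fit.y ** (2.0 / 3.0) - fit.mu ** (2.0 / 3.0))
        / (np.sqrt(fit.phi) * fit.mu ** (1.0 / 6.0) * np.sqrt(1.0 - h))
    )


def reweight_and_refit(fit: GLMFit, cfg: FarringtonConfig) -> GLMFit:
    """Downweight aberrant historical weeks and refit.

    Rows with Anscombe residual above ``cfg.reweight_threshold`` get raw
    weight ``r^-2`` (others 1); weights are rescaled to sum to *n* and
    the model is refit, ``cfg.max_reweight_iter`` times.  If no residual
    exceeds the threshold the input fit is returned unchanged.
    """
    current = fit
    for _ in range(cfg.max_reweight_iter):
        r = anscombe_residuals(current)
        exceed = r > cfg.reweight_threshold
        if not exceed.any():
            return current
        raw = np.where(exceed, r**-2.0, 1.0)
        w = raw * (len(raw) / raw.sum())
        current = _fit_matrix(
            current.X, current.y, w, current.names, current.has_trend
        )
    return current


# ---------------------------------------------------------------------------
# prediction


@dataclass(frozen=True)
class WeeklyEstimate:
    """Expected count and prediction bounds for one target week."""

    week: EpiWeek | None
    expected: float
    var_mu: float
    phi: float
    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower <= self.expected <= self.upper:
            raise ValueError("bounds must bracket the expected count")


def prediction_bounds(
    mu0: float, var_mu: float, phi: float, level: float
) -> tuple[float, float]:
    """Two-sided prediction bounds on the 2/3-power scale.

    The standardised half-width combines sampling variance ``phi*mu0``
    with estimation variance ``var_mu``; the lower bound's inner factor
    is floored at 0 before the 3/2 power, so lower >= 0.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    s = np.sqrt(phi * mu0 + var_mu) / mu0
    upper = mu0 * (1.0 + z * (2.0 / 3.0) * s) ** 1.5
    lower = mu0 * max(0.0, 1.0 - z * (2.0 / 3.0) * s) ** 1.5
    return float(lower), float(upper)


def predict_week(
    fit: GLMFit, target: EpiWeek | None, cfg: FarringtonConfig
) -> WeeklyEstimate:
    """Expected count and prediction interval for the target week.

    The design is centred on the target (trend covariate 0, seasonal
    factor at the reference level), so the target's covariate vector is
    the intercept alone: ``mu0 = exp(alpha)``, ``Var[mu0] = mu0^2 *
    Var[alpha]``.
    """
    x0 = np.zeros(fit.n_params)
    x0[fit.names.index("intercept")] = 1.0
    mu0 = float(np.exp(x0 @ fit.params))
    var_mu = float(mu0**2 * (x0 @ fit.cov @ x0))
    lower, upper = prediction_bounds(mu0, var_mu, fit.phi, cfg.interval_level)
    return WeeklyEstimate(
        week=target, expected=mu0, var_mu=var_mu, phi=fit.phi,
        lower=lower, upper=upper,
    )


def estimate_week(
    series: WeeklyCountSeries, target: EpiWeek, cfg: FarringtonConfig
) -> WeeklyEstimate:
    """Full per-week chain: design, fit, downweight-refit, predict."""
    target_pos = series.position_of(target)
    est, _ = _estimate_at(series.counts, target_pos, cfg)
    return WeeklyEstimate(
        week=target, expected=est.expected, var_mu=est.var_mu,
        phi=est.phi, lower=est.lower, upper=est.upper,
    )


def _estimate_at(
    counts: np.ndarray, target_pos: int, cfg: FarringtonConfig
) -> tuple[WeeklyEstimate, GLMFit]:
    """Fast internal path operating directly on the counts array."""
    _, t, level, y = _design_arrays(counts, target_pos, cfg)
    design = pd.DataFrame(
        {"t": t, "season_level": level, "y": y, "weight": 1.0}
    )
    include_seasonal = cfg.baseline_mode is BaselineMode.FULL_HISTORY
    fit = fit_quasipoisson(
        design, cfg.trend_mode, b_years=cfg.b, include_seasonal=include_seasonal
    )
    fit = reweight_and_refit(fit, cfg)
    return predict_week(fit, None, cfg), fit
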