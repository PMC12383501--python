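"""Trend estimation and comparison for annual series.

Covers ordinary least-squares linear trends, penalized cubic regression
splines with GCV-selected smoothness, linear-vs-spline model choice,
ANCOVA slope comparison between two series, leave-one-species-out
sensitivity of the MTC trend, and 0-4 year lagged driver models.

Inference is plain two-sided OLS throughout; no multiple-testing
correction is applied across lags or sensitivity rows, and no
autocorrelation-robust variant is enabled by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.interpolate import BSpline
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar

from tropicatch.thermal_mtc import ThermalAffinityTable, compute_mtc

logger = logging.getLogger(__name__)

ALPHA = 0.05
SENSITIVITY_FLAG_PCT = 5.0  # |slope change| above this is reported


# ---------------------------------------------------------------------------
# linear trends


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of an annual series on calendar year."""

    slope: float
    intercept: float
    slope_se: float
    p_value: float
    r2: float
    adj_r2: float
    aic: float
    bic: float
    n: int
    residuals: pd.Series
    fitted: pd.Series


def _gaussian_ic(rss: float, n: int, edf: float) -> tuple[float, float]:
    """AIC/BIC under a Gaussian likelihood with ``edf`` mean parameters.

    Matches the statsmodels OLS convention (the error variance is not
    counted), so linear and spline fits are directly comparable.
    """
    rss = max(rss, np.finfo(float).tiny)
    llf = -n / 2.0 * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)
    return -2 * llf + 2 * edf, -2 * llf + np.log(n) * edf


def fit_linear_trend(series: pd.Series) -> TrendFit:
    """Ordinary least squares of value on year."""
    clean = series.dropna()
    if len(clean) < 3:
        raise ValueError("need at least 3 non-missing points for a trend")
    x = clean.index.to_numpy(float)
    y = clean.to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in year")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:  # constant response: define r2 = 0, slope not significant
        r2, adj_r2, p = 0.0, 0.0, 1.0
    else:
        r2 = float(res.rsquared)
        adj_r2 = float(res.rsquared_adj)
        p = float(res.pvalues[1])
    aic, bic = _gaussian_ic(float(res.ssr), len(y), 2.0)
    return TrendFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        p_value=p,
        r2=r2,
        adj_r2=adj_r2,
        aic=aic,
        bic=bic,
        n=len(y),
        residuals=pd.Series(res.resid, index=clean.index, name="residual"),
        fitted=pd.Series(res.fittedvalues, index=clean.index, name="fitted"),
    )


# ---------------------------------------------------------------------------
# penalized cubic regression splines


@dataclass(frozen=True)
class SplineFit:
    """Penalized cubic regression spline of an annual series on year."""

    k: int
    lam: float
    edf: float
    gcv: float
    aic: float
    bic: float
    rss: float
    n: int
    fitted: pd.Series
    residuals: pd.Series
    adj_r2: float


def _spline_basis(x: np.ndarray, k: int, degree: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline design matrix with k columns, knots at quantiles."""
    n_interior = k - degree - 1
    if n_interior < 0:
        raise ValueError(f"basis dimension k={k} too small for cubic splines")
    uniq = np.unique(x)
    if n_interior > 0:
        probs = (np.arange(n_interior) + 1) / (n_interior + 1)
        interior = np.quantile(uniq, probs)
    else:
        interior = np.array([])
    knots = np.r_[[x.min()] * (degree + 1), interior, [x.max()] * (degree + 1)]
    design = BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()
    return design, knots


def _curvature_penalty(knots: np.ndarray, k: int, degree: int = 3) -> np.ndarray:
    """Exact integral of products of second derivatives of the basis.

    Second derivatives of cubic B-splines are piecewise linear, so a
    2-point Gauss rule per knot span integrates their products exactly.
    """
    gx, gw = np.polynomial.legendre.leggauss(2)
    spans = np.unique(knots)
    penalty = np.zeros((k, k))
    splines = [
        BSpline(knots, np.eye(k)[j], degree).derivative(2) for j in range(k)
    ]
    for a, b in zip(spans[:-1], spans[1:]):
        half = (b - a) / 2.0
        pts = (a + b) / 2.0 + half * gx
        d2 = np.column_stack([s(pts) for s in splines])
        penalty += half * (d2.T * gw) @ d2
    return penalty


def _penalized_solve(
    design: np.ndarray, penalty: np.ndarray, y: np.ndarray, lam: float
) -> tuple[np.ndarray, float, float]:
    """Return (fitted, edf, rss) of the penalized least-squares fit.

    Solved as an augmented least-squares problem (rows sqrt(lam) * Lᵀ
    with S = L Lᵀ appended to the design), which stays numerically
    stable for very large lam where the normal equations break down.
    """
    k = design.shape[1]
    w, U = np.linalg.eigh(penalty)
    root = U * np.sqrt(np.clip(w, 0.0, None))  # S = root @ root.T
    aug = np.vstack([design, np.sqrt(lam) * root.T])
    y_aug = np.concatenate([y, np.zeros(k)])
    coef, *_ = np.linalg.lstsq(aug, y_aug, rcond=None)
    fitted = design @ coef
    # edf = tr((BᵀB + lam S)⁻¹ BᵀB) = ||B R⁻¹||_F² with R from QR(aug)
    _, r = np.linalg.qr(aug)
    r_inv = solve_triangular(r, np.eye(k))
    edf = float(((design @ r_inv) ** 2).sum())
    rss = float(((y - fitted) ** 2).sum())
    return fitted, edf, rss


def fit_spline_trend(
    series: pd.Series,
    k: int = 5,
    lam: float | None = None,
    log10_lam_bounds: tuple[float, float] = (-8.0, 12.0),
) -> SplineFit:
    """Penalized cubic spline with curvature penalty.

    The smoothing parameter is chosen by generalized cross-validation
    (coarse log-grid scan refined by bounded scalar minimization)
    unless ``lam`` is given.  As lam -> infinity the fit collapses onto
    the OLS line (the penalty's null space), edf -> 2.
    """
    clean = series.dropna()
    if len(clean) < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} points, got {len(clean)}")
    years = clean.index.to_numpy(float)
    # scale the covariate to [0, 1]: conditions the Gram matrix and puts
    # the penalty on a fixed scale across series lengths
    x = (years - years.min()) / np.ptp(years)
    y = clean.to_numpy(float)
    design, knots = _spline_basis(x, k)
    penalty = _curvature_penalty(knots, k)
    n = len(y)

    def gcv_at(log10_lam: float) -> float:
        _, edf, rss = _penalized_solve(design, penalty, y, 10.0 ** log10_lam)
        denom = max(n - edf, 1e-8)
        return n * rss / denom**2

    if lam is None:
        lo, hi = log10_lam_bounds
        grid = np.linspace(lo, hi, 81)
        scores = np.array([gcv_at(g) for g in grid])
        best = int(np.argmin(scores))
        left = grid[max(best - 1, 0)]
        right = grid[min(best + 1, len(grid) - 1)]
        res = minimize_scalar(gcv_at, bounds=(left, right), method="bounded")
        lam = float(10.0 ** res.x)
        if gcv_at(grid[best]) < res.fun:  # guard against a flat refine
            lam = float(10.0 ** grid[best])
    fitted, edf, rss = _penalized_solve(design, penalty, y, lam)
    denom = max(n - edf, 1e-8)
    gcv = n * rss / denom**2
    aic, bic = _gaussian_ic(rss, n, edf)
    tss = float(((y - y.mean()) ** 2).sum())
    adj_r2 = 1.0 - (rss / denom) / (tss / (n - 1)) if tss > 0 else 0.0
    return SplineFit(
        k=k,
        lam=float(lam),
        edf=edf,
        gcv=gcv,
        aic=aic,
        bic=bic,
        rss=rss,
        n=n,
        fitted=pd.Series(fitted, index=clean.index, name="fitted"),
        residuals=pd.Series(y - fitted, index=clean.index, name="residual"),
        adj_r2=adj_r2,
    )


# ---------------------------------------------------------------------------
# model choice


@dataclass(frozen=True)
class ModelChoice:
    """Linear-vs-spline comparison report.

    The linear model is retained unless the spline wins on *all three*
    criteria (AIC, BIC, adjusted R^2); when criteria disagree the
    simpler model stands.
    """

    selected: str  # "linear" | "spline"
    delta_aic: float  # spline - linear (negative favors the spline)
    delta_bic: float
    delta_adj_r2: float  # spline - linear (positive favors the spline)
    residual_summary: pd.DataFrame


def _lag1_autocorr(resid: np.ndarray) -> float:
    r = resid - resid.mean()
    denom = float((r**2).sum())
    if denom == 0:
        return 0.0
    return float((r[1:] * r[:-1]).sum() / denom)


def choose_trend_model(lin: TrendFit, spl: SplineFit) -> ModelChoice:
    if lin.n != spl.n or not lin.fitted.index.equals(spl.fitted.index):
        raise ValueError("linear and spline fits cover different data")
    delta_aic = spl.aic - lin.aic
    delta_bic = spl.bic - lin.bic
    delta_adj = spl.adj_r2 - lin.adj_r2
    # ties within numerical tolerance (a fully smoothed spline IS the
    # OLS line, up to floating point) go to the simpler linear model
    tol = 1e-3
    spline_wins = delta_aic < -tol and delta_bic < -tol and delta_adj > 1e-6
    summary = pd.DataFrame(
        {
            "model": ["linear", "spline"],
            "resid_sd": [
                float(np.std(lin.residuals.to_numpy(), ddof=1)),
                float(np.std(spl.residuals.to_numpy(), ddof=1)),
            ],
            "resid_lag1_autocorr": [
                _lag1_autocorr(lin.residuals.to_numpy()),
                _lag1_autocorr(spl.residuals.to_numpy()),
            ],
        }
    )
    return ModelChoice(
        selected="spline" if spline_wins else "linear",
        delta_aic=delta_aic,
        delta_bic=delta_bic,
        delta_adj_r2=delta_adj,
        residual_summary=summary,
    )


# ---------------------------------------------------------------------------
# ANCOVA


@dataclass(frozen=True)
class AncovaResult:
    """Slope-equality test between two annual series."""

    slope_a: float
    slope_b: float
    slope_difference: float  # b - a
    interaction_p: float
    summary: str


def compare_slopes_ancova(
    series_a: pd.Series, series_b: pd.Series, labels: tuple[str, str] = ("a", "b")
) -> AncovaResult:
    """Pooled model value ~ year + group + year:group.

    The interaction p-value tests equality of the two slopes.
    """
    frames = []
    for series, label in ((series_a, labels[0]), (series_b, labels[1])):
        clean = series.dropna()
        if len(clean) < 3 or np.ptp(clean.index.to_numpy(float)) == 0:
            raise ValueError(f"group {label!r} is degenerate (<3 points or one year)")
        frames.append(
            pd.DataFrame(
                {
                    "value": clean.to_numpy(float),
                    "year": clean.index.to_numpy(float),
                    "group": label,
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    formula = f"value ~ year * C(group, Treatment(reference={labels[0]!r}))"
    model = smf.ols(formula, data=data).fit()
    inter = [name for name in model.params.index if name.startswith("year:")]
    assert len(inter) == 1
    diff = float(model.params[inter[0]])
    p = float(model.pvalues[inter[0]])
    if np.isnan(p):  # zero residual variance with a nonzero difference
        p = 0.0 if diff != 0 else 1.0
    slope_a = float(model.params["year"])
    return AncovaResult(
        slope_a=slope_a,
        slope_b=slope_a + diff,
        slope_difference=diff,
        interaction_p=p,
        summary=str(model.summary()),
    )


# ---------------------------------------------------------------------------
# leave-one-species-out sensitivity


def sensitivity_loo(
    matrix: pd.DataFrame,
    table: ThermalAffinityTable,
    flag_pct: float = SENSITIVITY_FLAG_PCT,
) -> pd.DataFrame:
    """Slope of the MTC trend with each species excluded in turn.

    The percent change is signed, 100 * (slope_without - slope_full) /
    |slope_full|, so a sign flip exceeds -100%.  Rows whose exclusion
    leaves fewer than 2 species with positive catch in some year are
    flagged unavailable.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 species for leave-one-out analysis")
    full = fit_linear_trend(compute_mtc(matrix, table))
    rows = []
    for species in matrix.columns:
        sub = matrix.drop(columns=species)
        available = bool(((sub > 0).sum(axis=1) >= 2).all())
        slope = p_val = change = np.nan
        if available:
            try:
                fit = fit_linear_trend(compute_mtc(sub, table))
            except ValueError:
                available = False
            else:
                slope, p_val = fit.slope, fit.p_value
                if full.slope != 0:
                    change = 100.0 * (slope - full.slope) / abs(full.slope)
                else:
                    change = np.nan
        rows.append(
            {
                "species_code": species,
                "affinity": table.classes.get(species, ""),
                "slope_without": slope,
                "p_without": p_val,
                "slope_change_pct": change,
                "flagged": bool(available and abs(change) > flag_pct),
                "available": available,
            }
        )
    result = pd.DataFrame(rows)
    result.attrs["slope_full"] = full.slope
    result.attrs["p_full"] = full.p_value
    return result


# ---------------------------------------------------------------------------
# lagged driver models


@dataclass(frozen=True)
class LagModelFit:
    """OLS of the response on a driver lagged by ``lag`` years."""

    driver: str
    lag: int
    slope: float
    slope_se: float
    p_value: float
    r2: float
    aic: float
    n: int


@dataclass(frozen=True)
class LagSelection:
    """The three selection criteria, reported separately."""

    by_aic: int
    by_r2: int
    significant: tuple[int, ...]
    common_sample: bool


def fit_lagged(
    response: pd.Series,
    driver: pd.Series,
    max_lag: int = 4,
    common_sample: bool = False,
    alpha: float = ALPHA,
    driver_name: str | None = None,
) -> tuple[list[LagModelFit], LagSelection]:
    """Fit response_y ~ driver_{y - lag} for lag = 0..max_lag.

    By default each lag uses its own maximal overlap of years; with
    ``common_sample=True`` every lag is refit on the years for which
    *all* lags are available, making the AIC comparison share one n.
    Lags with fewer than 3 aligned pairs are skipped with a log entry.
    """
    name = driver_name or (driver.name if driver.name else "driver")
    resp = response.dropna()
    drv = driver.dropna()

    def aligned_years(lag: int) -> pd.Index:
        shifted = pd.Index(drv.index.to_numpy() + lag)
        return resp.index.intersection(shifted)

    if common_sample:
        shared = aligned_years(0)
        for lag in range(1, max_lag + 1):
            shared = shared.intersection(aligned_years(lag))
    fits: list[LagModelFit] = []
    for lag in range(max_lag + 1):
        years = shared if common_sample else aligned_years(lag)
        if len(years) < 3:
            logger.warning("lag %d skipped: only %d aligned pairs", lag, len(years))
            continue
        y = resp.loc[years].to_numpy(float)
        x = drv.loc[years.to_numpy() - lag].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("lag %d skipped: degenerate (constant) series", lag)
            continue
        res = sm.OLS(y, sm.add_constant(x)).fit()
        aic, _ = _gaussian_ic(float(res.ssr), len(y), 2.0)
        fits.append(
            LagModelFit(
                driver=name,
                lag=lag,
                slope=float(res.params[1]),
                slope_se=float(res.bse[1]),
                p_value=float(res.pvalues[1]),
                r2=float(res.rsquared),
                aic=aic,
                n=len(y),
            )
        )
    if not fits:
        raise ValueError("no lag had sufficient overlap")
    selection = LagSelection(
        by_aic=min(fits, key=lambda f: f.aic).lag,
        by_r2=max(fits, key=lambda f: f.r2).lag,
        significant=tuple(f.lag for f in fits if f.p_value < alpha),
        common_sample=common_sample,
    )
    return fits, selection


def lag_table(fits: Sequence[LagModelFit]) -> pd.DataFrame:
    """Lag-model results in tabular form (driver, lag, slope, SE, ...)."""
    return pd.DataFrame(
        [
            {
                "driver": f.driver,
                "lag_yr": f.lag,
                "slope": f.slope,
                "se": f.slope_se,
                "p_value": f.p_value,
                "r2": f.r2,
                "aic": f.aic,
                "n": f.n,
            }
            for f in fits
        ]
    )
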