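"""Single-stage and weighted-stage linear yield models with LOOCV.

The yield model is simple linear regression of relative yield on either a
single-stage relative variable (rLAI or an rVI) or the stage-weighted
composite ``x_plot = sum_t w_t * value(plot, t)``.  Conventions follow the
weighted-growth-stage method: R^2 is the squared Pearson correlation,
adjusted as ``1 - (1 - R^2)(n-1)/(n-2)``; RMSE divides by n (not n-2);
significance is the F(1, n-2) test.  Leave-one-out cross-validation records
per-fold coefficients and training R^2, the held-out RMSE, and a mean
relative error computed on absolute yields reconstructed with the reference
yield (relative yields pass through zero, where relative errors diverge).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ValidationError
from .growth import STAGES
from .weights import (DEFAULT_COMPARISON, WeightVector, entropy_weights,
                      iahp_weights, ocw_weights)

__all__ = [
    "RegressionFit",
    "CVResult",
    "fit_linear",
    "loocv",
    "predict_yield",
    "weighted_composite",
    "correlation_screen",
    "pooled_multiperiod_correlation",
    "stage_matrix",
    "WeightedStageYieldRegressor",
]


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of y = slope*x + intercept with the package's conventions."""

    slope: float
    intercept: float
    r2: float
    adj_r2: float
    rmse: float
    f_stat: float
    p_value: float
    n: int

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    @property
    def significant_001(self) -> bool:
        """The conventional 'P < 0.001' significance flag."""
        return self.p_value < 0.001


@dataclass(frozen=True)
class CVResult:
    """Leave-one-out cross-validation summary (K = n folds)."""

    coef_mean: tuple  # (slope, intercept) averaged over folds
    r2_mean: float  # mean training R^2 over folds
    r2_pooled: float  # squared correlation of pooled held-out predictions vs observed
    rmse_cv: float  # RMSE of held-out errors, divided by K
    mre: float  # mean relative error on absolute yields
    K: int
    predictions: np.ndarray  # held-out prediction per sample, in input order


def _as_xy(x, y, min_n=3):
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < min_n:
        raise ValidationError(f"need at least {min_n} samples, got {x.size}")
    if np.ptp(x) == 0.0:
        raise ValidationError("regressor has zero variance")
    return x, y


def fit_linear(x, y) -> RegressionFit:
    """Ordinary least squares of y on x with F-test diagnostics."""
    x, y = _as_xy(x, y)
    n = x.size
    xc, yc = x - x.mean(), y - y.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ yc) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    sse = float(resid @ resid)
    sst = float(yc @ yc)
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    rmse = float(np.sqrt(sse / n))
    if r2 >= 1.0:
        f_stat, p_value = float("inf"), 0.0
    else:
        f_stat = r2 * (n - 2) / (1.0 - r2)
        p_value = float(stats.f.sf(f_stat, 1, n - 2))
    return RegressionFit(slope=slope, intercept=intercept, r2=r2, adj_r2=adj_r2,
                         rmse=rmse, f_stat=f_stat, p_value=p_value, n=n)


def loocv(x, y, ref_yield: float = 0.0) -> CVResult:
    """Leave-one-out cross-validation of the simple linear model.

    Each of the K = n folds refits on the remaining n-1 points and predicts
    the held-out one.  ``ref_yield`` shifts both predictions and
    observations back to absolute yields for the mean relative error.
    """
    x, y = _as_xy(x, y, min_n=4)
    n = x.size
    slopes, intercepts, r2s, preds = [], [], [], np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        xi, yi = x[mask], y[mask]
        if np.ptp(xi) == 0.0:
            raise ValidationError(f"fold {i}: training x has zero variance")
        fit = fit_linear(xi, yi)
        slopes.append(fit.slope)
        intercepts.append(fit.intercept)
        r2s.append(fit.r2)
        preds[i] = fit.slope * x[i] + fit.intercept
    errors = preds - y
    rmse_cv = float(np.sqrt(np.mean(errors**2)))
    actual_abs = y + ref_yield
    if np.any(actual_abs == 0.0):
        raise ValidationError("absolute yield of zero; supply the reference yield for MRE")
    mre = float(np.mean(np.abs(errors) / np.abs(actual_abs)))
    if np.ptp(preds) > 0 and np.ptp(y) > 0:
        r2_pooled = float(np.corrcoef(preds, y)[0, 1] ** 2)
    else:
        r2_pooled = float("nan")
    return CVResult(coef_mean=(float(np.mean(slopes)), float(np.mean(intercepts))),
                    r2_mean=float(np.mean(r2s)), r2_pooled=r2_pooled,
                    rmse_cv=rmse_cv, mre=mre, K=n, predictions=preds)


def predict_yield(fit: RegressionFit, x, ref_yield: float):
    """Absolute yield: slope*x + intercept + reference yield (kg/plot)."""
    return fit.predict(x) + ref_yield


def stage_matrix(obs: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Pivot a tidy observation table into a plots x stages matrix."""
    if variable not in obs.columns:
        raise ValidationError(f"variable {variable!r} not in observation table")
    wide = obs.pivot(index="plot_id", columns="stage", values=variable)
    missing = [s for s in STAGES if s not in wide.columns]
    if missing or wide.isna().any().any():
        raise ValidationError(f"incomplete plot x stage grid for {variable!r}")
    return wide[list(STAGES)]


def weighted_composite(obs: pd.DataFrame, W: WeightVector, variable: str) -> pd.Series:
    """Per-plot scalar ``sum_t w_t * value(plot, t, variable)``."""
    wide = stage_matrix(obs, variable)
    out = wide.to_numpy() @ W.w
    return pd.Series(out, index=wide.index, name=f"{variable}_weighted")


def correlation_screen(obs: pd.DataFrame, rel_yield: pd.Series,
                       variables=None) -> dict:
    """Pearson r of each (stage, variable) column against relative yield.

    Returns ``{"r": stages x variables DataFrame, "best_stage": Series per
    variable, "best_variable": Series per stage}``; zero-variance columns
    report NaN.
    """
    variables = variables or [c for c in obs.columns if c not in ("plot_id", "stage")]
    table = pd.DataFrame(index=list(STAGES), columns=variables, dtype=float)
    for var in variables:
        wide = stage_matrix(obs, var)
        y = rel_yield.loc[wide.index].to_numpy(dtype=float)
        if y.size < 3:
            raise ValidationError("need at least 3 plots for the correlation screen")
        for s in STAGES:
            col = wide[s].to_numpy(dtype=float)
            if np.ptp(col) == 0.0 or np.ptp(y) == 0.0:
                table.loc[s, var] = np.nan
            else:
                table.loc[s, var] = float(np.corrcoef(col, y)[0, 1])
    absr = table.abs()
    best_stage = absr.apply(lambda c: c.idxmax() if c.notna().any() else np.nan, axis=0)
    best_var = absr.apply(lambda r: r.idxmax() if r.notna().any() else np.nan, axis=1)
    return {"r": table, "best_stage": best_stage, "best_variable": best_var}


def pooled_multiperiod_correlation(obs: pd.DataFrame, plot_yield: pd.Series,
                                   variables=None) -> pd.Series:
    """|Pearson r| of each variable vs yield over ALL (plot, stage) rows.

    This is the multi-period pooled correlation where stage-level
    confounds (illumination offsets, phenological level shifts) attenuate
    absolute variables but cancel from relativized ones; per-stage
    correlations are blind to such shared offsets.
    """
    variables = variables or [c for c in obs.columns if c not in ("plot_id", "stage")]
    y = plot_yield.loc[obs["plot_id"]].to_numpy(dtype=float)
    out = {}
    for var in variables:
        v = obs[var].to_numpy(dtype=float)
        out[var] = abs(float(np.corrcoef(v, y)[0, 1])) if np.ptp(v) > 0 else np.nan
    return pd.Series(out, name="abs_pooled_r")


class WeightedStageYieldRegressor(BaseEstimator, RegressorMixin):
    """Stage-weighted linear yield model.

    Collapses an (n_plots, 5) stage matrix into a weighted composite and
    fits relative yield on it by OLS.

    Parameters
    ----------
    weighting : {"iahp", "ew", "ocw"} or array-like of 5 weights
        How the stage weights are obtained.  "iahp" uses the comparison
        matrix; "ew" derives entropy weights from the training matrix X
        itself; "ocw" combines the two with coefficient ``alpha``.
    comparison_matrix : array-like, optional
        Three-scale stage comparison matrix (defaults to the built-in
        agronomic ranking TES > SAS > TFS > HS > SS).
    alpha : float
        Subjective share of the OCW combination, in [0, 1].
    ew_normalization : {"minmax_shift", "none"}
        Column normalization for the entropy weights.
    ref_yield : float
        Reference-plot yield added back by :meth:`predict_absolute`.

    Attributes
    ----------
    stage_weights_ : WeightVector
    slope_, intercept_, adj_r2_, rmse_, f_stat_, p_value_ : float
    fit_ : RegressionFit
    """

    def __init__(self, weighting="ocw", comparison_matrix=None, alpha=0.7,
                 ew_normalization="minmax_shift", ref_yield=0.0):
        self.weighting = weighting
        self.comparison_matrix = comparison_matrix
        self.alpha = alpha
        self.ew_normalization = ew_normalization
        self.ref_yield = ref_yield

    def _resolve_weights(self, X):
        A = DEFAULT_COMPARISON if self.comparison_matrix is None else self.comparison_matrix
        if isinstance(self.weighting, str):
            method = self.weighting.lower()
            if method == "iahp":
                return iahp_weights(A)
            if method == "ew":
                return entropy_weights(X, normalization=self.ew_normalization)
            if method == "ocw":
                w1, audit1 = iahp_weights(A)
                w2, audit2 = entropy_weights(X, normalization=self.ew_normalization)
                w, audit = ocw_weights(w1, w2, alpha=self.alpha)
                audit.r, audit.kappa, audit.e, audit.d = audit1.r, audit1.kappa, audit2.e, audit2.d
                return w, audit
            raise ValidationError(f"unknown weighting {self.weighting!r}")
        return WeightVector(np.asarray(self.weighting, dtype=float), method="explicit"), None

    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y, dtype=float).reshape(-1)
        if y.size != X.shape[0]:
            raise ValidationError("X and y have inconsistent lengths")
        self.stage_weights_, self.weight_audit_ = self._resolve_weights(X)
        composite = X @ self.stage_weights_.w
        self.fit_ = fit_linear(composite, y)
        self.slope_ = self.fit_.slope
        self.intercept_ = self.fit_.intercept
        self.adj_r2_ = self.fit_.adj_r2
        self.rmse_ = self.fit_.rmse
        self.f_stat_ = self.fit_.f_stat
        self.p_value_ = self.fit_.p_value
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _check_X(X):
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(STAGES):
            raise ValidationError(f"X must be (n_plots, {len(STAGES)})")
        if not np.isfinite(X).all():
            raise ValidationError("X has missing stage values")
        return X

    def predict(self, X):
        """Relative yield prediction."""
        X = self._check_X(X)
        return self.slope_ * (X @ self.stage_weights_.w) + self.intercept_

    def predict_absolute(self, X):
        """Absolute yield prediction (adds the reference yield back)."""
        return self.predict(X) + self.ref_yield

    def loocv(self, X, y) -> CVResult:
        """Leave-one-out CV of the composite model (weights held fixed)."""
        X = self._check_X(X)
        return loocv(X @ self.stage_weights_.w, y, ref_yield=self.ref_yield)
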