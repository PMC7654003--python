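"""Slogistic dry-matter curve fitting and growth-stage partitioning.

Potato dry-matter accumulation over the season follows a flat-S logistic
curve ``y = a / (1 + b exp(-k x))`` with *a* the asymptotic dry weight
(g/plant), *b* a dimensionless shape parameter and *k* a rate (1/day).
The second derivative of the curve attains its extrema at
``(ln b -/+ ln(2 + sqrt(3))) / k``, which split the season into gradually,
rapidly and slowly increasing phases; aligning the five agronomic growth
stages (SS, TFS, TES, SAS, HS) with those phases anchors the stage
importance ranking used for weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FitConvergenceError, ValidationError

__all__ = [
    "STAGES",
    "LN_2_PLUS_SQRT3",
    "SlogisticParams",
    "StageCalendar",
    "StagePartition",
    "SlogisticCurve",
    "slogistic",
    "slogistic_rate",
    "slogistic_accel",
    "fit_slogistic",
    "slogistic_value",
    "growth_rate",
    "stage_boundaries",
    "rank_stages",
    "read_dry_weight_csv",
]

#: Growth-stage labels in chronological order: seeding, tuber formation,
#: tuber expansion, starch accumulation, harvest.
STAGES = ("SS", "TFS", "TES", "SAS", "HS")

#: ln(2 + sqrt(3)); the half-width of the rapid phase in units of 1/k.
LN_2_PLUS_SQRT3 = float(np.log(2.0 + np.sqrt(3.0)))


def slogistic(x, a, b, k):
    """Logistic value ``a / (1 + b exp(-k x))`` (g/plant)."""
    return a / (1.0 + b * np.exp(-k * np.asarray(x, dtype=float)))


def slogistic_rate(x, a, b, k):
    """First derivative ``a b k exp(-k x) / (1 + b exp(-k x))^2`` (g/plant/day)."""
    e = b * np.exp(-k * np.asarray(x, dtype=float))
    return a * k * e / (1.0 + e) ** 2


def slogistic_accel(x, a, b, k):
    """Second derivative ``a b k^2 exp(-k x) (b exp(-k x) - 1) / (1 + b exp(-k x))^3``."""
    e = b * np.exp(-k * np.asarray(x, dtype=float))
    return a * k * k * e * (e - 1.0) / (1.0 + e) ** 3


@dataclass(frozen=True)
class SlogisticParams:
    """Fitted logistic parameters with fit diagnostics."""

    a: float
    b: float
    k: float
    adj_r2: float = float("nan")
    n_obs: int = 0

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0 and self.k > 0):
            raise ValidationError(f"require a, b, k > 0; got {(self.a, self.b, self.k)}")
        if np.isfinite(self.adj_r2) and self.adj_r2 > 1.0:
            raise ValidationError("adjusted R^2 cannot exceed 1")

    @property
    def t_inflect(self) -> float:
        """Day of maximum growth rate, ln(b)/k."""
        return float(np.log(self.b) / self.k)


@dataclass(frozen=True)
class StageCalendar:
    """Calendar anchors (days after sowing) that the curve cannot supply.

    SS ends at the first post-emergence measurement; HS begins at the
    configured senescence onset.  Defaults follow a May-sown season with
    first field measurement 43 days after sowing and final measurement on
    day 117.
    """

    season_start: float = 0.0
    ss_end: float = 43.0
    harvest_onset: float = 105.0
    season_end: float = 117.0

    def __post_init__(self):
        if not (self.season_start < self.ss_end < self.harvest_onset < self.season_end):
            raise ValidationError("calendar anchors must be strictly ordered")


@dataclass(frozen=True)
class StagePartition:
    """Phase-change days and the five stage windows tiling the season."""

    t_low: float
    t_inflect: float
    t_high: float
    stage_windows: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.t_low < self.t_inflect < self.t_high):
            raise ValidationError("phase-change days must be ordered t_low < t_inflect < t_high")
        if abs(self.t_inflect - 0.5 * (self.t_low + self.t_high)) > 1e-9:
            raise ValidationError("t_inflect must be the midpoint of (t_low, t_high)")
        if self.stage_windows:
            # ordered and non-overlapping; contiguous tiling is guaranteed by
            # stage_boundaries construction (degenerate point windows allowed)
            prev_end = None
            for s in STAGES:
                if s not in self.stage_windows:
                    raise ValidationError(f"missing stage window {s}")
                lo, hi = self.stage_windows[s]
                if hi < lo:
                    raise ValidationError(f"window {s} has negative length")
                if prev_end is not None and lo < prev_end - 1e-9:
                    raise ValidationError("stage windows must not overlap")
                prev_end = hi


class SlogisticCurve(BaseEstimator, RegressorMixin):
    """Least-squares logistic growth-curve regressor.

    Fits ``y = a / (1 + b exp(-k x))`` by unweighted nonlinear least squares
    on raw g/plant.  Initialization: ``a0 = 1.05 * max(y)``, then (b0, k0)
    from an ordinary regression of ``ln(a0/y - 1)`` on x; parameters are
    refined iteratively to relative tolerance ``tol``.

    Attributes
    ----------
    a_, b_, k_ : float
        Fitted parameters.
    adj_r2_ : float
        Adjusted R^2 with three model parameters.
    params_ : SlogisticParams
        Bundled parameters and diagnostics.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 2000):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValidationError("x and y must have equal length")
        if x.size < 5:
            raise ValidationError("need at least 5 sampling dates")
        if np.any(np.diff(np.sort(x)) == 0):
            raise ValidationError("sampling days must be distinct")
        if np.any(y <= 0):
            raise ValidationError("dry weights must be positive")
        if y.max() == y.min():
            raise ValidationError("constant dry-weight series cannot be fitted")

        a0 = 1.05 * y.max()
        z = a0 / y - 1.0
        clip = z <= 0
        if clip.any():  # y >= a0 cannot happen with a0 > max(y), but guard anyway
            warnings.warn("dry weights at or above a0 clamped during linearization")
            z = np.clip(z, 1e-12, None)
        # ln z = ln b - k x
        slope, intercept = np.polyfit(x, np.log(z), 1)
        b0 = float(np.exp(intercept))
        k0 = float(-slope)
        if not (b0 > 0) or not (k0 > 0):
            b0, k0 = max(b0, 1.0), max(k0, 1e-3)
        p0 = (a0, b0, k0)
        try:
            popt, _ = curve_fit(
                slogistic, x, y, p0=p0,
                bounds=([1e-12] * 3, [np.inf] * 3),
                xtol=self.tol, ftol=self.tol, gtol=self.tol,
                maxfev=self.max_iter,
            )
        except RuntimeError as exc:
            raise FitConvergenceError(f"logistic fit did not converge: {exc}", last_params=p0) from exc
        a, b, k = (float(v) for v in popt)
        resid = y - slogistic(x, a, b, k)
        sse = float(resid @ resid)
        sst = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - sse / sst if sst > 0 else float("nan")
        n = x.size
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 3) if n > 3 else float("nan")
        self.a_, self.b_, self.k_ = a, b, k
        self.adj_r2_ = adj
        self.n_obs_ = n
        self.params_ = SlogisticParams(a=a, b=b, k=k, adj_r2=adj, n_obs=n)
        return self

    def predict(self, X):
        return slogistic(np.asarray(X, dtype=float).reshape(-1), self.a_, self.b_, self.k_)

    def growth_rate(self, X):
        return slogistic_rate(np.asarray(X, dtype=float).reshape(-1), self.a_, self.b_, self.k_)


def fit_slogistic(day, dry_weight, tol: float = 1e-8) -> SlogisticParams:
    """Functional wrapper around :class:`SlogisticCurve`."""
    return SlogisticCurve(tol=tol).fit(day, dry_weight).params_


def slogistic_value(p: SlogisticParams, x) -> np.ndarray | float:
    """Curve value at day(s) x (g/plant)."""
    v = slogistic(x, p.a, p.b, p.k)
    return float(v) if np.isscalar(x) else v


def growth_rate(p: SlogisticParams, x) -> np.ndarray | float:
    """Curve slope at day(s) x (g/plant/day); maximal value a k / 4 at ln(b)/k."""
    v = slogistic_rate(x, p.a, p.b, p.k)
    return float(v) if np.isscalar(x) else v


def stage_boundaries(p: SlogisticParams, calendar: StageCalendar | None = None) -> StagePartition:
    """Partition the season at the second-derivative extrema of the curve.

    The rapid phase runs from ``t_low = (ln b - ln(2+sqrt 3))/k`` to
    ``t_high = (ln b + ln(2+sqrt 3))/k``.  Stage windows: SS from season
    start to the calendar's ``ss_end``; TFS up to ``t_low``; TES the rapid
    phase ``[t_low, t_high)``; SAS up to the calendar's ``harvest_onset``;
    HS through season end.  SS/HS anchors are calendar-supplied, not
    curve-derived.
    """
    calendar = calendar or StageCalendar()
    lnb = np.log(p.b)
    t_low = float((lnb - LN_2_PLUS_SQRT3) / p.k)
    t_high = float((lnb + LN_2_PLUS_SQRT3) / p.k)
    t_inflect = float(lnb / p.k)
    edges = [calendar.season_start, calendar.ss_end, t_low, t_high,
             calendar.harvest_onset, calendar.season_end]
    if not all(e2 > e1 for e1, e2 in zip(edges, edges[1:])):
        raise ValidationError(
            f"curve phase days {t_low:.2f}/{t_high:.2f} do not interleave the "
            f"calendar anchors {calendar}; adjust the calendar"
        )
    windows = {s: (edges[i], edges[i + 1]) for i, s in enumerate(STAGES)}
    return StagePartition(t_low=t_low, t_inflect=t_inflect, t_high=t_high, stage_windows=windows)


def rank_stages(p: SlogisticParams, partition: StagePartition) -> list[str]:
    """Stages ordered by mean growth rate over their windows, descending.

    The mean rate over ``[lo, hi)`` is the exact increment
    ``(y(hi) - y(lo)) / (hi - lo)``; degenerate zero-width windows fall back
    to the point rate.  Ties break toward the later stage.

    This is the curve-only ordering.  Windows flanking the rapid phase
    symmetrically (tuber formation just before, starch accumulation just
    after) produce near-tied mean rates whose order is decided by window
    length alone; an agronomic importance ranking that overrides such
    near-ties belongs in the stage comparison matrix, not here.
    """
    rates = {}
    for s in STAGES:
        lo, hi = partition.stage_windows[s]
        if hi > lo:
            rates[s] = (slogistic_value(p, hi) - slogistic_value(p, lo)) / (hi - lo)
        else:
            rates[s] = growth_rate(p, lo)
    order = sorted(STAGES, key=lambda s: (rates[s], STAGES.index(s)), reverse=True)
    return order


def read_dry_weight_csv(path) -> pd.DataFrame:
    """Read a dry-weight series CSV with columns ``day, dry_weight_g``."""
    df = pd.read_csv(path)
    missing = {"day", "dry_weight_g"} - set(df.columns)
    if missing:
        raise ValidationError(f"dry-weight CSV missing columns: {sorted(missing)}")
    df = df.sort_values("day").reset_index(drop=True)
    if df["day"].duplicated().any():
        raise ValidationError("duplicate sampling days in dry-weight series")
    return df
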