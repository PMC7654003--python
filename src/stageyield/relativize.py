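"""Reference-plot selection and subtraction-based relative variables.

Multi-period canopy measurements are confounded by stage-to-stage changes in
illumination, aerosol and background.  Subtracting a single reference plot's
same-stage value from every plot's LAI, vegetation indices and yield removes
any component shared by all plots at a stage while leaving every pairwise
difference between plots — and hence every correlation, slope and R^2 —
exactly unchanged within a stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ValidationError
from .growth import STAGES

__all__ = [
    "WATER_LEVELS",
    "NITROGEN_LEVELS",
    "select_reference",
    "relativize_table",
    "StageRelativizer",
    "validate_plot_table",
    "validate_observation_table",
]

WATER_LEVELS = ("EM", "NM", "IM")
NITROGEN_LEVELS = ("N1", "N2", "N3")

#: Agronomically "normal" treatment used as the default designated reference.
DEFAULT_REFERENCE_TREATMENT = {"water": "NM", "nitrogen": "N2", "replicate": 1}


def validate_plot_table(plots: pd.DataFrame) -> pd.DataFrame:
    required = {"plot_id", "water", "nitrogen", "replicate", "yield_kg"}
    missing = required - set(plots.columns)
    if missing:
        raise ValidationError(f"plot table missing columns: {sorted(missing)}")
    if plots.empty:
        raise ValidationError("plot table is empty")
    if plots["plot_id"].duplicated().any():
        raise ValidationError("plot_id values must be unique")
    if (plots["yield_kg"] <= 0).any():
        raise ValidationError("yields must be positive")
    return plots


def validate_observation_table(obs: pd.DataFrame, value_columns=None) -> pd.DataFrame:
    required = {"plot_id", "stage"}
    missing = required - set(obs.columns)
    if missing:
        raise ValidationError(f"observation table missing columns: {sorted(missing)}")
    bad = set(obs["stage"]) - set(STAGES)
    if bad:
        raise ValidationError(f"unknown stage labels: {sorted(bad)}")
    if obs.duplicated(subset=["plot_id", "stage"]).any():
        raise ValidationError("duplicate (plot_id, stage) rows")
    counts = obs.groupby("plot_id")["stage"].nunique()
    if (counts != len(STAGES)).any():
        short = counts[counts != len(STAGES)].index.tolist()
        raise ValidationError(f"incomplete plot x stage grid for plots: {short}")
    cols = value_columns or [c for c in obs.columns if c not in ("plot_id", "stage")]
    if obs[cols].isna().any().any():
        raise ValidationError("observation table has missing cells")
    return obs


def select_reference(plots: pd.DataFrame, strategy: str = "designated",
                     designated: dict | str | None = None):
    """Pick the reference plot.

    ``designated`` (default): the plot named by a treatment dict
    (water/nitrogen/replicate, default NM x N2 replicate 1) or directly by
    plot_id.  ``median_yield``: the plot holding the lower median yield
    (element ``(n-1)//2`` of the sorted yields; ties resolve to the first
    such plot in plot_id order).
    """
    plots = validate_plot_table(plots)
    if strategy == "designated":
        spec = designated if designated is not None else DEFAULT_REFERENCE_TREATMENT
        if isinstance(spec, str):
            if spec not in set(plots["plot_id"]):
                raise ValidationError(f"designated reference plot {spec!r} not in plot table")
            return spec
        mask = np.ones(len(plots), dtype=bool)
        for key, val in spec.items():
            mask &= (plots[key] == val).to_numpy()
        hits = plots.loc[mask, "plot_id"]
        if hits.empty:
            raise ValidationError(f"no plot matches designated treatment {spec}")
        return hits.iloc[0]
    if strategy == "median_yield":
        ordered = plots.sort_values(["yield_kg", "plot_id"], kind="stable")
        return ordered["plot_id"].iloc[(len(ordered) - 1) // 2]
    raise ValidationError(f"unknown reference strategy {strategy!r}")


def relativize_table(obs: pd.DataFrame, plots: pd.DataFrame, ref,
                     value_columns=None) -> tuple[pd.DataFrame, pd.Series]:
    """Subtract the reference plot's same-stage values and reference yield.

    Returns ``(relative observation table, relative yield Series indexed by
    plot_id)``.  The reference plot's relative values are exactly 0 at every
    stage.  Raises listing the stages if the reference plot is missing any
    stage observation.
    """
    plots = validate_plot_table(plots)
    if ref not in set(plots["plot_id"]):
        raise ValidationError(f"reference plot {ref!r} not in plot table")
    if {"plot_id", "stage"} - set(obs.columns):
        raise ValidationError("observation table needs plot_id and stage columns")
    cols = value_columns or [c for c in obs.columns if c not in ("plot_id", "stage")]
    ref_rows = obs[obs["plot_id"] == ref].set_index("stage")
    missing = [s for s in STAGES if s not in ref_rows.index]
    if missing:
        raise ValidationError(f"reference plot {ref!r} missing observations at stages: {missing}")
    obs = validate_observation_table(obs, value_columns)
    rel = obs.copy()
    for col in cols:
        rel[col] = obs[col].to_numpy() - ref_rows.loc[obs["stage"], col].to_numpy()
    rel.attrs["relativized"] = True
    rel.attrs["reference_plot"] = ref
    yields = plots.set_index("plot_id")["yield_kg"]
    rel_yield = yields - yields.loc[ref]
    rel_yield.name = "relative_yield"
    rel_yield.attrs["reference_plot"] = ref
    rel_yield.attrs["reference_yield"] = float(yields.loc[ref])
    return rel, rel_yield


class StageRelativizer(BaseEstimator, TransformerMixin):
    """Transformer subtracting one reference row from a plots x stages matrix.

    ``fit`` records the reference row (by positional index or label for a
    DataFrame); ``transform`` subtracts it from every row, so the reference
    row maps to zero and all pairwise row differences are preserved exactly.
    """

    def __init__(self, reference=0):
        self.reference = reference

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            ref_row = X.loc[self.reference] if self.reference in X.index else X.iloc[self.reference]
            self.reference_row_ = ref_row.to_numpy(dtype=float)
            self.feature_names_in_ = np.asarray(X.columns)
        else:
            X = np.asarray(X, dtype=float)
            self.reference_row_ = X[self.reference].copy()
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X - self.reference_row_
        return np.asarray(X, dtype=float) - self.reference_row_
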