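"""End-to-end orchestration: spectra -> indices -> relative variables ->
growth-stage weights -> single-stage and weighted yield models -> LOOCV.

The pipeline consumes the fixture tree written by the simulator (or by a
real campaign arranged the same way: ``plots.csv``, ``lai.csv``,
``dryweight.csv``, ``manifest.csv`` + ``spectra/``) and emits a report with
one row per fitted model — five single-stage and three weighted models for
each of the two working variables (the red-edge chlorophyll index and LAI)
— plus the stage-weight audit, the correlation screen and the pooled
multi-period correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError
from .growth import (STAGES, StageCalendar, fit_slogistic, rank_stages,
                     read_dry_weight_csv, stage_boundaries)
from .regression import (correlation_screen, fit_linear, loocv,
                         pooled_multiperiod_correlation, stage_matrix,
                         weighted_composite)
from .relativize import relativize_table, select_reference, validate_plot_table
from .simulate import TrialConfig, TrialData, simulate_trial
from .spectra import indices_from_manifest
from .weights import (DEFAULT_COMPARISON, entropy_weights, iahp_weights,
                      ocw_weights, read_comparison_csv)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "load_fixture_tree",
           "write_report"]

log = logging.getLogger("stageyield")

#: The two working variables the yield models are built on.
MODEL_VARIABLES = ("CIrededge", "lai")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, in one place.

    ``data_dir`` points at a fixture tree; if None, a synthetic trial is
    generated from ``trial`` (seeded).  The remaining fields mirror the
    method's decision points: band window, reference-plot rule, comparison
    matrix, entropy normalization, combination coefficient, stage calendar.
    """

    data_dir: str | None = None
    trial: TrialConfig = dataclass_field(default_factory=TrialConfig)
    half_window_nm: float = 2.5
    reference_strategy: str = "designated"
    designated_reference: str | dict | None = None
    comparison_matrix_path: str | None = None
    ew_normalization: str = "minmax_shift"
    alpha: float = 0.7
    calendar: StageCalendar = dataclass_field(default_factory=StageCalendar)
    exclude_reference: bool = True

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "trial" in raw:
            raw["trial"] = TrialConfig(**{k: tuple(v) if isinstance(v, list) else v
                                          for k, v in raw["trial"].items()})
        if "calendar" in raw:
            raw["calendar"] = StageCalendar(**raw["calendar"])
        return cls(**raw)


@dataclass
class PipelineReport:
    """All pipeline outputs; every table is a plain DataFrame/Series."""

    reference_plot: str
    reference_yield: float
    slogistic: dict
    partition: dict
    stage_ranking: list
    weights: pd.DataFrame  # one row per (method, variable)
    models: pd.DataFrame  # 16 rows: variable x (stage | weighting method)
    screen: pd.DataFrame  # stages x variables Pearson r
    pooled_r_absolute: pd.Series
    pooled_r_relative: pd.Series


def load_fixture_tree(data_dir, half_window_nm: float = 2.5):
    """Read a fixture tree and compute indices from its spectra."""
    data_dir = Path(data_dir)
    plots = validate_plot_table(pd.read_csv(data_dir / "plots.csv"))
    lai = pd.read_csv(data_dir / "lai.csv")
    vis = indices_from_manifest(data_dir / "manifest.csv", half_window_nm=half_window_nm)
    obs = lai.merge(vis, on=["plot_id", "stage"], how="outer")
    if obs.isna().any().any():
        raise ValidationError("lai.csv and manifest.csv cover different (plot, stage) sets")
    dry = read_dry_weight_csv(data_dir / "dryweight.csv")
    return plots, obs, dry


def _fit_model_row(x, y, ref_yield):
    fit = fit_linear(x, y)
    cv = loocv(x, y, ref_yield=ref_yield)
    return {
        "slope": fit.slope, "intercept": fit.intercept,
        "adj_r2": fit.adj_r2, "rmse": fit.rmse,
        "f_stat": fit.f_stat, "p_value": fit.p_value,
        "significant_001": fit.significant_001, "n": fit.n,
        "rmse_cv": cv.rmse_cv, "mre": cv.mre,
        "r2_cv_mean": cv.r2_mean, "r2_cv_pooled": cv.r2_pooled,
    }


def run_pipeline(cfg: PipelineConfig | None = None,
                 trial: TrialData | None = None) -> PipelineReport:
    """Execute the full weighted-growth-stage estimation workflow."""
    cfg = cfg or PipelineConfig()

    # ---- inputs ---------------------------------------------------------
    if trial is not None:
        plots, obs, dry = trial.plots, trial.observations, trial.dry_weight
    elif cfg.data_dir is not None:
        plots, obs, dry = load_fixture_tree(cfg.data_dir, cfg.half_window_nm)
    else:
        sim = simulate_trial(cfg.trial)
        plots, obs, dry = sim.plots, sim.observations, sim.dry_weight

    # ---- reference plot and relative variables --------------------------
    ref = select_reference(plots, strategy=cfg.reference_strategy,
                           designated=cfg.designated_reference)
    ref_yield = float(plots.set_index("plot_id").loc[ref, "yield_kg"])
    log.info("reference plot: %s (yield %.3f kg)", ref, ref_yield)
    rel_obs, rel_yield = relativize_table(obs, plots, ref)

    # ---- growth curve and stage partition -------------------------------
    params = fit_slogistic(dry["day"], dry["dry_weight_g"])
    partition = stage_boundaries(params, cfg.calendar)
    ranking = rank_stages(params, partition)
    log.info("rapid phase: day %.1f to %.1f; stage ranking %s",
             partition.t_low, partition.t_high, " > ".join(ranking))

    # ---- stage weights ---------------------------------------------------
    A = (read_comparison_csv(cfg.comparison_matrix_path)
         if cfg.comparison_matrix_path else DEFAULT_COMPARISON)
    w_iahp, _ = iahp_weights(A)
    weight_rows = []
    weights_by = {}
    for var in MODEL_VARIABLES:
        G = stage_matrix(rel_obs, var)
        w_ew, _ = entropy_weights(G, normalization=cfg.ew_normalization)
        w_ocw, _ = ocw_weights(w_iahp, w_ew, alpha=cfg.alpha)
        weights_by[("IAHP", var)] = w_iahp
        weights_by[("EW", var)] = w_ew
        weights_by[("OCW", var)] = w_ocw
        for method, wv in (("IAHP", w_iahp), ("EW", w_ew), ("OCW", w_ocw)):
            weight_rows.append({"method": method, "variable": var,
                                **dict(zip(STAGES, wv.w))})
    log.info("combination coefficient alpha = %.3f", cfg.alpha)
    weights_df = pd.DataFrame(weight_rows)

    # ---- model fitting ---------------------------------------------------
    fit_obs = rel_obs[rel_obs["plot_id"] != ref] if cfg.exclude_reference else rel_obs
    fit_yield = rel_yield.drop(ref) if cfg.exclude_reference else rel_yield
    model_rows = []
    for var in MODEL_VARIABLES:
        wide = stage_matrix(fit_obs, var)
        y = fit_yield.loc[wide.index].to_numpy()
        for stage in STAGES:
            row = _fit_model_row(wide[stage].to_numpy(), y, ref_yield)
            model_rows.append({"variable": var, "weighting": "single", "stage": stage, **row})
        for method in ("IAHP", "EW", "OCW"):
            comp = weighted_composite(fit_obs, weights_by[(method, var)], var)
            row = _fit_model_row(comp.loc[wide.index].to_numpy(), y, ref_yield)
            model_rows.append({"variable": var, "weighting": method, "stage": "weighted", **row})
    models = pd.DataFrame(model_rows)

    # ---- screening and pooled diagnostics --------------------------------
    screen = correlation_screen(fit_obs, fit_yield)["r"]
    value_cols = [c for c in obs.columns if c not in ("plot_id", "stage")]
    abs_yield = plots.set_index("plot_id")["yield_kg"]
    pooled_abs = pooled_multiperiod_correlation(obs, abs_yield, value_cols)
    pooled_rel = pooled_multiperiod_correlation(rel_obs, rel_yield, value_cols)

    return PipelineReport(
        reference_plot=str(ref),
        reference_yield=ref_yield,
        slogistic={"a": params.a, "b": params.b, "k": params.k,
                   "adj_r2": params.adj_r2, "n_obs": params.n_obs},
        partition={"t_low": partition.t_low, "t_inflect": partition.t_inflect,
                   "t_high": partition.t_high,
                   "stage_windows": {s: list(w) for s, w in partition.stage_windows.items()}},
        stage_ranking=list(ranking),
        weights=weights_df,
        models=models,
        screen=screen,
        pooled_r_absolute=pooled_abs,
        pooled_r_relative=pooled_rel,
    )


def write_report(report: PipelineReport, outdir) -> Path:
    """Serialize a report to CSV/JSON files under ``outdir``."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.models.to_csv(outdir / "models.csv", index=False)
    report.weights.to_csv(outdir / "weights.csv", index=False)
    report.screen.to_csv(outdir / "screen.csv")
    pooled = pd.DataFrame({"absolute": report.pooled_r_absolute,
                           "relative": report.pooled_r_relative})
    pooled.to_csv(outdir / "pooled_correlations.csv")
    meta = {
        "reference_plot": report.reference_plot,
        "reference_yield": report.reference_yield,
        "slogistic": report.slogistic,
        "partition": report.partition,
        "stage_ranking": report.stage_ranking,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return outdir
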