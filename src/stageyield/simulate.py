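"""Synthetic water x nitrogen potato trial generator.

Emulates the measurement campaign the weighted-growth-stage method expects:
27 plots (3 water x 3 nitrogen x 3 replicates), five measurement stages,
a 17-date dry-weight series following a Slogistic curve, plot-level canopy
spectra, per-stage LAI, and plot yields driven predominantly by mid-season
canopy state.

Mechanism, per plot p and stage t:

* growth amplitude ``a_p = a * m_water * m_nitrogen * exp(eps_p)`` with
  lognormal replicate scatter;
* ``LAI(p, t) = lai_per_dry_g * Slogistic(a_p, b, k)(day_t) * lognormal noise``;
* canopy reflectance is a Beer-Lambert linear mixture
  ``R = f * R_veg + (1 - f) * R_soil + delta_t + noise`` with cover fraction
  ``f = 1 - exp(-extinction * LAI)`` and fixed tabulated vegetation/soil
  endmember spectra (400-900 nm); the per-stage offsets ``delta_t`` are the
  shared illumination/background confound that subtraction-based
  relativization removes;
* ``yield_p = c0 + c1 * sum_t w*_t LAI(p, t) + Gaussian noise`` — the
  coupling weights ``w*`` peak at tuber expansion (TES).

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .growth import STAGES, slogistic
from .spectra import Spectrum, all_indices, extract_bands

__all__ = [
    "TrialConfig",
    "TrialData",
    "simulate_trial",
    "ground_truth",
    "write_fixture_tree",
    "vegetation_endmember",
    "soil_endmember",
]

_ENDMEMBER_WL = np.arange(400.0, 901.0, 10.0)

# Green potato-canopy endmember: chlorophyll absorption wells at blue/red,
# green bump at ~550 nm, red-edge rise to a NIR plateau.
_VEG_REFLECTANCE = np.array([
    0.030, 0.032, 0.033, 0.034, 0.035, 0.037, 0.039, 0.042, 0.047, 0.054,
    0.065, 0.080, 0.100, 0.115, 0.123, 0.125, 0.122, 0.115, 0.105, 0.095,
    0.085, 0.075, 0.066, 0.058, 0.052, 0.047, 0.043, 0.040, 0.042, 0.060,
    0.100, 0.170, 0.260, 0.360, 0.440, 0.490, 0.510, 0.520, 0.525, 0.528,
    0.530, 0.531, 0.532, 0.533, 0.533, 0.534, 0.534, 0.535, 0.535, 0.535,
    0.535,
])

# Dry-soil endmember: featureless, slowly brightening with wavelength.
_SOIL_REFLECTANCE = 0.10 + 0.22 * (_ENDMEMBER_WL - 400.0) / 500.0


def vegetation_endmember(wavelength_nm) -> np.ndarray:
    """Tabulated vegetation endmember interpolated to the requested grid."""
    return np.interp(np.asarray(wavelength_nm, dtype=float), _ENDMEMBER_WL, _VEG_REFLECTANCE)


def soil_endmember(wavelength_nm) -> np.ndarray:
    """Tabulated soil endmember interpolated to the requested grid."""
    return np.interp(np.asarray(wavelength_nm, dtype=float), _ENDMEMBER_WL, _SOIL_REFLECTANCE)


@dataclass(frozen=True)
class TrialConfig:
    """Study conditions for one simulated trial.

    Defaults follow the emulated campaign: a May-sown season with stage
    measurement days 43/57/82/99/117 after sowing, 17 dry-weight sampling
    dates, a Slogistic base curve whose rapid phase spans days 60-86
    (k = 2 ln(2+sqrt 3)/26, inflection at day 73), mid-season-peaked yield
    coupling, and measurement noise typical of SUNSCAN LAI (~10%) and
    field spectroradiometry.
    """

    seed: int = 42
    n_water: int = 3
    n_nitrogen: int = 3
    n_reps: int = 3
    # Slogistic base curve (g/plant, -, 1/day)
    a: float = 100.0
    b: float = 1627.5
    k: float = 0.101304
    water_multipliers: tuple = (0.92, 1.00, 0.80)  # EM, NM, IM on a
    nitrogen_multipliers: tuple = (0.85, 1.00, 1.05)  # N1, N2, N3 on a
    plot_sigma: float = 0.08  # lognormal replicate scatter on a_p
    # measurement calendar (days after sowing)
    stage_days: tuple = (43.0, 57.0, 82.0, 99.0, 117.0)
    dry_weight_days: tuple = (43, 51, 54, 57, 60, 68, 72, 75, 78, 82,
                              90, 93, 96, 99, 106, 111, 117)
    # LAI and yield coupling
    lai_per_dry_g: float = 0.045  # LAI per g/plant of dry matter
    yield_weights: tuple = (0.05, 0.15, 0.45, 0.25, 0.10)  # w*, sums to 1
    yield_c0: float = 4.0  # kg/plot
    yield_c1: float = 3.0  # kg/plot per unit of weighted LAI
    # noise levels
    lai_sigma: float = 0.10  # lognormal, multiplicative
    yield_sigma: float = 0.25  # kg/plot, additive Gaussian
    spectral_sigma: float = 0.005  # reflectance units, per wavelength
    dry_weight_sigma: float = 0.05  # lognormal, multiplicative
    # optics
    extinction: float = 0.5  # Beer-Lambert cover-fraction coefficient
    stage_offsets: tuple = (0.030, -0.020, 0.015, -0.025, 0.020)  # delta_t
    wavelength_start: float = 400.0
    wavelength_stop: float = 900.0
    wavelength_step: float = 1.0

    def __post_init__(self):
        for name in ("plot_sigma", "lai_sigma", "yield_sigma", "spectral_sigma",
                     "dry_weight_sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if len(self.yield_weights) != len(STAGES):
            raise ValidationError("yield_weights must have one entry per stage")
        if abs(sum(self.yield_weights) - 1.0) > 1e-9:
            raise ValidationError("yield_weights must sum to 1")
        if len(self.stage_days) != len(STAGES):
            raise ValidationError("stage_days must have one entry per stage")
        if len(self.stage_offsets) != len(STAGES):
            raise ValidationError("stage_offsets must have one entry per stage")
        if not (self.a > 0 and self.b > 0 and self.k > 0):
            raise ValidationError("Slogistic base parameters must be positive")
        if len(self.dry_weight_days) < 5:
            raise ValidationError("need at least 5 dry-weight sampling dates")


@dataclass
class TrialData:
    """Output bundle of :func:`simulate_trial`."""

    plots: pd.DataFrame  # plot_id, water, nitrogen, replicate, yield_kg
    observations: pd.DataFrame  # plot_id, stage, lai, and the six indices
    dry_weight: pd.DataFrame  # day, dry_weight_g
    spectra: dict  # (plot_id, stage) -> Spectrum
    truth: dict  # generating parameters, for recovery tests


def ground_truth(cfg: TrialConfig) -> dict:
    """Generating parameters of a trial, for recovery tests."""
    water = ["EM", "NM", "IM"][: cfg.n_water]
    nitrogen = ["N1", "N2", "N3"][: cfg.n_nitrogen]
    return {
        "yield_weights": dict(zip(STAGES, cfg.yield_weights)),
        "slogistic": {"a": cfg.a, "b": cfg.b, "k": cfg.k},
        "water_multipliers": dict(zip(water, cfg.water_multipliers)),
        "nitrogen_multipliers": dict(zip(nitrogen, cfg.nitrogen_multipliers)),
        "stage_days": dict(zip(STAGES, cfg.stage_days)),
        "yield_c0": cfg.yield_c0,
        "yield_c1": cfg.yield_c1,
        "stage_offsets": dict(zip(STAGES, cfg.stage_offsets)),
    }


def simulate_trial(cfg: TrialConfig | None = None) -> TrialData:
    """Simulate one complete trial; deterministic given ``cfg.seed``."""
    cfg = cfg or TrialConfig()
    rng = np.random.default_rng(cfg.seed)
    water_levels = ["EM", "NM", "IM"][: cfg.n_water]
    nitrogen_levels = ["N1", "N2", "N3"][: cfg.n_nitrogen]
    wl = np.arange(cfg.wavelength_start, cfg.wavelength_stop + cfg.wavelength_step / 2,
                   cfg.wavelength_step)
    veg = vegetation_endmember(wl)
    soil = soil_endmember(wl)

    plot_rows, obs_rows, spectra = [], [], {}
    for wi, w in enumerate(water_levels):
        for ni, n in enumerate(nitrogen_levels):
            for rep in range(1, cfg.n_reps + 1):
                plot_id = f"{w}-{n}-{rep}"
                eps = rng.normal(0.0, cfg.plot_sigma) if cfg.plot_sigma > 0 else 0.0
                a_p = cfg.a * cfg.water_multipliers[wi] * cfg.nitrogen_multipliers[ni] * np.exp(eps)
                lai_true = cfg.lai_per_dry_g * slogistic(np.array(cfg.stage_days), a_p, cfg.b, cfg.k)
                lai_noise = (np.exp(rng.normal(0.0, cfg.lai_sigma, size=len(STAGES)))
                             if cfg.lai_sigma > 0 else np.ones(len(STAGES)))
                lai = lai_true * lai_noise
                yld = (cfg.yield_c0
                       + cfg.yield_c1 * float(np.dot(cfg.yield_weights, lai))
                       + (rng.normal(0.0, cfg.yield_sigma) if cfg.yield_sigma > 0 else 0.0))
                if yld <= 0:
                    raise ValidationError(
                        f"simulated yield for {plot_id} is nonpositive; lower the noise levels"
                    )
                plot_rows.append({"plot_id": plot_id, "water": w, "nitrogen": n,
                                  "replicate": rep, "yield_kg": yld})
                for si, stage in enumerate(STAGES):
                    f = 1.0 - np.exp(-cfg.extinction * lai[si])
                    refl = f * veg + (1.0 - f) * soil + cfg.stage_offsets[si]
                    if cfg.spectral_sigma > 0:
                        refl = refl + rng.normal(0.0, cfg.spectral_sigma, size=wl.size)
                    refl = np.clip(refl, 1e-4, 1.5)
                    spec = Spectrum(wl, refl)
                    spectra[(plot_id, stage)] = spec
                    obs_rows.append({"plot_id": plot_id, "stage": stage,
                                     "lai": float(lai[si]),
                                     **all_indices(extract_bands(spec))})

    days = np.asarray(cfg.dry_weight_days, dtype=float)
    dw_true = slogistic(days, cfg.a, cfg.b, cfg.k)
    dw_noise = (np.exp(rng.normal(0.0, cfg.dry_weight_sigma, size=days.size))
                if cfg.dry_weight_sigma > 0 else np.ones(days.size))
    dry_weight = pd.DataFrame({"day": days, "dry_weight_g": dw_true * dw_noise})

    return TrialData(
        plots=pd.DataFrame(plot_rows),
        observations=pd.DataFrame(obs_rows),
        dry_weight=dry_weight,
        spectra=spectra,
        truth=ground_truth(cfg),
    )


def write_fixture_tree(trial: TrialData, outdir, float_format: str = "%.10g") -> Path:
    """Write the full fixture tree for the CLI pipeline.

    Layout: ``plots.csv``, ``lai.csv``, ``dryweight.csv``,
    ``spectra/<plot>_<stage>.txt``, ``manifest.csv`` and ``truth.json``.
    """
    outdir = Path(outdir)
    (outdir / "spectra").mkdir(parents=True, exist_ok=True)
    trial.plots.to_csv(outdir / "plots.csv", index=False, float_format=float_format)
    trial.observations[["plot_id", "stage", "lai"]].to_csv(
        outdir / "lai.csv", index=False, float_format=float_format)
    trial.dry_weight.rename(columns={"dry_weight_g": "dry_weight_g"}).to_csv(
        outdir / "dryweight.csv", index=False, float_format=float_format)
    manifest = []
    for (plot_id, stage), spec in trial.spectra.items():
        rel = f"spectra/{plot_id}_{stage}.txt"
        with open(outdir / rel, "w") as fh:
            fh.write("# wavelength_nm reflectance\n")
            for lam, r in zip(spec.wavelength_nm, spec.reflectance):
                fh.write(f"{lam:.2f} {r:.6f}\n")
        manifest.append({"plot_id": plot_id, "stage": stage, "path": rel})
    pd.DataFrame(manifest).to_csv(outdir / "manifest.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(trial.truth, fh, indent=2, sort_keys=True)
    return outdir
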