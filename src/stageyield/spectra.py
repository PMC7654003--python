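"""Canopy reflectance spectra, working-band extraction and vegetation indices.

A plot-level canopy spectrum is a two-column table of wavelength (nm) and
reflectance (unitless, whiteboard-relative so values slightly above 1 are
tolerated).  Four working bands are taken as windowed means around the
green (550 nm), red (670 nm), red-edge (720 nm) and near-infrared (800 nm)
centres, and six standard vegetation indices are computed from them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CoverageError, SpectrumParseError, UndefinedIndexError, ValidationError

__all__ = [
    "BAND_CENTERS_NM",
    "VEGETATION_INDICES",
    "BandReflectance",
    "Spectrum",
    "read_spectrum",
    "extract_bands",
    "vegetation_index",
    "all_indices",
    "indices_from_manifest",
]

#: Band centres (nm) used by every index formula.
BAND_CENTERS_NM = {"r550": 550.0, "r670": 670.0, "r720": 720.0, "r800": 800.0}

#: Canonical index names, in reporting order.
VEGETATION_INDICES = ("NDVI", "CIrededge", "CIgreen", "EVI2", "NDRE", "MTCI")

#: Wavelength range (nm) a spectrum must cover before bands can be extracted.
REQUIRED_COVERAGE_NM = (545.0, 805.0)

_MAX_REFLECTANCE = 1.5


@dataclass(frozen=True)
class Spectrum:
    """One plot-stage reflectance measurement.

    Wavelengths are sorted strictly increasing on construction; duplicate
    wavelengths are averaged into a single sample.  Negative reflectance is
    rejected; values up to 1.5 are tolerated (whiteboard-relative calibration
    can exceed 1).
    """

    wavelength_nm: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        rf = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or rf.ndim != 1 or wl.size != rf.size:
            raise ValidationError("wavelength and reflectance must be equal-length 1-D arrays")
        if wl.size == 0:
            raise ValidationError("empty spectrum")
        if not (np.isfinite(wl).all() and np.isfinite(rf).all()):
            raise ValidationError("non-finite values in spectrum")
        order = np.argsort(wl, kind="stable")
        wl, rf = wl[order], rf[order]
        if np.any(np.diff(wl) == 0.0):
            # average duplicate wavelengths into one sample each
            uniq, inverse = np.unique(wl, return_inverse=True)
            sums = np.bincount(inverse, weights=rf)
            counts = np.bincount(inverse)
            wl, rf = uniq, sums / counts
        if np.any(rf < 0.0):
            raise ValidationError("negative reflectance values are not physical")
        if np.any(rf > _MAX_REFLECTANCE):
            raise ValidationError(
                f"reflectance above {_MAX_REFLECTANCE} exceeds the calibration tolerance"
            )
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "reflectance", rf)

    def __len__(self):
        return self.wavelength_nm.size

    def covers(self, lo_nm: float, hi_nm: float) -> bool:
        return self.wavelength_nm[0] <= lo_nm and self.wavelength_nm[-1] >= hi_nm


@dataclass(frozen=True)
class BandReflectance:
    """Mean reflectance in the four working bands."""

    r550: float
    r670: float
    r720: float
    r800: float

    def __post_init__(self):
        for name in ("r550", "r670", "r720", "r800"):
            v = getattr(self, name)
            if not (0.0 < v <= _MAX_REFLECTANCE):
                raise ValidationError(f"band {name}={v!r} outside (0, {_MAX_REFLECTANCE}]")

    def scaled(self, c: float) -> "BandReflectance":
        return BandReflectance(self.r550 * c, self.r670 * c, self.r720 * c, self.r800 * c)


_SPLIT = re.compile(r"[,\s]+")


def read_spectrum(path) -> Spectrum:
    """Read a two-column ASCII spectrum (wavelength nm, reflectance).

    Whitespace- or comma-delimited; blank lines and ``#`` comments are
    skipped; out-of-order rows are sorted and duplicated wavelengths
    averaged.  Raises :class:`SpectrumParseError` naming the offending line,
    or :class:`CoverageError` if the file does not span 545-805 nm.
    """
    path = Path(path)
    wl, rf = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = [p for p in _SPLIT.split(line) if p]
            try:
                if len(parts) != 2:
                    raise ValueError("expected two columns")
                wl.append(float(parts[0]))
                rf.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(f"{path}, line {lineno}: {raw.strip()!r} ({exc})") from None
    if not wl:
        raise SpectrumParseError(f"{path}: no data rows")
    spec = Spectrum(np.array(wl), np.array(rf))
    lo, hi = REQUIRED_COVERAGE_NM
    if not spec.covers(lo, hi):
        raise CoverageError(
            f"{path}: spectrum spans [{spec.wavelength_nm[0]:g}, "
            f"{spec.wavelength_nm[-1]:g}] nm, must cover [{lo:g}, {hi:g}] nm"
        )
    return spec


def extract_bands(spec: Spectrum, half_window_nm: float = 2.5) -> BandReflectance:
    """Windowed-mean band extraction.

    Each band is the arithmetic mean of reflectance samples with wavelength
    in ``[center - w, center + w]``.  Raises :class:`CoverageError` naming
    the band if a window contains no samples.
    """
    if half_window_nm <= 0:
        raise ValidationError("half_window_nm must be positive")
    out = {}
    for name, center in BAND_CENTERS_NM.items():
        mask = np.abs(spec.wavelength_nm - center) <= half_window_nm
        if not mask.any():
            raise CoverageError(
                f"no spectral samples within +/-{half_window_nm:g} nm of the "
                f"{name} band ({center:g} nm)"
            )
        out[name] = float(spec.reflectance[mask].mean())
    return BandReflectance(**out)


def vegetation_index(bands: BandReflectance, name: str) -> float:
    """Compute one of the six supported vegetation indices from band means.

    NDVI = (r800-r670)/(r800+r670); CIrededge = r800/r720 - 1;
    CIgreen = r800/r550 - 1; EVI2 = 2.5(r800-r670)/(1+r800+2.4 r670);
    NDRE = (r800-r720)/(r800+r720); MTCI = (r800-r720)/(r720-r670).
    """
    r550, r670, r720, r800 = bands.r550, bands.r670, bands.r720, bands.r800

    def _div(num, den):
        if den == 0.0:
            raise UndefinedIndexError(f"{name}: zero denominator")
        return num / den

    if name == "NDVI":
        return _div(r800 - r670, r800 + r670)
    if name == "CIrededge":
        return _div(r800, r720) - 1.0
    if name == "CIgreen":
        return _div(r800, r550) - 1.0
    if name == "EVI2":
        return _div(2.5 * (r800 - r670), 1.0 + r800 + 2.4 * r670)
    if name == "NDRE":
        return _div(r800 - r720, r800 + r720)
    if name == "MTCI":
        return _div(r800 - r720, r720 - r670)
    raise ValidationError(f"unknown vegetation index {name!r}; choose from {VEGETATION_INDICES}")


def all_indices(bands: BandReflectance) -> dict:
    """All six indices as a name -> value mapping."""
    return {name: vegetation_index(bands, name) for name in VEGETATION_INDICES}


def indices_from_manifest(manifest_path, half_window_nm: float = 2.5) -> pd.DataFrame:
    """Compute the six indices for every spectrum listed in a manifest CSV.

    The manifest has columns ``plot_id, stage, path`` (paths relative to the
    manifest's directory or absolute).  Returns a tidy frame keyed by
    (plot_id, stage) with one column per index.  A missing or unreadable
    spectrum raises an error naming the (plot, stage) pair.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    missing = {"plot_id", "stage", "path"} - set(manifest.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    rows = []
    for rec in manifest.itertuples(index=False):
        spec_path = Path(rec.path)
        if not spec_path.is_absolute():
            spec_path = manifest_path.parent / spec_path
        try:
            spec = read_spectrum(spec_path)
        except (OSError, SpectrumParseError, CoverageError) as exc:
            raise ValidationError(
                f"spectrum for plot {rec.plot_id!r}, stage {rec.stage!r}: {exc}"
            ) from exc
        bands = extract_bands(spec, half_window_nm=half_window_nm)
        rows.append({"plot_id": rec.plot_id, "stage": rec.stage, **all_indices(bands)})
    return pd.DataFrame(rows)
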