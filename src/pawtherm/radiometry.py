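"""Radiometric emissivity correction and blackbody calibration QC.

A microbolometer camera reports an *apparent* temperature that mixes the
radiance emitted by the target with radiance from the surroundings
reflected off it. For a grey body of emissivity eps viewed through a
transparent 20 cm air path, the band-integrated Stefan-Boltzmann model

    W(T_app) = eps * W(T_obj) + (1 - eps) * W(T_refl),   W(T) = T_K**4

lets the true surface temperature be recovered by inverting the mixture.
All arithmetic is done in Kelvin; inputs and outputs are Celsius.

The module also fits the linear calibration curve of camera readings
against blackbody reference sources and checks the maximum deviation
against an accuracy tolerance (the camera certification step that must
pass before any animal imaging).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "SKIN_EMISSIVITY",
    "FUR_EMISSIVITY",
    "BLACKBODY_EMISSIVITY",
    "KELVIN_OFFSET",
    "EmissivitySpec",
    "CalibrationResult",
    "AccuracyReport",
    "correct_apparent_temperature",
    "simulate_apparent_temperature",
    "fit_calibration",
    "accuracy_check",
]

#: Tissue emissivities used throughout the framework.
SKIN_EMISSIVITY = 0.98
FUR_EMISSIVITY = 0.94
#: Emissivity of the blackbody reference sources used for calibration.
BLACKBODY_EMISSIVITY = 0.95

KELVIN_OFFSET = 273.15

#: Camera scene range, Celsius.
SCENE_MIN_C = -20.0
SCENE_MAX_C = 120.0


@dataclass(frozen=True)
class EmissivitySpec:
    """Radiometric correction parameters for one material.

    Parameters
    ----------
    emissivity : float
        Grey-body emissivity in (0, 1]. 0.98 for mouse skin, 0.94 for fur.
    reflected_temp_c : float
        Effective temperature (Celsius) of the radiance reflected off the
        target, normally the ambient temperature of the imaging room.
    atmospheric_transmittance : float
        Transmittance of the air path in (0, 1]. Unity at the 20 cm
        working distance used here.
    """

    emissivity: float
    reflected_temp_c: float = 24.0
    atmospheric_transmittance: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.emissivity <= 1.0:
            raise ValueError(f"emissivity must be in (0, 1], got {self.emissivity}")
        if not 0.0 < self.atmospheric_transmittance <= 1.0:
            raise ValueError(
                "atmospheric_transmittance must be in (0, 1], "
                f"got {self.atmospheric_transmittance}"
            )
        if not SCENE_MIN_C <= self.reflected_temp_c <= SCENE_MAX_C:
            raise ValueError(
                f"reflected_temp_c {self.reflected_temp_c} outside scene range "
                f"[{SCENE_MIN_C}, {SCENE_MAX_C}] degC"
            )


def _check_scene_range(temp_c, name: str) -> np.ndarray:
    arr = np.asarray(temp_c, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if np.any(arr < SCENE_MIN_C) or np.any(arr > SCENE_MAX_C):
        raise ValueError(
            f"{name} outside camera scene range [{SCENE_MIN_C}, {SCENE_MAX_C}] degC"
        )
    return arr


def simulate_apparent_temperature(surface_c, spec: EmissivitySpec):
    """Forward model: apparent temperature the camera would report.

    T_app = (eps*T_obj_K**4 + (1-eps)*T_refl_K**4) ** (1/4), in Celsius.
    Exact algebraic inverse of :func:`correct_apparent_temperature`;
    identity for a perfect emitter (eps = 1). Accepts scalars or arrays.
    """
    surface = _check_scene_range(surface_c, "surface temperature")
    eps = spec.emissivity
    t_obj4 = (surface + KELVIN_OFFSET) ** 4
    t_refl4 = (spec.reflected_temp_c + KELVIN_OFFSET) ** 4
    apparent_k = (eps * t_obj4 + (1.0 - eps) * t_refl4) ** 0.25
    out = apparent_k - KELVIN_OFFSET
    return float(out) if np.isscalar(surface_c) else out


def correct_apparent_temperature(apparent_c, spec: EmissivitySpec):
    """Recover the true surface temperature from an apparent reading.

    Inverts the grey-body radiance mixture:
    T_obj = ((T_app_K**4 - (1-eps)*T_refl_K**4) / eps) ** (1/4), Celsius.

    Raises
    ------
    ValueError
        If the bracketed radicand is non-positive, i.e. the apparent
        reading is colder than the reflected component allows — a
        physically impossible input combination.
    """
    apparent = _check_scene_range(apparent_c, "apparent temperature")
    eps = spec.emissivity
    t_app4 = (apparent + KELVIN_OFFSET) ** 4
    t_refl4 = (spec.reflected_temp_c + KELVIN_OFFSET) ** 4
    radicand = (t_app4 - (1.0 - eps) * t_refl4) / eps
    if np.any(radicand <= 0.0):
        raise ValueError(
            "emissivity correction has non-positive radicand: apparent "
            "temperature is inconsistent with the reflected temperature "
            f"(eps={eps}, T_refl={spec.reflected_temp_c} degC)"
        )
    out = radicand**0.25 - KELVIN_OFFSET
    return float(out) if np.isscalar(apparent_c) else out


@dataclass(frozen=True)
class CalibrationResult:
    """Linear calibration of camera readings against blackbody references.

    slope/intercept are the OLS coefficients of mean reading vs. reference
    temperature; ``max_abs_dev_c`` is the largest absolute deviation of a
    mean reading from its reference value (the accuracy statistic, not a
    regression residual).
    """

    slope: float
    intercept_c: float
    r_squared: float
    max_abs_dev_c: float
    n_points: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared must be in [0, 1], got {self.r_squared}")
        if self.max_abs_dev_c < 0:
            raise ValueError("max_abs_dev_c must be >= 0")

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept_c": self.intercept_c,
            "r_squared": self.r_squared,
            "max_abs_dev_c": self.max_abs_dev_c,
            "n_points": self.n_points,
        }


def fit_calibration(series) -> CalibrationResult:
    """Fit the camera calibration line: mean reading vs. reference.

    Replicate readings at each reference temperature are averaged first
    (readings are reported as average of triplicates), then ordinary
    least squares is fit through the per-reference means.

    Parameters
    ----------
    series : CalibrationSeries or pandas.DataFrame
        Must expose columns ``reference_c`` and ``reading_c`` (one row
        per replicate), as produced by
        :func:`pawtherm.simulate.generate_calibration_series` or read
        from a calibration CSV.

    Raises
    ------
    ValueError
        Fewer than two distinct reference temperatures (degenerate
        design: the regression slope is unidentifiable).
    """
    frame = series.to_frame() if hasattr(series, "to_frame") else series
    refs_all = np.asarray(frame["reference_c"], dtype=float)
    readings_all = np.asarray(frame["reading_c"], dtype=float)
    if refs_all.size == 0:
        raise ValueError("calibration series is empty")

    refs = np.unique(refs_all)
    if refs.size < 2:
        raise ValueError(
            "calibration requires >= 2 distinct reference temperatures "
            "(zero variance in references: degenerate design)"
        )
    means = np.array([readings_all[refs_all == r].mean() for r in refs])

    fit = _sps.linregress(refs, means)
    r_squared = float(fit.rvalue**2)
    max_abs_dev = float(np.max(np.abs(means - refs)))
    return CalibrationResult(
        slope=float(fit.slope),
        intercept_c=float(fit.intercept),
        r_squared=min(r_squared, 1.0),
        max_abs_dev_c=max_abs_dev,
        n_points=int(refs.size),
    )


@dataclass(frozen=True)
class AccuracyReport:
    passed: bool
    max_abs_dev_c: float
    tolerance_c: float

    def as_dict(self) -> dict:
        return {
            "passed": self.passed,
            "max_abs_dev_c": self.max_abs_dev_c,
            "tolerance_c": self.tolerance_c,
        }


def accuracy_check(result: CalibrationResult, tolerance_c: float = 0.2) -> AccuracyReport:
    """Pass/fail camera accuracy gate: max deviation within tolerance.

    The default 0.2 degC tolerance is the accuracy required of the camera
    over the 35-40 degC mouse body-temperature range.
    """
    if tolerance_c <= 0:
        raise ValueError("tolerance_c must be > 0")
    return AccuracyReport(
        # small grace for float round-off in the deviation itself
        passed=result.max_abs_dev_c <= tolerance_c + 1e-9,
        max_abs_dev_c=result.max_abs_dev_c,
        tolerance_c=tolerance_c,
    )
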