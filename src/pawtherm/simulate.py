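"""Synthetic thermograms and collagen-induced-arthritis (CIA) cohorts.

Every downstream stage of the pipeline (ROI extraction, TI scoring,
severity classification, longitudinal statistics) is exercised here on
simulated data with the statistical structure the analysis assumes:

* **Phantom frames** — an 80x60 px thermogram of a prone mouse on a
  34 degC plate: a warm body ellipse at the back temperature, four paw
  ellipses at their own temperatures, i.i.d. Gaussian sensor noise
  (NETD 0.1 degC), painted at the exact geometry of the standard
  7-ellipse ROI layout so that zero-noise ROI means are bit-exact.

* **Cohorts** — 14 CIA mice (of which 2 non-responders) and 4 healthy
  controls measured on days 0, 7, 14, 21, 28. Responders ramp to a
  synchronized day-28 flare; non-responders and controls stay at
  baseline. Paw surface temperature, caliper thickness and the ordinal
  clinical score are all driven by one latent severity per animal
  (a shared mouse factor) plus modality-specific and per-paw noise, so
  cross-modality correlations are tunable without changing the marginal
  group distributions.

Default measurement model (all Celsius / mm, all tunable via
:class:`CohortConfig`): back temperature N(34.0, 0.2); baseline paw
temperature N(28.65, 0.35) for CIA and N(28.14, 0.35) for controls;
flared responder paws N(31.9, 0.5); per-paw thickness N(1.79, 0.13) at
baseline and N(2.65, 0.20) flared; ordinal scores by thresholding a
latent severity at (0.35, 0.65, 0.95, 1.25) with SD 0.25. These imply
per-paw TI near 0.843 (CIA baseline), 0.828 (control) and 0.938
(flared), i.e. TI_total near 3.37, 3.31 and 3.71.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from pawtherm.roi import (
    BACK_LABELS,
    BASE_BODY_ELLIPSE,
    PAW_LABELS,
    EllipseROI,
    ThermalFrame,
    default_roi_layout,
    ellipse_mask,
)

__all__ = [
    "CameraModel",
    "MouseState",
    "CohortConfig",
    "CohortStudy",
    "CalibrationSeries",
    "generate_phantom_frame",
    "generate_cohort",
    "generate_calibration_series",
    "phantom_frame_for_row",
    "temperature_mean",
    "thickness_mean",
    "expected_clinical_score",
]


@dataclass(frozen=True)
class CameraModel:
    """Thermal camera parameters (defaults: an 80x60 microbolometer
    with 0.1 degC noise-equivalent temperature difference and a
    -20..120 degC scene range)."""

    width_px: int = 80
    height_px: int = 60
    noise_sd: float = 0.1
    scene_min: float = -20.0
    scene_max: float = 120.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("camera dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.scene_min >= self.scene_max:
            raise ValueError("scene_min must be < scene_max")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.height_px, self.width_px)


@dataclass(frozen=True)
class MouseState:
    """Ground-truth surface temperatures of one animal at one timepoint.

    ``paw_temps`` are the FL, FR, HL, HR surface temperatures (degC);
    ``latent_severity`` the four unitless per-paw severities behind them.
    """

    paw_temps: Tuple[float, float, float, float]
    back_temp: float
    plate_temp: float = 34.0
    latent_severity: Tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.paw_temps) != 4 or len(self.latent_severity) != 4:
            raise ValueError("paw_temps and latent_severity must have 4 entries")
        if not all(np.isfinite(self.latent_severity)):
            raise ValueError("latent_severity must be finite")


def generate_phantom_frame(
    state: MouseState,
    camera: CameraModel = CameraModel(),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Tuple[ThermalFrame, Tuple[EllipseROI, ...]]:
    """Paint a piecewise-constant mouse phantom plus sensor noise.

    Background pixels sit at the plate temperature, the body ellipse at
    the back temperature and each paw ellipse at its own temperature;
    i.i.d. N(0, noise_sd) sensor noise is added on top. Returns the
    frame together with the ground-truth 7-ellipse ROI layout used, so
    ROI extraction can be validated bit-exactly at zero noise.
    """
    temps = list(state.paw_temps) + [state.back_temp, state.plate_temp]
    for t in temps:
        if not np.isfinite(t) or t < camera.scene_min or t > camera.scene_max:
            raise ValueError(
                f"temperature {t} degC outside camera scene range "
                f"[{camera.scene_min}, {camera.scene_max}]"
            )
    shape = camera.shape
    layout = default_roi_layout(shape)
    sx, sy = shape[1] / 80.0, shape[0] / 60.0
    cx, cy, a, b = BASE_BODY_ELLIPSE
    body = EllipseROI("body", cx * sx, cy * sy, a * sx, b * sy, 0.0, "fur")

    values = np.full(shape, float(state.plate_temp))
    values[ellipse_mask(body, shape)] = state.back_temp
    paw_temp = dict(zip(PAW_LABELS, state.paw_temps))
    for roi in layout:
        if roi.label in paw_temp:
            values[ellipse_mask(roi, shape)] = paw_temp[roi.label]
    if camera.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, camera.noise_sd, size=shape)
    frame = ThermalFrame(
        np.clip(values, camera.scene_min, camera.scene_max),
        metadata={"seed": seed, "plate_temp_c": state.plate_temp},
    )
    return frame, layout


# ---------------------------------------------------------------------------
# Cohort generation


def _as_mean_sd(pair: Sequence[float], name: str) -> Tuple[float, float]:
    mean, sd = float(pair[0]), float(pair[1])
    if sd < 0:
        raise ValueError(f"{name} SD must be >= 0, got {sd}")
    return mean, sd


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and measurement-model parameters.

    The defaults are the study conditions the pipeline is validated
    against: CIA n=14 with 2 non-responders, control n=4, weekly
    measurements to day 28 with an LPS-synchronized flare.

    Noise structure: each measurement deviates from its group mean by
    ``sd * (m + kappa*u + lambda*w) / sqrt(1 + kappa^2 + lambda^2)``
    where ``m`` is the persistent per-mouse latent-severity factor
    shared across modalities and days, ``u`` a modality-specific
    per-mouse-day factor and ``w`` per-paw noise. ``kappa`` is
    ``cross_modality_noise`` (larger = weaker coupling between TI,
    thickness and clinical score); ``lambda`` is the per-modality paw
    scatter. Marginal group SDs are unchanged by either knob.
    """

    n_cia: int = 14
    n_control: int = 4
    n_nonresponders: int = 2
    days: Tuple[int, ...] = (0, 7, 14, 21, 28)
    seed: int = 0

    plate_temp: float = 34.0
    back_temp: Tuple[float, float] = (34.0, 0.2)
    back_roi_scatter: float = 0.05

    cia_baseline_temp: Tuple[float, float] = (28.65, 0.35)
    control_baseline_temp: Tuple[float, float] = (28.14, 0.35)
    flare_temp: Tuple[float, float] = (31.9, 0.5)

    baseline_thickness: Tuple[float, float] = (1.79, 0.13)
    flare_thickness: Tuple[float, float] = (2.65, 0.20)

    clinical_latent_sd: float = 0.25
    clinical_thresholds: Tuple[float, float, float, float] = (0.35, 0.65, 0.95, 1.25)

    cross_modality_noise: float = 4.0
    paw_scatter_temp: float = 0.15
    paw_scatter_thickness: float = 0.15
    paw_scatter_clinical: float = 3.0

    #: Flare fraction of responders by study day (piecewise-linear in
    #: between): subclinical until week 3, full flare 48 h post-LPS.
    severity_profile: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.0, 7: 0.0, 14: 0.05, 21: 0.2, 28: 1.0}
    )

    def __post_init__(self) -> None:
        if self.n_cia < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be >= 0")
        if not 0 <= self.n_nonresponders <= self.n_cia:
            raise ValueError("n_nonresponders must be in 0..n_cia")
        days = tuple(self.days)
        if len(days) == 0 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be non-empty and strictly increasing")
        for name in (
            "back_temp",
            "cia_baseline_temp",
            "control_baseline_temp",
            "flare_temp",
            "baseline_thickness",
            "flare_thickness",
        ):
            _as_mean_sd(getattr(self, name), name)
        if self.back_roi_scatter < 0 or self.clinical_latent_sd < 0:
            raise ValueError("scatter parameters must be >= 0")
        if self.cross_modality_noise < 0:
            raise ValueError("cross_modality_noise must be >= 0")
        th = tuple(self.clinical_thresholds)
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("clinical_thresholds must be strictly increasing")

    def severity_at(self, day: int) -> float:
        """Responder flare fraction at a study day (linear in between)."""
        keys = np.array(sorted(self.severity_profile), dtype=float)
        vals = np.array([self.severity_profile[int(k)] for k in keys])
        return float(np.interp(day, keys, vals))


def temperature_mean(config: CohortConfig, severity: float, group: str = "CIA") -> float:
    """Expected paw surface temperature at a latent severity in [0, 1]."""
    base = config.cia_baseline_temp if group == "CIA" else config.control_baseline_temp
    return base[0] + severity * (config.flare_temp[0] - base[0])


def thickness_mean(config: CohortConfig, severity: float) -> float:
    """Expected per-paw caliper thickness (mm) at a latent severity."""
    return config.baseline_thickness[0] + severity * (
        config.flare_thickness[0] - config.baseline_thickness[0]
    )


def expected_clinical_score(config: CohortConfig, severity: float) -> float:
    """Expected ordinal score at a latent severity (sum of exceedance
    probabilities of the four thresholds under the latent noise)."""
    from scipy.stats import norm

    th = np.asarray(config.clinical_thresholds)
    return float(norm.sf((th - severity) / config.clinical_latent_sd).sum())


@dataclass
class CohortStudy:
    """A generated longitudinal cohort: tidy table + provenance.

    ``table`` has one row per (mouse, day, site) with columns
    ``mouse_id, group, responder, day, paw, surface_temp_c,
    thickness_mm, clinical_score, latent_severity``; back-reference
    sites carry only temperature.
    """

    table: pd.DataFrame
    config: CohortConfig

    @property
    def seed(self) -> int:
        return self.config.seed

    def to_csv(self, path) -> None:
        out = self.table.copy()
        for col in ("surface_temp_c", "thickness_mm"):
            out[col] = out[col].round(2)
        out.to_csv(path, index=False)


def generate_cohort(config: CohortConfig = CohortConfig()) -> CohortStudy:
    """Simulate the full longitudinal cohort under one RNG seed.

    All stochastic draws flow from ``numpy.random.default_rng(config.seed)``
    in a fixed order, so a fixed seed reproduces the table byte-for-byte.
    """
    rng = np.random.default_rng(config.seed)

    mice = [f"CIA{i + 1:02d}" for i in range(config.n_cia)] + [
        f"CTL{i + 1:02d}" for i in range(config.n_control)
    ]
    groups = ["CIA"] * config.n_cia + ["control"] * config.n_control
    n = len(mice)

    # Non-responders: a random subset of the CIA mice.
    responder = np.array([g == "CIA" for g in groups])
    if config.n_cia > 0 and config.n_nonresponders > 0:
        non_resp_idx = rng.choice(config.n_cia, size=config.n_nonresponders, replace=False)
        responder[non_resp_idx] = False

    m = rng.normal(0.0, 1.0, n)  # persistent shared latent-severity factor
    kappa = config.cross_modality_noise

    def deviates(lam: float) -> np.ndarray:
        u = rng.normal(0.0, 1.0, n)
        w = rng.normal(0.0, 1.0, (n, 4))
        return (m[:, None] + kappa * u[:, None] + lam * w) / np.sqrt(
            1.0 + kappa**2 + lam**2
        )

    t_mean, t_sd = {}, {}
    for g, pair in (("CIA", config.cia_baseline_temp), ("control", config.control_baseline_temp)):
        t_mean[g], t_sd[g] = _as_mean_sd(pair, g)
    flare_mean, flare_sd = _as_mean_sd(config.flare_temp, "flare_temp")
    thk0_mean, thk0_sd = _as_mean_sd(config.baseline_thickness, "baseline_thickness")
    thk1_mean, thk1_sd = _as_mean_sd(config.flare_thickness, "flare_thickness")

    records = []
    for day in config.days:
        f_day = config.severity_at(int(day))
        sev = np.where(responder, f_day, 0.0)  # per-mouse flare fraction

        d_temp = deviates(config.paw_scatter_temp)
        d_thk = deviates(config.paw_scatter_thickness)
        d_cs = deviates(config.paw_scatter_clinical)
        back = rng.normal(config.back_temp[0], config.back_temp[1], n)
        back_rois = back[:, None] + rng.normal(0.0, config.back_roi_scatter, (n, 3))

        for i in range(n):
            base_mean = t_mean[groups[i]]
            base_sd = t_sd[groups[i]]
            mu_t = base_mean + sev[i] * (flare_mean - base_mean)
            sd_t = base_sd + sev[i] * (flare_sd - base_sd)
            mu_k = thk0_mean + sev[i] * (thk1_mean - thk0_mean)
            sd_k = thk0_sd + sev[i] * (thk1_sd - thk0_sd)
            latent = sev[i] + config.clinical_latent_sd * d_cs[i]
            scores = np.digitize(latent, config.clinical_thresholds)
            for p, paw in enumerate(PAW_LABELS):
                records.append(
                    {
                        "mouse_id": mice[i],
                        "group": groups[i],
                        "responder": bool(responder[i]),
                        "day": int(day),
                        "paw": paw,
                        "surface_temp_c": mu_t + sd_t * d_temp[i, p],
                        "thickness_mm": max(mu_k + sd_k * d_thk[i, p], 0.05),
                        "clinical_score": int(scores[p]),
                        "latent_severity": max(float(latent[p]), 0.0),
                    }
                )
            for b, back_label in enumerate(BACK_LABELS):
                records.append(
                    {
                        "mouse_id": mice[i],
                        "group": groups[i],
                        "responder": bool(responder[i]),
                        "day": int(day),
                        "paw": back_label,
                        "surface_temp_c": back_rois[i, b],
                        "thickness_mm": np.nan,
                        "clinical_score": np.nan,
                        "latent_severity": np.nan,
                    }
                )
    table = pd.DataFrame.from_records(records)
    return CohortStudy(table=table, config=config)


def phantom_frame_for_row(
    study: CohortStudy,
    mouse_id: str,
    day: int,
    camera: CameraModel = CameraModel(),
    seed: int | None = None,
) -> Tuple[ThermalFrame, Tuple[EllipseROI, ...]]:
    """Render the phantom thermogram for one (mouse, day) of a cohort.

    Paw ellipses are painted at the cohort table's surface temperatures
    and the body at the mean of the three back-reference values, so
    zero-noise ROI extraction reproduces the table exactly (up to the
    small scatter between the three back ROIs, which share one body
    region in the phantom).
    """
    sub = study.table[(study.table["mouse_id"] == mouse_id) & (study.table["day"] == day)]
    if sub.empty:
        raise ValueError(f"no rows for mouse {mouse_id!r} day {day}")
    sub = sub.set_index("paw")
    state = MouseState(
        paw_temps=tuple(float(sub.loc[p, "surface_temp_c"]) for p in PAW_LABELS),
        back_temp=float(np.mean([sub.loc[b, "surface_temp_c"] for b in BACK_LABELS])),
        plate_temp=study.config.plate_temp,
        latent_severity=tuple(
            float(sub.loc[p, "latent_severity"]) for p in PAW_LABELS
        ),
    )
    return generate_phantom_frame(state, camera, seed=seed)


# ---------------------------------------------------------------------------
# Calibration series


@dataclass(frozen=True)
class CalibrationSeries:
    """Replicate camera readings against blackbody reference sources."""

    reference_c: np.ndarray  # (n_refs,)
    readings_c: np.ndarray  # (n_refs, n_reps)

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference_c", np.asarray(self.reference_c, float))
        object.__setattr__(self, "readings_c", np.asarray(self.readings_c, float))
        if self.reference_c.ndim != 1 or self.reference_c.size == 0:
            raise ValueError("reference_c must be a non-empty 1D array")
        if self.readings_c.shape[0] != self.reference_c.size or self.readings_c.ndim != 2:
            raise ValueError("readings_c must have shape (n_refs, n_reps)")

    def to_frame(self) -> pd.DataFrame:
        n_refs, n_reps = self.readings_c.shape
        return pd.DataFrame(
            {
                "reference_c": np.repeat(self.reference_c, n_reps),
                "reading_c": self.readings_c.ravel(),
                "replicate": np.tile(np.arange(1, n_reps + 1), n_refs),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CalibrationSeries":
        refs = np.unique(np.asarray(frame["reference_c"], float))
        readings = [
            np.asarray(frame.loc[frame["reference_c"] == r, "reading_c"], float)
            for r in refs
        ]
        n_reps = {len(r) for r in readings}
        if len(n_reps) != 1:
            raise ValueError("unbalanced replicate counts across references")
        return cls(refs, np.vstack(readings))


def generate_calibration_series(
    ref_temps: Sequence[float],
    reps: int = 3,
    noise_sd: float = 0.1,
    seed: int | None = None,
) -> CalibrationSeries:
    """Noisy replicate readings around each reference temperature.

    Ground truth is an ideal camera (slope 1, intercept 0); readings are
    reference + N(0, noise_sd), ``reps`` replicates per reference.
    """
    refs = np.asarray(list(ref_temps), dtype=float)
    if refs.size == 0:
        raise ValueError("ref_temps must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    readings = refs[:, None] + rng.normal(0.0, noise_sd, (refs.size, reps))
    return CalibrationSeries(refs, readings)
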