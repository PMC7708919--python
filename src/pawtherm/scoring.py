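"""Temperature-index scoring, severity classification, cohort selection.

The temperature index of one paw is its ROI mean temperature normalized
to the averaged back reference temperature of the same animal,

    TI_paw = T_paw / T_back,

and the total temperature index is the sum over the four paws,

    TI_total = TI_FL + TI_FR + TI_HL + TI_HR,

with a nominal maximum of 4 (every paw as warm as the back). The ratio is
taken on the Celsius scale: the published severity bins (TI 0.80-1.0 at
paw temperatures of 28-34 degC) are only consistent with a Celsius ratio;
a Kelvin variant is available through the ``scale`` argument for
sensitivity analyses.

Severity bins per modality (left-closed, right-open; top bin closed
above):

======== =============== ============== ==========
level    TI              THK (mm)       CS
======== =============== ============== ==========
absent   0.80-0.85       1.5-2          0
mild     0.85-0.90       2-2.5          1
moderate 0.90-0.95       2.5-3          2, 3
severe   0.95-1          3-3.5          4
======== =============== ============== ==========

A mouse enters a therapeutic study only if *all four* joints score
TI >= 0.9 (moderate or worse); the boundary is inclusive.
"""

from __future__ import annotations

import enum
import warnings
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd

from pawtherm.roi import BACK_LABELS, PAW_LABELS

__all__ = [
    "SeverityLevel",
    "TI_BINS",
    "THK_BINS",
    "back_reference",
    "temperature_index",
    "ti_total",
    "total_clinical_score",
    "total_thickness",
    "classify_severity",
    "mouse_inclusion",
    "score_cohort",
    "severity_heatmap",
    "HeatmapResult",
]

_KELVIN_OFFSET = 273.15

#: Inclusion threshold for the therapeutic study (all four joints).
INCLUSION_TI_THRESHOLD = 0.9

#: Lower edges of the mild/moderate/severe bins per modality.
TI_BINS = (0.85, 0.90, 0.95)
THK_BINS = (2.0, 2.5, 3.0)


class SeverityLevel(enum.IntEnum):
    """Ordered arthritis severity level; comparisons follow the order."""

    ABSENT = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


def back_reference(back_means: Sequence[float]) -> float:
    """Average the three back-ROI mean temperatures into T_back."""
    vals = np.asarray(back_means, dtype=float)
    if vals.size != 3:
        raise ValueError(f"back reference requires exactly 3 ROI means, got {vals.size}")
    if not np.all(np.isfinite(vals)):
        raise ValueError("back ROI means must be finite")
    return float(vals.mean())


def temperature_index(t_paw: float, t_back: float, scale: str = "celsius") -> float:
    """TI of one paw: paw ROI mean over back reference temperature.

    ``scale`` selects the unit in which the ratio is formed ("celsius",
    the published convention, or "kelvin"). The value is not clamped.
    """
    if scale not in ("celsius", "kelvin"):
        raise ValueError(f"scale must be 'celsius' or 'kelvin', got {scale!r}")
    t_paw = float(t_paw)
    t_back = float(t_back)
    if not (np.isfinite(t_paw) and np.isfinite(t_back)):
        raise ValueError("temperatures must be finite")
    if t_paw <= -_KELVIN_OFFSET or t_back <= -_KELVIN_OFFSET:
        raise ValueError("temperatures below absolute zero")
    if scale == "kelvin":
        return (t_paw + _KELVIN_OFFSET) / (t_back + _KELVIN_OFFSET)
    if t_back <= 0.0:
        raise ValueError(
            f"back reference {t_back} degC is <= 0; the Celsius-scale TI is undefined"
        )
    return t_paw / t_back


def ti_total(tis: Sequence[float]) -> float:
    """TI_total: sum of the four per-paw temperature indices."""
    vals = np.asarray(tis, dtype=float)
    if vals.size != 4:
        raise ValueError(f"ti_total requires exactly 4 per-paw TIs, got {vals.size}")
    if not np.all(np.isfinite(vals)):
        raise ValueError("per-paw TIs must be finite")
    return float(vals.sum())


def total_clinical_score(scores: Sequence[int]) -> int:
    """Sum the four per-paw ordinal clinical scores (each 0-4, total 0-16)."""
    vals = list(scores)
    if len(vals) != 4:
        raise ValueError(f"expected 4 per-paw scores, got {len(vals)}")
    out = 0
    for s in vals:
        if float(s) != int(s) or not 0 <= int(s) <= 4:
            raise ValueError(f"clinical score must be an integer in 0..4, got {s!r}")
        out += int(s)
    return out


def total_thickness(thicknesses_mm: Sequence[float]) -> float:
    """Sum the four per-paw caliper thicknesses in mm."""
    vals = np.asarray(thicknesses_mm, dtype=float)
    if vals.size != 4:
        raise ValueError(f"expected 4 per-paw thicknesses, got {vals.size}")
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("paw thicknesses must be finite and > 0")
    return float(vals.sum())


def classify_severity(value: float, modality: str) -> SeverityLevel:
    """Bin one measurement into absent/mild/moderate/severe.

    ``modality`` is "TI" (temperature index), "THK" (paw thickness, mm)
    or "CS" (ordinal clinical score). Bins are left-closed/right-open
    except the open-ended severe bin. TI values below the nominal absent
    bin (< 0.80) or above 1 are accepted with a warning (absent and
    severe respectively): the published range does not state handling.
    """
    if modality == "TI":
        v = float(value)
        if v < 0.80:
            warnings.warn(
                f"TI {v:.3f} below the nominal absent bin (0.80-0.85); "
                "classified absent",
                stacklevel=2,
            )
        if v > 1.0:
            warnings.warn(
                f"TI {v:.3f} above the nominal maximum of 1; classified severe",
                stacklevel=2,
            )
        edges = TI_BINS
    elif modality == "THK":
        v = float(value)
        edges = THK_BINS
    elif modality == "CS":
        if float(value) != int(value) or not 0 <= int(value) <= 4:
            raise ValueError(f"clinical score must be an integer in 0..4, got {value!r}")
        return (
            SeverityLevel.ABSENT,
            SeverityLevel.MILD,
            SeverityLevel.MODERATE,
            SeverityLevel.MODERATE,
            SeverityLevel.SEVERE,
        )[int(value)]
    else:
        raise ValueError(f"unknown modality {modality!r}; expected TI, THK or CS")
    if not np.isfinite(v):
        raise ValueError("value must be finite")
    return SeverityLevel(int(np.searchsorted(edges, v, side="right")))


def mouse_inclusion(paw_tis: Dict[str, float] | Sequence[float]) -> bool:
    """Therapeutic-study inclusion rule: every joint TI >= 0.9.

    The boundary is inclusive (0.9 <= TI <= 1 defines a fully developed
    responder). Accepts a {paw: TI} mapping or the four TIs in FL, FR,
    HL, HR order; a missing paw raises.
    """
    if isinstance(paw_tis, dict):
        missing = [p for p in PAW_LABELS if p not in paw_tis]
        if missing:
            raise ValueError(f"missing paw TIs: {missing}")
        vals = [float(paw_tis[p]) for p in PAW_LABELS]
    else:
        vals = [float(v) for v in paw_tis]
        if len(vals) != 4:
            raise ValueError(f"expected 4 paw TIs, got {len(vals)}")
    if not all(np.isfinite(vals)):
        raise ValueError("paw TIs must be finite")
    return all(v >= INCLUSION_TI_THRESHOLD for v in vals)


def score_cohort(cohort: pd.DataFrame, scale: str = "celsius") -> pd.DataFrame:
    """Score a tidy cohort table into per-mouse, per-day endpoints.

    ``cohort`` is tidy with one row per (mouse, day, site): columns
    ``mouse_id, group, day, paw, surface_temp_c`` plus, for paw rows,
    ``thickness_mm`` and ``clinical_score``. Back reference rows use paw
    labels ``back1, back2, back3``.

    Returns one row per (mouse, day) with columns ``ti_fl, ti_fr, ti_hl,
    ti_hr, ti_total, t_back_c, total_thickness_mm, total_clinical_score``
    plus per-paw thickness/score columns.
    """
    required = {"mouse_id", "group", "day", "paw", "surface_temp_c"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")

    rows = []
    for (mouse, day), sub in cohort.groupby(["mouse_id", "day"], sort=True):
        sub = sub.set_index("paw")
        back_missing = [b for b in BACK_LABELS if b not in sub.index]
        paw_missing = [p for p in PAW_LABELS if p not in sub.index]
        if back_missing or paw_missing:
            raise ValueError(
                f"mouse {mouse!r} day {day}: missing sites "
                f"{back_missing + paw_missing}"
            )
        t_back = back_reference([sub.loc[b, "surface_temp_c"] for b in BACK_LABELS])
        tis = {
            p: temperature_index(sub.loc[p, "surface_temp_c"], t_back, scale=scale)
            for p in PAW_LABELS
        }
        row = {
            "mouse_id": mouse,
            "group": sub["group"].iloc[0],
            "day": day,
            "t_back_c": t_back,
            **{f"ti_{p.lower()}": tis[p] for p in PAW_LABELS},
            "ti_total": ti_total([tis[p] for p in PAW_LABELS]),
        }
        if "thickness_mm" in sub.columns and sub.loc[list(PAW_LABELS), "thickness_mm"].notna().all():
            thk = [float(sub.loc[p, "thickness_mm"]) for p in PAW_LABELS]
            row.update({f"thickness_{p.lower()}_mm": t for p, t in zip(PAW_LABELS, thk)})
            row["total_thickness_mm"] = total_thickness(thk)
        if "clinical_score" in sub.columns and sub.loc[list(PAW_LABELS), "clinical_score"].notna().all():
            cs = [int(sub.loc[p, "clinical_score"]) for p in PAW_LABELS]
            row.update({f"clinical_{p.lower()}": c for p, c in zip(PAW_LABELS, cs)})
            row["total_clinical_score"] = total_clinical_score(cs)
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["day", "mouse_id"]).reset_index(drop=True)


class HeatmapResult:
    """Per-mouse x per-paw severity matrix for one modality at one day.

    Attributes
    ----------
    labels : pandas.DataFrame
        Mice (rows) by paws (columns), values :class:`SeverityLevel`.
    moderate_severe : pandas.Series
        Per mouse, True iff *all four* joints reach moderate or worse.
    n_moderate_severe : int
        Count of such mice (the cohort-selection headline number).
    any_mild_or_worse : pandas.Series
        Per mouse, True iff any paw reaches mild or worse (incidence).
    """

    def __init__(self, labels: pd.DataFrame):
        self.labels = labels
        self.moderate_severe = (labels >= SeverityLevel.MODERATE).all(axis=1)
        self.n_moderate_severe = int(self.moderate_severe.sum())
        self.any_mild_or_worse = (labels >= SeverityLevel.MILD).any(axis=1)

    @property
    def incidence_percent(self) -> float:
        """Percent of mice with at least mild disease in any paw."""
        return 100.0 * float(self.any_mild_or_worse.mean())

    def as_frame(self) -> pd.DataFrame:
        out = self.labels.map(lambda lv: str(SeverityLevel(lv)))
        out["moderate_severe"] = self.moderate_severe
        return out


def severity_heatmap(
    scores: pd.DataFrame,
    modality: str = "TI",
    day: int | None = None,
    groups: Iterable[str] | None = None,
) -> HeatmapResult:
    """Severity matrix (mice x paws) for one modality, plus selection counts.

    ``scores`` is the output of :func:`score_cohort`. ``day`` restricts
    to one study day (required if several are present); ``groups``
    restricts to given group labels (e.g. ``["CIA"]``).
    """
    df = scores
    if day is not None:
        df = df[df["day"] == day]
    if groups is not None:
        df = df[df["group"].isin(list(groups))]
    if df.empty:
        raise ValueError("no rows selected for the severity heatmap")
    if df["day"].nunique() > 1:
        raise ValueError("scores span several days; pass day=... explicitly")
    col_prefix = {"TI": "ti_", "THK": "thickness_", "CS": "clinical_"}
    if modality not in col_prefix:
        raise ValueError(f"unknown modality {modality!r}; expected TI, THK or CS")
    labels = {}
    for _, row in df.iterrows():
        cells = []
        for p in PAW_LABELS:
            col = f"{col_prefix[modality]}{p.lower()}"
            if modality == "THK":
                col += "_mm"
            if col not in row or pd.isna(row[col]):
                raise ValueError(f"mouse {row['mouse_id']!r}: missing {col}")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cells.append(classify_severity(row[col], modality))
        labels[row["mouse_id"]] = cells
    frame = pd.DataFrame.from_dict(labels, orient="index", columns=list(PAW_LABELS))
    return HeatmapResult(frame.sort_index())
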