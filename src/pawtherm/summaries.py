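"""Replicate-simulation summaries of the default study conditions.

Runs many independently seeded synthetic cohorts through the scoring
pipeline and collects, per replicate, the headline quantities of the
framework: group mean TI_total at baseline and at the day-28 flare,
total-thickness means, the cohort median clinical score, the
cross-modality correlation, severity/selection counts. Used to
characterize what the generator defaults imply and to regression-test
the whole pipeline against those expectations.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from pawtherm.scoring import mouse_inclusion, score_cohort, severity_heatmap
from pawtherm.simulate import CohortConfig, generate_cohort
from pawtherm.stats import correlate

__all__ = [
    "replicate_cohort_summaries",
    "replicate_selection_summaries",
    "day28_inclusion_counts",
    "derive_seeds",
    "modal_value",
]


def derive_seeds(base_seed: int, n: int) -> np.ndarray:
    """n reproducible child seeds (< 2**31) from one base seed."""
    return np.random.SeedSequence(base_seed).generate_state(n) % np.uint32(2**31)


def replicate_cohort_summaries(
    n_seeds: int = 200,
    base_seed: int = 0,
    config_overrides: dict | None = None,
) -> pd.DataFrame:
    """One row of summary statistics per seeded default cohort.

    Columns: ``seed, baseline_cia_ti, baseline_control_ti, d28_cia_ti,
    d28_cia_thickness, d28_control_thickness, d28_cia_cs_median,
    d28_pearson_r, n_moderate_severe_ti, incidence_percent, n_included``.
    """
    rows = []
    overrides = config_overrides or {}
    for seed in derive_seeds(base_seed, n_seeds):
        config = CohortConfig(seed=int(seed), **overrides)
        scores = score_cohort(generate_cohort(config).table)
        first_day = min(config.days)
        last_day = max(config.days)
        base = scores[scores["day"] == first_day]
        d28 = scores[scores["day"] == last_day]
        cia28 = d28[d28["group"] == "CIA"]
        ctl28 = d28[d28["group"] == "control"]

        hm = severity_heatmap(scores, "TI", day=last_day, groups=["CIA"])
        n_included = sum(
            mouse_inclusion({p: row[f"ti_{p.lower()}"] for p in ("FL", "FR", "HL", "HR")})
            for _, row in cia28.iterrows()
        )
        r = (
            correlate(cia28["ti_total"], cia28["total_thickness_mm"]).coefficient
            if len(cia28) >= 3
            else np.nan
        )
        rows.append(
            {
                "seed": int(seed),
                "baseline_cia_ti": base.loc[base["group"] == "CIA", "ti_total"].mean(),
                "baseline_control_ti": base.loc[
                    base["group"] == "control", "ti_total"
                ].mean(),
                "d28_cia_ti": cia28["ti_total"].mean(),
                "d28_cia_thickness": cia28["total_thickness_mm"].mean(),
                "d28_control_thickness": ctl28["total_thickness_mm"].mean(),
                "d28_cia_cs_median": cia28["total_clinical_score"].median(),
                "d28_pearson_r": r,
                "n_moderate_severe_ti": hm.n_moderate_severe,
                "incidence_percent": round(hm.incidence_percent),
                "n_included": n_included,
            }
        )
    return pd.DataFrame(rows)


def replicate_selection_summaries(
    n_seeds: int = 1000,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Day-28 severity classification and selection counts per seed.

    Uses CIA-only cohorts on a (0, 28) day grid — the day-28 marginals
    are identical to the full default design — so that the selection
    probability can be estimated with many more replicates at the same
    cost. Columns: ``seed, n_moderate_severe_ti, incidence_percent,
    n_included``.
    """
    rows = []
    for seed in derive_seeds(base_seed, n_seeds):
        config = CohortConfig(seed=int(seed), n_control=0, days=(0, 28))
        scores = score_cohort(generate_cohort(config).table)
        cia28 = scores[(scores["day"] == 28) & (scores["group"] == "CIA")]
        hm = severity_heatmap(scores, "TI", day=28, groups=["CIA"])
        n_included = sum(
            mouse_inclusion({p: row[f"ti_{p.lower()}"] for p in ("FL", "FR", "HL", "HR")})
            for _, row in cia28.iterrows()
        )
        rows.append(
            {
                "seed": int(seed),
                "n_moderate_severe_ti": hm.n_moderate_severe,
                "incidence_percent": round(hm.incidence_percent),
                "n_included": n_included,
            }
        )
    return pd.DataFrame(rows)


def day28_inclusion_counts(n_seeds: int = 10000, base_seed: int = 0) -> np.ndarray:
    """Included-mouse count at day 28 for many seeded CIA cohorts.

    Vectorized evaluation of the selection rule (every paw TI >= 0.9,
    TI = paw temperature over the mean of the three back references) on
    CIA-only (0, 28)-day cohorts. Mathematically identical to scoring
    via :func:`pawtherm.scoring.score_cohort` +
    :func:`pawtherm.scoring.mouse_inclusion` (a unit test asserts the
    equivalence) but fast enough to pin down the selection probability,
    which sits within a percent of its design value.
    """
    from pawtherm.roi import BACK_LABELS, PAW_LABELS

    counts = np.empty(n_seeds, dtype=int)
    for k, seed in enumerate(derive_seeds(base_seed, n_seeds)):
        config = CohortConfig(seed=int(seed), n_control=0, days=(0, 28))
        t = generate_cohort(config).table
        t28 = t[t["day"] == 28]
        paw = t28[t28["paw"].isin(PAW_LABELS)].pivot(
            index="mouse_id", columns="paw", values="surface_temp_c"
        )
        back = t28[t28["paw"].isin(BACK_LABELS)].groupby("mouse_id")[
            "surface_temp_c"
        ].mean()
        ti = paw.div(back, axis=0)
        counts[k] = int((ti >= 0.9).all(axis=1).sum())
    return counts


def modal_value(values: Iterable) -> float:
    """Most frequent value (smallest wins ties), for modal-count summaries."""
    vals, counts = np.unique(np.asarray(list(values)), return_counts=True)
    return float(vals[np.argmax(counts)])
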