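"""Temperature-index arithmetic, severity bins and cohort selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pawtherm.scoring import (
    SeverityLevel,
    back_reference,
    classify_severity,
    mouse_inclusion,
    score_cohort,
    severity_heatmap,
    temperature_index,
    ti_total,
    total_clinical_score,
    total_thickness,
)


class TestBackReference:
    def test_mean_of_three(self):
        assert back_reference([33.5, 34.0, 34.5]) == pytest.approx(34.0)
        assert back_reference([34.0, 34.0, 34.0]) == 34.0

    def test_permutation_invariant(self):
        for perm in itertools.permutations([33.2, 34.1, 34.9]):
            assert back_reference(perm) == pytest.approx(back_reference([33.2, 34.1, 34.9]))

    @pytest.mark.parametrize("bad", [[34.0, 34.0], [1, 2, 3, 4], [np.nan, 34, 34]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            back_reference(bad)


class TestTemperatureIndex:
    @pytest.mark.parametrize(
        "paw, back, expected",
        [(34.0, 34.0, 1.0), (30.6, 34.0, 0.9), (28.65, 34.0, 28.65 / 34.0)],
    )
    def test_celsius_ratio(self, paw, back, expected):
        assert temperature_index(paw, back) == pytest.approx(expected, abs=1e-12)

    def test_common_rescaling_invariance(self, rng):
        for _ in range(20):
            paw, back = rng.uniform(25, 35), rng.uniform(30, 36)
            c = rng.uniform(0.5, 2.0)
            assert temperature_index(c * paw, c * back) == pytest.approx(
                temperature_index(paw, back), rel=1e-12
            )

    def test_kelvin_scale_switch(self):
        assert temperature_index(30.6, 34.0, scale="kelvin") == pytest.approx(
            303.75 / 307.15, abs=1e-12
        )

    def test_nonpositive_back_rejected_on_celsius_scale(self):
        with pytest.raises(ValueError, match="undefined"):
            temperature_index(30.0, 0.0)
        with pytest.raises(ValueError, match="undefined"):
            temperature_index(30.0, -5.0)

    def test_not_clamped(self):
        assert temperature_index(35.0, 34.0) > 1.0


class TestTotals:
    def test_ti_total_maximum(self):
        assert ti_total([1.0, 1.0, 1.0, 1.0]) == 4.0

    def test_ti_total_sum_and_permutation(self):
        vals = [0.9, 0.92, 0.95, 0.88]
        assert ti_total(vals) == pytest.approx(sum(vals), abs=1e-12)
        for perm in itertools.permutations(vals):
            assert ti_total(perm) == pytest.approx(sum(vals), abs=1e-12)

    def test_sum_of_indices_differs_from_index_of_sums(self):
        # Guard: temperatures must be normalized per paw BEFORE summing.
        paws = [30.0, 31.0, 32.0, 33.0]
        backs = [30.0, 36.0, 33.0, 34.0]
        per_paw = ti_total([p / b for p, b in zip(paws, backs)])
        pooled = sum(paws) / np.mean(backs)
        assert per_paw != pytest.approx(pooled, abs=1e-3)

    def test_clinical_totals(self):
        assert total_clinical_score([4, 4, 4, 4]) == 16
        assert total_clinical_score([0, 0, 0, 0]) == 0
        assert total_clinical_score([1, 2, 3, 4]) == 10
        with pytest.raises(ValueError):
            total_clinical_score([1, 2, 3, 5])
        with pytest.raises(ValueError):
            total_clinical_score([1, 2, 3])

    def test_thickness_totals(self):
        assert total_thickness([1.79, 1.79, 1.79, 1.80]) == pytest.approx(7.17)
        with pytest.raises(ValueError):
            total_thickness([0.0, 1.79, 1.79, 1.79])


class TestSeverityClassification:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.82, SeverityLevel.ABSENT),
            (0.84999, SeverityLevel.ABSENT),
            (0.85, SeverityLevel.MILD),
            (0.88, SeverityLevel.MILD),
            (0.90, SeverityLevel.MODERATE),  # left-closed boundary
            (0.92, SeverityLevel.MODERATE),
            (0.95, SeverityLevel.SEVERE),
            (0.99, SeverityLevel.SEVERE),
        ],
    )
    def test_ti_bins(self, value, expected):
        assert classify_severity(value, "TI") == expected

    @pytest.mark.parametrize(
        "value, expected",
        [
            (1.7, SeverityLevel.ABSENT),
            (2.0, SeverityLevel.MILD),
            (2.49, SeverityLevel.MILD),
            (2.5, SeverityLevel.MODERATE),
            (3.0, SeverityLevel.SEVERE),
            (3.4, SeverityLevel.SEVERE),
        ],
    )
    def test_thickness_bins(self, value, expected):
        assert classify_severity(value, "THK") == expected

    @pytest.mark.parametrize(
        "value, expected",
        [
            (0, SeverityLevel.ABSENT),
            (1, SeverityLevel.MILD),
            (2, SeverityLevel.MODERATE),
            (3, SeverityLevel.MODERATE),
            (4, SeverityLevel.SEVERE),
        ],
    )
    def test_clinical_bins(self, value, expected):
        assert classify_severity(value, "CS") == expected

    def test_out_of_range_ti_warns(self):
        with pytest.warns(UserWarning, match="below"):
            assert classify_severity(0.75, "TI") == SeverityLevel.ABSENT
        with pytest.warns(UserWarning, match="above"):
            assert classify_severity(1.05, "TI") == SeverityLevel.SEVERE

    def test_unknown_modality_rejected(self):
        with pytest.raises(ValueError, match="modality"):
            classify_severity(0.9, "XYZ")

    @pytest.mark.parametrize("modality, lo, hi", [("TI", 0.80, 1.0), ("THK", 1.5, 3.5)])
    def test_classification_non_decreasing(self, modality, lo, hi):
        values = np.linspace(lo, hi, 100)
        levels = [classify_severity(v, modality) for v in values]
        assert all(b >= a for a, b in zip(levels, levels[1:]))


class TestInclusion:
    def test_all_joints_above_threshold_included(self):
        assert mouse_inclusion([0.92, 0.95, 0.91, 0.93])

    def test_one_mild_joint_excluded(self):
        assert not mouse_inclusion([0.92, 0.88, 0.95, 0.93])

    def test_boundary_inclusive(self):
        assert mouse_inclusion([0.90, 0.90, 0.90, 0.90])

    def test_missing_paw_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            mouse_inclusion({"FL": 0.92, "FR": 0.95, "HL": 0.91})


def _tidy_row(mouse, day, paw, temp, thk=np.nan, cs=np.nan, group="CIA"):
    return {
        "mouse_id": mouse, "group": group, "day": day, "paw": paw,
        "surface_temp_c": temp, "thickness_mm": thk, "clinical_score": cs,
    }


def _one_mouse_table(paw_temps, backs=(34.0, 34.0, 34.0), thk=2.0, cs=2):
    rows = [
        _tidy_row("M1", 28, paw, t, thk, cs)
        for paw, t in zip(("FL", "FR", "HL", "HR"), paw_temps)
    ]
    rows += [_tidy_row("M1", 28, b, t) for b, t in zip(("back1", "back2", "back3"), backs)]
    return pd.DataFrame(rows)


class TestScoreCohort:
    def test_hand_ratios(self):
        table = _one_mouse_table([30.6, 32.3, 34.0, 27.2], backs=(33.5, 34.0, 34.5))
        scores = score_cohort(table)
        row = scores.iloc[0]
        assert row["t_back_c"] == pytest.approx(34.0)
        assert row["ti_fl"] == pytest.approx(0.9)
        assert row["ti_fr"] == pytest.approx(0.95)
        assert row["ti_hl"] == pytest.approx(1.0)
        assert row["ti_hr"] == pytest.approx(0.8)
        assert row["ti_total"] == pytest.approx(0.9 + 0.95 + 1.0 + 0.8)
        assert row["total_thickness_mm"] == pytest.approx(8.0)
        assert row["total_clinical_score"] == 8

    def test_missing_site_rejected(self):
        table = _one_mouse_table([30.6, 32.3, 34.0, 27.2])
        with pytest.raises(ValueError, match="missing sites"):
            score_cohort(table[table["paw"] != "HL"])


class TestSeverityHeatmap:
    def _random_scores(self, rng, n=10):
        rows = []
        for i in range(n):
            tis = rng.uniform(0.80, 1.0, 4)
            rows.append(
                {
                    "mouse_id": f"M{i:02d}", "group": "CIA", "day": 28,
                    **{f"ti_{p}": t for p, t in zip(("fl", "fr", "hl", "hr"), tis)},
                    "ti_total": tis.sum(),
                }
            )
        return pd.DataFrame(rows)

    def test_counts_match_brute_force(self, rng):
        for _ in range(20):
            scores = self._random_scores(rng)
            hm = severity_heatmap(scores, "TI", day=28)
            brute = 0
            for _, row in scores.iterrows():
                tis = [row[f"ti_{p}"] for p in ("fl", "fr", "hl", "hr")]
                brute += all(t >= 0.90 for t in tis)
            assert hm.n_moderate_severe == brute
            brute_any = sum(
                any(row[f"ti_{p}"] >= 0.85 for p in ("fl", "fr", "hl", "hr"))
                for _, row in scores.iterrows()
            )
            assert int(hm.any_mild_or_worse.sum()) == brute_any

    def test_all_healthy_cohort(self):
        scores = pd.DataFrame(
            [
                {
                    "mouse_id": f"M{i}", "group": "CIA", "day": 28,
                    "ti_fl": 0.82, "ti_fr": 0.83, "ti_hl": 0.81, "ti_hr": 0.84,
                    "ti_total": 3.3,
                }
                for i in range(5)
            ]
        )
        hm = severity_heatmap(scores, "TI", day=28)
        assert (hm.labels == SeverityLevel.ABSENT).all().all()
        assert hm.n_moderate_severe == 0
        assert hm.incidence_percent == 0.0

    def test_single_severe_mouse(self):
        scores = pd.DataFrame(
            [
                {
                    "mouse_id": "M1", "group": "CIA", "day": 28,
                    "ti_fl": 0.96, "ti_fr": 0.96, "ti_hl": 0.96, "ti_hr": 0.96,
                    "ti_total": 3.84,
                }
            ]
        )
        hm = severity_heatmap(scores, "TI", day=28)
        assert (hm.labels == SeverityLevel.SEVERE).all().all()
        assert hm.n_moderate_severe == 1
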