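"""AUC, gated group comparisons, correlations and efficacy analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pawtherm.stats import (
    auc_trapezoid,
    compare_groups,
    correlate,
    efficacy_analysis,
    interval_summary,
    significance_stars,
)


def _auc_oracle(days, values):
    return sum(
        (values[i] + values[i + 1]) / 2.0 * (days[i + 1] - days[i])
        for i in range(len(days) - 1)
    )


class TestAUC:
    def test_constant_trajectory(self):
        assert auc_trapezoid([0, 28], [3.0, 3.0]) == pytest.approx(84.0)
        assert auc_trapezoid([0, 7, 14, 21, 28], [3.0] * 5) == pytest.approx(84.0)

    def test_hand_trapezoid(self):
        assert auc_trapezoid([0, 3, 7], [0, 3, 7]) == pytest.approx(24.5)

    def test_single_segment(self):
        assert auc_trapezoid([0, 28], [4.0, 3.0]) == pytest.approx(14 * 7.0)

    def test_matches_oracle_on_random_trajectories(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 10))
            days = np.sort(rng.choice(np.arange(0, 60), size=n, replace=False))
            vals = rng.uniform(-5, 5, n)
            assert auc_trapezoid(days, vals) == pytest.approx(
                _auc_oracle(days, vals), abs=1e-9
            )

    def test_additive_over_concatenated_ranges(self, rng):
        days = np.array([0, 3, 7, 10, 14], dtype=float)
        vals = rng.uniform(0, 5, 5)
        whole = auc_trapezoid(days, vals)
        parts = auc_trapezoid(days[:3], vals[:3]) + auc_trapezoid(days[2:], vals[2:])
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_linear_in_values(self, rng):
        days = np.array([0, 7, 14], dtype=float)
        v1, v2 = rng.uniform(0, 5, 3), rng.uniform(0, 5, 3)
        assert auc_trapezoid(days, 2 * v1 + v2) == pytest.approx(
            2 * auc_trapezoid(days, v1) + auc_trapezoid(days, v2), abs=1e-12
        )

    def test_unordered_days_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            auc_trapezoid([0, 7, 5], [1, 2, 3])
        with pytest.raises(ValueError):
            auc_trapezoid([0], [1])


def _mw_u(a, b):
    return sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )


def _mw_exact_p_oracle(a, b):
    """Exhaustive two-sided permutation p for the Mann-Whitney U."""
    pooled = list(a) + list(b)
    n1 = len(a)
    mu = n1 * len(b) / 2.0
    obs = abs(_mw_u(a, b) - mu)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(_mw_u(ga, gb) - mu) >= obs - 1e-12:
            count += 1
    return count / total


class TestCompareGroups:
    def test_identical_groups(self):
        rep = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.p_value >= 0.99

    def test_ordinal_separated_groups_exact_p(self):
        # {1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 2/20 = 0.1.
        rep = compare_groups([1, 2, 3], [4, 5, 6], ordinal=True)
        assert rep.test_name == "Mann-Whitney"
        assert min(rep.statistic, 9 - rep.statistic) == 0.0
        assert rep.p_value == pytest.approx(0.1, abs=1e-12)

    def test_mann_whitney_matches_permutation_oracle(self, rng):
        for _ in range(100):
            n1, n2 = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            a = rng.normal(0, 1, n1)  # continuous draws: ties impossible
            b = rng.normal(0.5, 1, n2)
            rep = compare_groups(a, b, ordinal=True)
            assert rep.p_value == pytest.approx(_mw_exact_p_oracle(a, b), abs=1e-12)

    def test_normal_groups_route_to_t_test(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0, 1, 12)
        rep = compare_groups(a, b)
        assert rep.test_name == "t"
        assert rep.normality_p is not None and all(p > 0.05 for p in rep.normality_p)

    def test_non_normal_group_routes_to_mann_whitney(self, rng):
        a = np.concatenate([rng.normal(0, 0.05, 9), [50.0]])  # gross outlier
        b = rng.normal(0, 1, 10)
        rep = compare_groups(a, b)
        assert rep.test_name == "Mann-Whitney"
        assert "normality rejected" in rep.route

    def test_small_groups_bypass_gate(self):
        rep = compare_groups([1.0, 2.0], [3.0, 4.0])
        assert rep.test_name == "Mann-Whitney"
        assert "too small" in rep.route

    def test_power_at_large_shift(self):
        # 3-sigma shift, n=4 per group: significant in >= 90% of draws.
        rng = np.random.default_rng(2024)
        hits = sum(
            compare_groups(rng.normal(0, 1, 4), rng.normal(3, 1, 4)).p_value < 0.05
            for _ in range(300)
        )
        assert hits / 300 >= 0.90

    def test_type_one_error_calibrated_under_null(self):
        # Full gated procedure at alpha 0.05 under a true null: empirical
        # rejection rate within the binomial CI of 0.05 over 1000 draws.
        rng = np.random.default_rng(77)
        n_rep = 1000
        hits = sum(
            compare_groups(rng.normal(0, 1, 8), rng.normal(0, 1, 8)).p_value < 0.05
            for _ in range(n_rep)
        )
        ci_half = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(hits / n_rep - 0.05) < ci_half

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])


def _kendall_tau_b_oracle(x, y):
    n = len(x)
    num = 0
    for i in range(n):
        for j in range(i + 1, n):
            num += np.sign(x[j] - x[i]) * np.sign(y[j] - y[i])
    n0 = n * (n - 1) / 2

    def tie_term(v):
        _, counts = np.unique(v, return_counts=True)
        return sum(c * (c - 1) / 2 for c in counts)

    return num / np.sqrt((n0 - tie_term(x)) * (n0 - tie_term(y)))


def _pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))


class TestCorrelate:
    def test_perfect_linear_relation(self):
        res = correlate([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.method == "pearson"
        assert res.coefficient == pytest.approx(1.0)

    def test_kendall_hand_case(self):
        # (1,2,3) vs (1,3,2): 2 concordant, 1 discordant -> tau = 1/3.
        res = correlate([1, 2, 3], [1, 3, 2], y_ordinal=True)
        assert res.method == "kendall"
        assert res.coefficient == pytest.approx(1 / 3, abs=1e-12)

    def test_pearson_matches_textbook_formula(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 11))
            x, y = rng.normal(0, 1, n), rng.normal(0, 1, n)
            res = correlate(x, y)
            assert res.coefficient == pytest.approx(_pearson_oracle(x, y), abs=1e-12)

    def test_kendall_matches_tie_corrected_formula(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 11))
            x = rng.normal(0, 1, n)
            y = rng.integers(0, 4, n).astype(float)  # ordinal with ties
            if np.ptp(y) == 0:
                continue
            res = correlate(x, y, y_ordinal=True)
            assert res.coefficient == pytest.approx(
                _kendall_tau_b_oracle(x, y), abs=1e-12
            )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            correlate([1.0, 1.0, 1.0], [1, 2, 3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 2], [3, 4])


class TestIntervalSummary:
    def test_hand_summary(self):
        scores = pd.DataFrame(
            {
                "mouse_id": ["a", "b", "c"],
                "group": ["CIA"] * 3,
                "day": [0] * 3,
                "ti_total": [3.5, 3.6, 3.7],
            }
        )
        out = interval_summary(scores, "ti_total")
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(3.6)
        assert (row["min"], row["max"]) == (3.5, 3.7)
        assert row["n"] == 3

    def test_single_mouse_sd_reported_as_zero(self):
        scores = pd.DataFrame(
            {"mouse_id": ["a"], "group": ["CIA"], "day": [0], "ti_total": [3.5]}
        )
        assert interval_summary(scores, "ti_total").iloc[0]["sd"] == 0.0

    def test_matches_brute_force_on_random_tables(self, rng):
        scores = pd.DataFrame(
            {
                "mouse_id": [f"m{i}" for i in range(30)],
                "group": rng.choice(["A", "B"], 30),
                "day": rng.choice([0, 28], 30),
                "ti_total": rng.uniform(3, 4, 30),
            }
        )
        out = interval_summary(scores, "ti_total").set_index(["group", "day"])
        for (g, d), sub in scores.groupby(["group", "day"]):
            vals = sub["ti_total"].to_numpy()
            row = out.loc[(g, d)]
            assert row["mean"] == pytest.approx(vals.mean())
            expected_sd = vals.std(ddof=1) if vals.size > 1 else 0.0
            assert row["sd"] == pytest.approx(expected_sd)


def _trajectories(values_by_group, days=(0, 14, 28)):
    rows = []
    for group, mice in values_by_group.items():
        for m, vals in enumerate(mice):
            for d, v in zip(days, vals):
                rows.append(
                    {
                        "mouse_id": f"{group}{m}", "group": group, "day": d,
                        "ti_total": v,
                    }
                )
    return pd.DataFrame(rows)


class TestEfficacyAnalysis:
    def test_identical_groups_not_significant(self):
        traj = _trajectories(
            {"A": [[3, 3, 3]] * 4, "B": [[3, 3, 3]] * 4}
        )
        res = efficacy_analysis(traj, {"ti_total": False})
        assert (res.comparisons["p_value"] >= 0.99).all()
        assert (res.comparisons["stars"] == "ns").all()

    def test_two_timepoint_hand_aucs(self):
        traj = _trajectories({"A": [[4, 4]] * 2, "B": [[4, 3]] * 2}, days=(0, 28))
        res = efficacy_analysis(traj, {"ti_total": False})
        aucs = res.auc_table.set_index("mouse_id")["auc"]
        assert aucs["A0"] == pytest.approx(112.0)
        assert aucs["B0"] == pytest.approx(98.0)

    def test_treated_group_has_lower_burden_every_seed(self):
        # Treatment returns TI to baseline; vehicle stays flared.
        for seed in range(10):
            rng = np.random.default_rng(seed)
            treated = [[3.7, 3.5 + rng.normal(0, 0.02), 3.3] for _ in range(4)]
            vehicle = [[3.7, 3.7 + rng.normal(0, 0.02), 3.75] for _ in range(4)]
            traj = _trajectories({"NP-MTX": treated, "vehicle": vehicle})
            res = efficacy_analysis(traj, {"ti_total": False})
            by_group = res.auc_table.groupby("group")["auc"].mean()
            assert by_group["NP-MTX"] < by_group["vehicle"]

    def test_single_group_rejected(self):
        traj = _trajectories({"A": [[3, 3, 3]] * 4})
        with pytest.raises(ValueError, match="2 groups"):
            efficacy_analysis(traj, {"ti_total": False})


def test_significance_star_thresholds():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"
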