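"""Longitudinal group statistics and AUC-based treatment efficacy.

Cross-sectional two-group comparisons follow a normality-gated routing
rule: ordinal endpoints go straight to the two-sided Mann-Whitney U
test; continuous endpoints are first checked per group with Shapiro-Wilk
at alpha = 0.05 and compared with Student's t test only if *both* groups
pass, otherwise Mann-Whitney. Correlations are Pearson's r for
continuous-continuous pairs and tie-corrected Kendall's tau-b for
continuous-ordinal pairs. No multiple-testing correction is applied by
default (a Holm adjustment can be switched on).

Cumulative disease burden over a treatment period is summarized per
mouse as the trapezoid area under its endpoint trajectory on the
observed day grid, with no baseline subtraction; groups are then
compared on the per-mouse AUCs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "TestReport",
    "CorrelationResult",
    "auc_trapezoid",
    "compare_groups",
    "correlate",
    "interval_summary",
    "efficacy_analysis",
    "EfficacyResult",
    "significance_stars",
]

ALPHA_NORMALITY = 0.05

#: Endpoint columns recognized in score tables, with their ordinal flag.
ENDPOINTS: Dict[str, bool] = {
    "ti_total": False,
    "total_thickness_mm": False,
    "total_clinical_score": True,
}


def auc_trapezoid(days: Sequence[float], values: Sequence[float]) -> float:
    """Composite trapezoid area under one trajectory.

    ``days`` must be strictly increasing (handles irregular grids such
    as measurements every 3-4 days); units are endpoint-units x days.
    """
    d = np.asarray(days, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.size != v.size:
        raise ValueError("days and values must have equal length")
    if d.size < 2:
        raise ValueError("AUC requires at least 2 timepoints")
    if np.any(np.diff(d) <= 0):
        raise ValueError("days must be strictly increasing")
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(v))):
        raise ValueError("days and values must be finite")
    return float(np.trapezoid(v, d))


@dataclass(frozen=True)
class TestReport:
    """Outcome of one gated two-group comparison."""

    test_name: str  # "t" or "Mann-Whitney"
    statistic: float
    p_value: float
    normality_p: Tuple[float, float] | None
    alpha: float
    route: str  # how the test was chosen

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value must be in [0, 1], got {self.p_value}")

    def as_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "normality_p": list(self.normality_p) if self.normality_p else None,
            "alpha": self.alpha,
            "route": self.route,
        }


def _mannwhitney(a: np.ndarray, b: np.ndarray, route: str, normality_p=None) -> TestReport:
    if np.array_equal(np.sort(a), np.sort(b)):
        # Degenerate identical samples: U at its null mean, p = 1.
        return TestReport(
            "Mann-Whitney", float(len(a) * len(b) / 2.0), 1.0, normality_p,
            ALPHA_NORMALITY, route + "; identical samples",
        )
    res = _sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestReport(
        "Mann-Whitney", float(res.statistic), float(min(res.pvalue, 1.0)),
        normality_p, ALPHA_NORMALITY, route,
    )


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    ordinal: bool = False,
    alpha: float = ALPHA_NORMALITY,
) -> TestReport:
    """Two-sided two-group comparison with normality-gated test choice.

    Ordinal endpoints bypass the gate (Mann-Whitney). Continuous
    endpoints run Shapiro-Wilk per group at ``alpha``; Student's t only
    if both groups look normal, Mann-Whitney otherwise (including the
    ambiguous one-normal-one-not case, and groups too small to gate).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("group values must be finite")

    if ordinal:
        return _mannwhitney(a, b, "ordinal endpoint")

    if a.size < 3 or b.size < 3:
        return _mannwhitney(a, b, "group too small for normality gate")

    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0.0:  # constant sample: certainly not Gaussian-looking
            return 0.0
        return float(_sps.shapiro(x).pvalue)

    norm_p = (_shapiro_p(a), _shapiro_p(b))
    if norm_p[0] > alpha and norm_p[1] > alpha:
        res = _sps.ttest_ind(a, b, equal_var=True)
        return TestReport(
            "t", float(res.statistic), float(res.pvalue), norm_p, alpha,
            "both groups normal (Shapiro-Wilk)",
        )
    return _mannwhitney(a, b, "normality rejected in >= 1 group", norm_p)


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" or "kendall"
    coefficient: float
    p_value: float
    n: int

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "coefficient": self.coefficient,
            "p_value": self.p_value,
            "n": self.n,
        }


def correlate(x: Sequence[float], y: Sequence[float], y_ordinal: bool = False) -> CorrelationResult:
    """Pearson r (continuous-continuous) or Kendall tau-b
    (continuous-ordinal) with its two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation requires n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    if y_ordinal:
        res = _sps.kendalltau(x, y)  # tau-b, tie-corrected
        return CorrelationResult("kendall", float(res.statistic), float(res.pvalue), int(x.size))
    res = _sps.pearsonr(x, y)
    return CorrelationResult("pearson", float(res.statistic), float(res.pvalue), int(x.size))


def interval_summary(scores: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Per-group, per-day mean, SD, range and n of one endpoint.

    SD is the sample SD (ddof=1), reported as 0 for a single mouse.
    """
    if endpoint not in scores.columns:
        raise ValueError(f"endpoint {endpoint!r} not in score table")
    if scores.empty:
        raise ValueError("empty score table")

    def _agg(x: pd.Series) -> pd.Series:
        return pd.Series(
            {
                "mean": x.mean(),
                "sd": x.std(ddof=1) if x.size > 1 else 0.0,
                "min": x.min(),
                "max": x.max(),
                "n": x.size,
            }
        )

    out = (
        scores.groupby(["group", "day"])[endpoint]
        .apply(_agg)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


def significance_stars(p: float) -> str:
    """Star notation at the usual thresholds 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class EfficacyResult:
    """Per-mouse AUCs plus pairwise group comparisons on them."""

    auc_table: pd.DataFrame  # mouse_id, group, endpoint, auc
    comparisons: pd.DataFrame  # endpoint, group_a, group_b, test, p, stars

    def as_dict(self) -> dict:
        return {
            "auc_table": self.auc_table.to_dict(orient="records"),
            "comparisons": self.comparisons.to_dict(orient="records"),
        }


def efficacy_analysis(
    trajectories: pd.DataFrame,
    endpoints: Dict[str, bool] | None = None,
    holm: bool = False,
) -> EfficacyResult:
    """Quantify treatment response as per-mouse AUCs and compare groups.

    ``trajectories`` is a score table (one row per mouse and day, a
    ``group`` column, endpoint columns as in :data:`ENDPOINTS`). For
    each endpoint, the trapezoid AUC over each mouse's observed days is
    computed, then every pair of groups is compared on the AUCs with the
    gated test. ``holm`` applies a Holm step-down adjustment across the
    pairwise p values of each endpoint (off by default).
    """
    if endpoints is None:
        endpoints = {k: v for k, v in ENDPOINTS.items() if k in trajectories.columns}
    groups = sorted(trajectories["group"].unique())
    if len(groups) < 2:
        raise ValueError("efficacy analysis requires >= 2 groups")

    auc_rows = []
    for (mouse, group), sub in trajectories.groupby(["mouse_id", "group"]):
        sub = sub.sort_values("day")
        for ep in endpoints:
            auc_rows.append(
                {
                    "mouse_id": mouse,
                    "group": group,
                    "endpoint": ep,
                    "auc": auc_trapezoid(sub["day"].to_numpy(), sub[ep].to_numpy()),
                }
            )
    auc_table = pd.DataFrame(auc_rows)

    comp_rows = []
    for ep, is_ordinal in endpoints.items():
        ep_aucs = auc_table[auc_table["endpoint"] == ep]
        pair_reports = []
        for ga, gb in itertools.combinations(groups, 2):
            va = ep_aucs.loc[ep_aucs["group"] == ga, "auc"]
            vb = ep_aucs.loc[ep_aucs["group"] == gb, "auc"]
            if len(va) < 2 or len(vb) < 2:  # too few mice to test
                continue
            rep = compare_groups(va, vb, ordinal=is_ordinal)
            pair_reports.append((ga, gb, rep))
        pvals = np.array([r.p_value for _, _, r in pair_reports])
        adj = _holm(pvals) if holm else pvals
        for (ga, gb, rep), p in zip(pair_reports, adj):
            comp_rows.append(
                {
                    "endpoint": ep,
                    "group_a": ga,
                    "group_b": gb,
                    "test_name": rep.test_name,
                    "statistic": rep.statistic,
                    "p_value": float(p),
                    "stars": significance_stars(float(p)),
                    "route": rep.route,
                }
            )
    return EfficacyResult(auc_table, pd.DataFrame(comp_rows))


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p values."""
    m = pvals.size
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj
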