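"""End-to-end pipeline: simulate -> score -> classify -> analyze -> report.

Every artifact written by :func:`run_pipeline` is stamped with the run
seed and a hash of the configuration, so a results directory is fully
reproducible from its ``run_metadata.json``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict

import pandas as pd

import pawtherm
from pawtherm.io import RunConfig, config_hash, read_layout_json, write_frame
from pawtherm.radiometry import accuracy_check, fit_calibration
from pawtherm.roi import default_roi_layout, layout_stats
from pawtherm.scoring import mouse_inclusion, score_cohort, severity_heatmap
from pawtherm.simulate import (
    CameraModel,
    CohortConfig,
    generate_calibration_series,
    generate_cohort,
    phantom_frame_for_row,
)
from pawtherm.stats import ENDPOINTS, compare_groups, correlate, efficacy_analysis, interval_summary

__all__ = ["run_pipeline", "score_frames_dir", "analyze_scores", "classify_scores"]

log = logging.getLogger("pawtherm")


def run_pipeline(config: RunConfig) -> Path:
    """Run the whole synthetic study and write a results directory.

    Outputs: ``cohort.csv``, ``scores.csv``, per-modality severity
    heatmaps (CSV + PNG) with selection counts, interval summaries,
    day-of-selection group tests, cross-modality correlations, per-mouse
    AUC efficacy analysis, the calibration QC report and
    ``run_metadata.json``. Deterministic given the seed.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config_hash(config),
             "pawtherm_version": pawtherm.__version__}

    log.info("simulate: generating cohort (seed=%d)", config.seed)
    cohort_cfg = CohortConfig(**{"seed": config.seed, **config.cohort})
    study = generate_cohort(cohort_cfg)
    study.to_csv(out / "cohort.csv")

    if config.write_frames:
        camera = CameraModel(**config.camera)
        frames_dir = out / "frames"
        frames_dir.mkdir(exist_ok=True)
        suffix = "csv" if config.frame_format == "csv" else "tif"
        for (mouse, day), _ in study.table.groupby(["mouse_id", "day"]):
            frame, _layout = phantom_frame_for_row(
                study, mouse, day, camera, seed=config.seed
            )
            write_frame(frame, frames_dir / f"{mouse}_d{day:02d}.{suffix}",
                        config.frame_format)

    log.info("score: computing temperature indices")
    scores = score_cohort(study.table, scale=config.ti_scale)
    scores.to_csv(out / "scores.csv", index=False, float_format="%.4f")

    sel_day = config.selection_day if config.selection_day is not None else max(cohort_cfg.days)
    classify_scores(scores, sel_day, out, stamp)
    analyze_scores(scores, sel_day, out, stamp)

    log.info("calibrate: blackbody QC")
    series = generate_calibration_series(range(35, 41), reps=3, noise_sd=0.1,
                                         seed=config.seed)
    result = fit_calibration(series)
    report = accuracy_check(result, tolerance_c=0.2)
    (out / "calibration.json").write_text(json.dumps(
        {**stamp, "fit": result.as_dict(), "accuracy": report.as_dict()}, indent=2))

    (out / "run_metadata.json").write_text(json.dumps(
        {**stamp, "config": config.as_dict()}, indent=2))
    log.info("done: %s", out)
    return out


def classify_scores(scores: pd.DataFrame, day: int, out: Path, stamp: Dict) -> Dict:
    """Severity heatmaps per modality + cohort-selection counts."""
    log.info("classify: severity heatmaps at day %d", day)
    counts: Dict[str, object] = dict(stamp, day=day)
    from pawtherm.plots import plot_severity_heatmap

    modality_cols = {"TI": "ti_fl", "THK": "thickness_fl_mm", "CS": "clinical_fl"}
    cia = scores[(scores["day"] == day) & (scores["group"] == "CIA")]
    for modality, probe in modality_cols.items():
        if probe not in scores.columns:
            continue
        hm = severity_heatmap(scores, modality, day=day, groups=["CIA"])
        hm.as_frame().to_csv(out / f"heatmap_{modality}.csv")
        plot_severity_heatmap(hm, f"{modality} severity, day {day}",
                              out / f"heatmap_{modality}.png")
        counts[modality] = {
            "n_mice": int(hm.labels.shape[0]),
            "n_moderate_severe": hm.n_moderate_severe,
            "incidence_percent": round(hm.incidence_percent, 1),
        }
    included = [
        mouse for _, row in cia.iterrows()
        if mouse_inclusion({p: row[f"ti_{p.lower()}"] for p in ("FL", "FR", "HL", "HR")})
        for mouse in [row["mouse_id"]]
    ]
    counts["included_mice"] = included
    counts["n_included"] = len(included)
    (out / "selection.json").write_text(json.dumps(counts, indent=2))
    return counts


def analyze_scores(scores: pd.DataFrame, day: int, out: Path, stamp: Dict) -> Dict:
    """Interval summaries, group tests, correlations and AUC efficacy."""
    log.info("analyze: summaries, tests, correlations, AUC")
    from pawtherm.plots import plot_auc_bars, plot_interval_summary

    endpoints = {k: v for k, v in ENDPOINTS.items() if k in scores.columns}
    results: Dict[str, object] = dict(stamp, day=day)

    for ep in endpoints:
        summary = interval_summary(scores, ep)
        summary.to_csv(out / f"summary_{ep}.csv", index=False, float_format="%.4f")
        plot_interval_summary(summary, ep, out / f"summary_{ep}.png")

    at_day = scores[scores["day"] == day]
    tests = {}
    for ep, is_ordinal in endpoints.items():
        groups = sorted(at_day["group"].unique())
        sizes = at_day["group"].value_counts()
        if len(groups) == 2 and (sizes >= 2).all():
            rep = compare_groups(
                at_day.loc[at_day["group"] == groups[0], ep],
                at_day.loc[at_day["group"] == groups[1], ep],
                ordinal=is_ordinal,
            )
            tests[ep] = dict(rep.as_dict(), groups=groups)
    results["group_tests"] = tests

    cia = at_day[at_day["group"] == "CIA"]
    correlations = {}
    if len(cia) >= 3 and "total_thickness_mm" in cia.columns:
        correlations["ti_total_vs_total_thickness"] = correlate(
            cia["ti_total"], cia["total_thickness_mm"]
        ).as_dict()
    if len(cia) >= 3 and "total_clinical_score" in cia.columns:
        correlations["ti_total_vs_total_clinical"] = correlate(
            cia["ti_total"], cia["total_clinical_score"], y_ordinal=True
        ).as_dict()
    results["correlations"] = correlations

    if scores["day"].nunique() >= 2:
        eff = efficacy_analysis(scores, endpoints)
        eff.auc_table.to_csv(out / "auc_per_mouse.csv", index=False, float_format="%.4f")
        eff.comparisons.to_csv(out / "auc_comparisons.csv", index=False, float_format="%.4g")
        for ep in endpoints:
            plot_auc_bars(eff.auc_table, ep, out / f"auc_{ep}.png")
        results["auc_comparisons"] = eff.comparisons.to_dict(orient="records")

    (out / "analysis.json").write_text(json.dumps(results, indent=2))
    return results


def score_frames_dir(
    frames_dir: Path,
    layout_path: str = "default",
    reflected_temp_c: float | None = None,
    scale: str = "celsius",
) -> pd.DataFrame:
    """Score a directory of frame files named ``<mouse>_d<day>.<ext>``.

    Applies the (default or supplied) ROI layout to every frame, builds
    the tidy site table and scores it. With ``reflected_temp_c`` given,
    per-ROI emissivity correction (skin for paws, fur for back) is
    applied to the apparent temperatures first.
    """
    from pawtherm.io import read_frame

    frames_dir = Path(frames_dir)
    paths = sorted(
        p for p in frames_dir.iterdir() if p.suffix.lower() in (".csv", ".tif", ".tiff")
    )
    if not paths:
        raise ValueError(f"no frame files found in {frames_dir}")
    rows = []
    for path in paths:
        stem = path.stem
        if "_d" not in stem:
            raise ValueError(f"frame name {path.name!r} not of form <mouse>_d<day>")
        mouse, day_part = stem.rsplit("_d", 1)
        frame = read_frame(path)
        layout = (
            default_roi_layout(frame.shape)
            if layout_path == "default"
            else read_layout_json(layout_path)
        )
        stats = layout_stats(frame, layout, reflected_temp_c=reflected_temp_c)
        for label, st in stats.items():
            rows.append(
                {
                    "mouse_id": mouse,
                    "group": "unknown",
                    "day": int(day_part),
                    "paw": label,
                    "surface_temp_c": st.mean_c,
                }
            )
    return score_cohort(pd.DataFrame(rows), scale=scale)
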