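"""End-to-end evaluation: predictions -> global frame -> smoothing ->
alignment -> error metrics -> statistics.

The processing order is configurable: smoothing before alignment
(default — the offset estimate from six frames is less noise-sensitive
when the noise has been attenuated first) or alignment before
smoothing.  The incremental geodesic error is invariant to the
alignment either way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Sequence

import numpy as np
import pandas as pd

from headkin import stats as hstats
from headkin.alignment import align_predictions, camera_to_global
from headkin.detection import (
    DetectionCounts,
    detection_metrics,
    match_detections,
    visibility_ratio_series,
    visible_face_area,
)
from headkin.metrics import ErrorSeries, summarize_errors
from headkin.simulate import DEFAULT_PROFILES, TrialRecord
from headkin.smoothing import SmoothingSpec, smooth_sequence

logger = logging.getLogger(__name__)

__all__ = ["EvaluationConfig", "EvaluationResult", "compute_visibility", "evaluate_records", "detection_report"]


@dataclass(frozen=True)
class EvaluationConfig:
    """Knobs of the evaluation pipeline."""

    order: Literal["smooth-then-align", "align-then-smooth"] = "smooth-then-align"
    smoothing_sigmas: Dict[str, float] | None = None  # per model; None -> profile defaults
    truncation: float = 4.0
    iou_threshold: float = 0.3
    stats: hstats.StatsConfig = field(default_factory=hstats.StatsConfig)
    visibility_source: Literal["boxes", "manifest"] = "boxes"


@dataclass
class EvaluationResult:
    errors: pd.DataFrame  # long format, one row per frame per model
    summary: pd.DataFrame  # per-model pooled summary
    stats_report: dict
    binned: pd.DataFrame  # visibility-binned GE/IGE per model
    phases: pd.DataFrame  # per-time-step GE/IGE/visibility per model
    alignments: pd.DataFrame  # per trial-camera-model offset estimates


def compute_visibility(records: Sequence[TrialRecord], source: str = "boxes") -> Dict[str, np.ndarray]:
    """Per-record visibility ratio series, keyed by trial id.

    ``boxes`` recomputes visible areas from the annotated face/occluder
    boxes and normalises per camera over the whole dataset; ``manifest``
    uses the generator's intended ratios directly.
    """
    if source == "manifest":
        return {r.trial_id: r.visibility for r in records}
    areas_by_cam: Dict[str, list] = {}
    index: Dict[str, list] = {}
    for rec in records:
        areas = [visible_face_area(f) for f in rec.boxes]
        areas_by_cam.setdefault(rec.camera, []).extend(areas)
        index.setdefault(rec.camera, []).append((rec.trial_id, len(areas)))
    ratios = visibility_ratio_series(areas_by_cam)
    out: Dict[str, np.ndarray] = {}
    for cam, entries in index.items():
        pos = 0
        for tid, n in entries:
            out[tid] = ratios[cam][pos : pos + n]
            pos += n
    return out


def _sigma_for(model: str, config: EvaluationConfig) -> float:
    if config.smoothing_sigmas and model in config.smoothing_sigmas:
        return config.smoothing_sigmas[model]
    if model in DEFAULT_PROFILES:
        return DEFAULT_PROFILES[model].smoothing_sigma
    return 0.0


def evaluate_records(
    records: Sequence[TrialRecord],
    config: EvaluationConfig | None = None,
) -> EvaluationResult:
    """Run the full evaluation over a set of trial records."""
    config = config or EvaluationConfig()
    visibility = compute_visibility(records, config.visibility_source)
    series: List[ErrorSeries] = []
    align_rows = []
    for rec in records:
        vis = visibility[rec.trial_id]
        for model, pred_cam in rec.predictions.items():
            pred = camera_to_global(pred_cam, rec.extrinsics)
            spec = SmoothingSpec(sigma=_sigma_for(model, config), truncation=config.truncation)
            if config.order == "smooth-then-align":
                pred = smooth_sequence(pred, spec)
                pred, ares = align_predictions(rec.reference_video, pred)
            else:
                pred, ares = align_predictions(rec.reference_video, pred)
                pred = smooth_sequence(pred, spec)
            series.append(
                ErrorSeries.from_sequences(
                    rec.reference_video,
                    pred,
                    visibility=vis,
                    participant=rec.participant,
                    trial=rec.trial,
                    trial_type=rec.trial_type,
                    camera=rec.camera,
                    model=model,
                )
            )
            align_rows.append(
                {
                    "trial_id": rec.trial_id,
                    "model": model,
                    **{k: v for k, v in ares.to_dict().items() if not k.endswith("row_major")},
                }
            )
    errors = pd.concat([s.to_frame() for s in series], ignore_index=True)
    summary = summarize_errors(errors, by=["model"]).sort_values("mean_ge_deg").reset_index(drop=True)
    stats_report = _stats_battery(errors, config.stats)
    binned = _binned_errors(errors, config.stats)
    phases = _phase_table(errors, config.stats)
    return EvaluationResult(
        errors=errors,
        summary=summary,
        stats_report=stats_report,
        binned=binned,
        phases=phases,
        alignments=pd.DataFrame(align_rows),
    )


def _per_trial_means(errors: pd.DataFrame, value: str) -> pd.DataFrame:
    return (
        errors.groupby(["model", "participant", "trial", "trial_type", "camera"])[value]
        .mean()
        .reset_index()
    )


def _stats_battery(errors: pd.DataFrame, cfg: hstats.StatsConfig) -> dict:
    """Normality gate, paired F-vs-S, unpaired L-vs-R, correlations, Bland-Altman.

    Camera comparisons pair per-trial mean errors (the same physical
    trial seen by both cameras); trial-type comparisons are unpaired
    over per-trial means.  Raw p-values, no multiple-testing correction.
    """
    report: dict = {
        "alpha": cfg.alpha,
        "multiple_testing_correction": "none (raw p-values)",
        "models": {},
    }
    for model, sub in errors.groupby("model"):
        entry: dict = {}
        ge = sub["ge_deg"].to_numpy()
        p_norm, nonpar = hstats.normality_gate(ge, alpha=cfg.alpha)
        entry["normality"] = {"shapiro_p": p_norm, "use_nonparametric": nonpar}
        for value, key in (("ge_deg", "ge"), ("ige_deg", "ige")):
            per_trial = _per_trial_means(sub.dropna(subset=[value]), value)
            wide = per_trial.pivot_table(
                index=["participant", "trial"], columns="camera", values=value
            ).dropna()
            cam_res = None
            if {"F", "S"}.issubset(wide.columns) and len(wide) >= 5:
                r = hstats.wilcoxon_signed_rank(wide["S"], wide["F"])
                cam_res = {
                    "method": r.method,
                    "statistic": r.statistic,
                    "p": r.p_value,
                    "n_pairs": r.n,
                    "median_diff_S_minus_F": r.effect_size,
                    "significant": bool(r.p_value < cfg.alpha),
                }
            entry[f"camera_F_vs_S_{key}"] = cam_res
            l_vals = per_trial.loc[per_trial["trial_type"] == "L", value].to_numpy()
            r_vals = per_trial.loc[per_trial["trial_type"] == "R", value].to_numpy()
            tt_res = None
            if len(l_vals) >= 3 and len(r_vals) >= 3:
                r2 = hstats.mann_whitney_u(l_vals, r_vals)
                tt_res = {
                    "method": r2.method,
                    "statistic": r2.statistic,
                    "p": r2.p_value,
                    "n": r2.n,
                    "cliffs_delta_L_vs_R": r2.effect_size,
                    "significant": bool(r2.p_value < cfg.alpha),
                }
            entry[f"trial_type_L_vs_R_{key}"] = tt_res
        mag_ref = sub["magnitude_ref_deg"].to_numpy()
        mag_pred = sub["magnitude_pred_deg"].to_numpy()
        entry["magnitude_pearson_r"] = hstats.pearson_r(mag_ref, mag_pred)
        bias, lo, hi = hstats.bland_altman_nonparametric(mag_pred, mag_ref)
        entry["bland_altman_magnitude"] = {
            "median_bias_deg": bias,
            "loa_low_deg": lo,
            "loa_high_deg": hi,
        }
        report["models"][model] = entry
    return report


def _binned_errors(errors: pd.DataFrame, cfg: hstats.StatsConfig) -> pd.DataFrame:
    rows = []
    for model, sub in errors.groupby("model"):
        for value, name in (("ge_deg", "ge"), ("ige_deg", "ige")):
            # IGE rows are NaN on first frames; the first visibility
            # sample is thereby excluded from incremental analyses.
            ok = sub.dropna(subset=[value, "visibility"])
            table = hstats.bin_by_visibility(
                ok[value].to_numpy(), ok["visibility"].to_numpy(), cfg.visibility_bins
            )
            table["model"] = model
            table["metric"] = name
            rows.append(table)
    return pd.concat(rows, ignore_index=True)


def _phase_table(errors: pd.DataFrame, cfg: hstats.StatsConfig) -> pd.DataFrame:
    rows = []
    for model, sub in errors.groupby("model"):
        for value, name in (("ge_deg", "ge"), ("ige_deg", "ige"), ("visibility", "visibility")):
            ok = sub.dropna(subset=[value])
            table = hstats.phase_aggregate(ok["t_ms"].to_numpy(), ok[value].to_numpy(), cfg)
            table["model"] = model
            table["metric"] = name
            rows.append(table)
    return pd.concat(rows, ignore_index=True)


def detection_report(records: Sequence[TrialRecord], threshold: float = 0.3) -> dict:
    """Pooled detection precision/recall/F1 over every annotated frame."""
    counts = DetectionCounts(0, 0, 0)
    for rec in records:
        for frame in rec.boxes:
            counts = counts + match_detections(frame, threshold=threshold)
    precision, recall, f1 = detection_metrics(counts)
    return {
        "tp": counts.tp,
        "fp": counts.fp,
        "fn": counts.fn,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "iou_threshold": threshold,
    }
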