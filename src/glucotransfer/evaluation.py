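"""Segment-level prediction metrics and the seven-configuration comparison.

Four errors are computed per test segment over its 18 postprandial CGM
samples: RMSE, MAE, the absolute difference of the summed trajectories
(ERR_AUC) and the absolute difference of the postprandial maxima (ERR_MAX).
Scores are averaged (with standard errors) within two strata — segments
with and without postprandial exercise (energy expenditure > 60 kcal) —
because the exercise stratum is where the modelling choices and transfer
learning matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .segments import SegmentSet, Segment, is_exercise_segment
from .responses import PersonParams, predict
from .inference import SamplerConfig, point_estimates, fit_target_task
from .transfer import RescalePolicy, run_transfer_pipeline

METRIC_NAMES = ("rmse", "mae", "err_auc", "err_max")

#: the seven model x transfer configurations compared in the evaluation
CONFIGURATIONS = (
    ("Mbase", "single", "none"),
    ("Madd", "additive", "none"),
    ("Msyn", "synergistic", "none"),
    ("Madd+trans", "additive", "normal"),
    ("Msyn+trans", "synergistic", "normal"),
    ("Madd+trans_ext", "additive", "extended"),
    ("Msyn+trans_ext", "synergistic", "extended"),
)


@dataclass
class SegmentMetrics:
    """The four error metrics for one segment."""

    rmse: float
    mae: float
    err_auc: float
    err_max: float
    exercise_flag: bool = False

    def as_tuple(self):
        return (self.rmse, self.mae, self.err_auc, self.err_max)


def segment_metrics(y: np.ndarray, y_hat: np.ndarray,
                    exercise_flag: bool = False) -> SegmentMetrics:
    """RMSE, MAE, |sum difference| and |max difference| over one grid."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("observed and predicted series must have equal length")
    diff = y - y_hat
    return SegmentMetrics(
        rmse=float(np.sqrt(np.mean(diff ** 2))),
        mae=float(np.mean(np.abs(diff))),
        err_auc=float(abs(np.sum(y) - np.sum(y_hat))),
        err_max=float(abs(np.max(y) - np.max(y_hat))),
        exercise_flag=exercise_flag,
    )


def evaluate_segment(segment: Segment, params: PersonParams,
                     model_kind: str) -> SegmentMetrics:
    """Predict one segment with point-estimate parameters and score it."""
    traj = predict(model_kind, params, segment)
    return segment_metrics(segment.post_glucose, traj.y_hat,
                           exercise_flag=is_exercise_segment(segment))


@dataclass
class MetricReport:
    """Mean +/- standard error of each metric per configuration and stratum."""

    table: pd.DataFrame   # rows: (configuration, stratum); cols: metric means/SEs/n

    def to_csv(self, path: str | Path) -> None:
        pretty = self.table.copy()
        for m in METRIC_NAMES:
            pretty[m] = [f"{mu:.2f} (±{se:.2f})" for mu, se in
                         zip(self.table[f"{m}_mean"], self.table[f"{m}_se"])]
        cols = ["configuration", "stratum", "n"] + list(METRIC_NAMES)
        pretty[cols].to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.table.to_json(orient="records", indent=1))

    def stratum(self, configuration: str, with_exercise: bool) -> Optional[pd.Series]:
        name = "with_exercise" if with_exercise else "without_exercise"
        rows = self.table[(self.table.configuration == configuration)
                          & (self.table.stratum == name)]
        return rows.iloc[0] if len(rows) else None


def aggregate(metrics: Sequence[SegmentMetrics],
              configuration: str = "model") -> MetricReport:
    """Stratify by exercise flag and average each metric with its SE.

    A stratum with a single segment reports SE = 0 (flagged by n = 1); an
    empty stratum is absent from the table.
    """
    rows = []
    for name, flag in (("with_exercise", True), ("without_exercise", False)):
        vals = np.array([m.as_tuple() for m in metrics if m.exercise_flag == flag])
        if vals.size == 0:
            continue
        n = vals.shape[0]
        row = {"configuration": configuration, "stratum": name, "n": n}
        for j, metric in enumerate(METRIC_NAMES):
            row[f"{metric}_mean"] = float(vals[:, j].mean())
            row[f"{metric}_se"] = float(vals[:, j].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(row)
    return MetricReport(table=pd.DataFrame(rows))


def evaluate_posterior(test_segments: SegmentSet, posterior,
                       model_kind: str, configuration: str = "model") -> MetricReport:
    """Score a fitted posterior's median parameters on held-out segments."""
    params = point_estimates(posterior)
    per_segment = [evaluate_segment(seg, params[seg.person_id], model_kind)
                   for seg in test_segments if seg.person_id in params]
    return MetricReport(table=aggregate(per_segment, configuration).table)


def score_configuration(rct_train: Optional[SegmentSet],
                        patient_segments: SegmentSet,
                        model_kind: str, mode: str,
                        config: SamplerConfig,
                        source_config: Optional[SamplerConfig] = None,
                        source_summary=None,
                        per_session: bool = True):
    """Per-segment test metrics for one model x transfer configuration.

    Sessions are heterogeneous (months apart in the emulated study), so the
    model is fitted within each session — days 1-2 of a session train the
    model evaluated on that session's day 3 — and per-segment metrics are
    pooled across sessions.  Returns (metrics, source_summary); the source
    summary can be reused across configurations of the same model kind.
    """
    from .segments import SegmentSet as _SS

    session_ids = sorted({s.session_id for s in patient_segments}) \
        if per_session else [None]
    metrics: list[SegmentMetrics] = []
    for sid in session_ids:
        segs = patient_segments if sid is None else _SS(
            [s for s in patient_segments if s.session_id == sid],
            patient_segments.group)
        train = segs.subset("train")
        test = segs.subset("test")
        if not len(test) or not len(train):
            continue
        if mode == "none":
            posterior = fit_target_task(train, model_kind, config=config)
        else:
            result = run_transfer_pipeline(
                rct_train, train, model_kind, RescalePolicy(mode=mode),
                config=config, source_config=source_config,
                source_summary=source_summary)
            source_summary = result.source_summary
            posterior = result.target_posterior
        params = point_estimates(posterior)
        metrics += [evaluate_segment(seg, params[seg.person_id], model_kind)
                    for seg in test if seg.person_id in params]
    return metrics, source_summary


def run_comparison(rct_train: Optional[SegmentSet],
                   patient_segments: SegmentSet,
                   config: Optional[SamplerConfig] = None,
                   source_config: Optional[SamplerConfig] = None,
                   configurations: Sequence[tuple] = CONFIGURATIONS,
                   per_session: bool = True) -> MetricReport:
    """Fit and score the requested model x transfer configurations.

    ``patient_segments`` must carry train/test roles.  One source fit per
    model kind is shared by its normal and extended transfer variants.
    """
    if config is None:
        config = SamplerConfig()
    if not len(patient_segments.subset("test")):
        raise ValueError("no test segments: assign roles with split_train_test")

    source_cache: dict[str, object] = {}
    tables = []
    for label, model_kind, mode in configurations:
        metrics, summary = score_configuration(
            rct_train, patient_segments, model_kind, mode, config,
            source_config=source_config,
            source_summary=source_cache.get(model_kind),
            per_session=per_session)
        if summary is not None:
            source_cache[model_kind] = summary
        tables.append(aggregate(metrics, label).table)
    return MetricReport(table=pd.concat(tables, ignore_index=True))
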