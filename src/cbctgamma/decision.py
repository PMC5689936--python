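"""Re-CT decision rule, cohort scoring, and ROC parameter training.

A re-CT recommendation fires when ``run_length`` (default 3) *consecutive*
MQP values are less than or equal to a negative decision threshold.
"Consecutive" means consecutive acquired comparisons: calendar gaps between
CBCTs do not break a run, an above-threshold MQP does.

Against a recorded re-CT order at fraction f_o, a trigger at fraction f_t is
a true positive when |f_t − f_o| ≤ window (default ±3 fractions), a false
positive when too early, and a false negative when too late or absent.  A
segment with no order scores a true negative unless the algorithm triggers.

Training sweeps gamma criteria (DTA, dHU), failed-histogram percentile, and
the 500-value threshold grid −0.001 … −0.5, scoring TP/TN/FP/FN over a
cohort; the operating point maximizing the Youden index J = TPF − FPF is
selected with a deterministic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gamma import GammaCriteria
from .grids import Mask3D
from .io import Course
from .masking import build_analysis_mask
from .mqp import MQPSeries, segment_comparisons, series_from_comparisons

@dataclass(frozen=True)
class DecisionConfig:
    """Threshold (< 0), required run length, and the TP fraction window."""

    threshold: float
    run_length: int = 3
    window: int = 3

    def __post_init__(self) -> None:
        if self.threshold >= 0:
            raise ValueError(
                "decision threshold must be negative; positive thresholds would "
                "recommend re-CT when the match has not deteriorated"
            )
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")
        if self.window < 0:
            raise ValueError("window must be >= 0")


@dataclass(frozen=True)
class TriggerResult:
    triggered: bool
    trigger_fraction: int | None
    segment: int

    def __post_init__(self) -> None:
        if self.triggered != (self.trigger_fraction is not None):
            raise ValueError("trigger_fraction must be present iff triggered")


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    n_non_evaluable: int = 0

    @property
    def tpf(self) -> float | None:
        """Sensitivity; None when there are no evaluable positives."""
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def fpf(self) -> float | None:
        """1 − specificity; None when there are no evaluable negatives."""
        d = self.fp + self.tn
        return self.fp / d if d else None


@dataclass(frozen=True)
class ParameterSet:
    """One operating point of the sweep with its cohort performance."""

    dta: float
    dhu: float
    percentile: float
    threshold: float
    tp: int
    tn: int
    fp: int
    fn: int
    tpf: float | None
    fpf: float | None


def evaluate_trigger(series: MQPSeries, cfg: DecisionConfig) -> TriggerResult:
    """First record completing ``run_length`` consecutive MQP ≤ threshold.

    The segment's zero-valued reference record participates in the scan (it
    can never satisfy a negative threshold, so it acts as a run breaker at
    the start of the series).
    """
    run = 0
    for rec in series.records:
        if rec.mqp <= cfg.threshold:
            run += 1
            if run == cfg.run_length:
                return TriggerResult(True, rec.fraction, series.segment)
        else:
            run = 0
    return TriggerResult(False, None, series.segment)


def is_evaluable(series: MQPSeries, cfg: DecisionConfig) -> bool:
    """A segment qualifies when it has ≥ run_length comparisons beyond the
    reference comparison."""
    if series.non_evaluable_reason is not None:
        return False
    return len(series.records) - 1 >= cfg.run_length


def classify_outcome(
    trigger: TriggerResult,
    rect_order_fraction: int | None,
    cfg: DecisionConfig,
    evaluable: bool = True,
) -> str:
    """Label a segment TP/TN/FP/FN against the recorded re-CT order."""
    if not evaluable:
        return "non-evaluable"
    if rect_order_fraction is None:
        return "FP" if trigger.triggered else "TN"
    if not trigger.triggered:
        return "FN"
    f_t, f_o = trigger.trigger_fraction, rect_order_fraction
    if abs(f_t - f_o) <= cfg.window:
        return "TP"
    return "FP" if f_t < f_o - cfg.window else "FN"


def score_cohort(labels: Iterable[str]) -> ConfusionCounts:
    """Tally outcome labels; non-evaluable segments stay out of denominators."""
    counts = ConfusionCounts()
    for lab in labels:
        if lab == "TP":
            counts.tp += 1
        elif lab == "TN":
            counts.tn += 1
        elif lab == "FP":
            counts.fp += 1
        elif lab == "FN":
            counts.fn += 1
        elif lab == "non-evaluable":
            counts.n_non_evaluable += 1
        else:
            raise ValueError(f"unknown outcome label {lab!r}")
    return counts


def threshold_grid() -> list[float]:
    """The training sweep's thresholds: −0.001·k for k = 1..500."""
    return [float(-k) / 1000.0 for k in range(1, 501)]


DEFAULT_DTA_GRID = (3.0, 4.0, 5.0, 6.0, 7.0)
DEFAULT_DHU_GRID = (20.0, 30.0, 40.0, 50.0, 60.0)
DEFAULT_PERCENTILE_GRID = tuple(float(x) for x in range(50, 96, 5))


def roc_sweep(
    courses: Sequence[Course],
    dta_grid: Sequence[float] = (3.0,),
    dhu_grid: Sequence[float] = (30.0,),
    percentile_grid: Sequence[float] = (80.0,),
    thresholds: Sequence[float] | None = None,
    run_length: int = 3,
    window: int = 3,
    margin_mm: float = 10.0,
    cap: float = 5.0,
    masks: Sequence[Mask3D] | None = None,
) -> pd.DataFrame:
    """Sweep (DTA, dHU, percentile, threshold) over a cohort.

    The expensive gamma stage runs once per (course, DTA, dHU); percentile
    and threshold reuse the cached failed-pixel sets.  Per-course failures
    (e.g. missing masks) are raised as named errors, never dropped silently.
    Returns one row per parameter combination with TP/TN/FP/FN and rates
    (NaN where a rate's denominator is zero).
    """
    if thresholds is None:
        thresholds = threshold_grid()
    if masks is None:
        masks = []
        for course in courses:
            if course.external is None or course.ctv is None:
                raise ValueError(
                    f"course {course.manifest.patient_id!r} has no structure masks"
                )
            masks.append(build_analysis_mask(course.external, course.ctv, margin_mm))

    rows = []
    for dta in dta_grid:
        for dhu in dhu_grid:
            criteria = GammaCriteria(dta, dhu)
            cached = []
            for course, mask in zip(courses, masks):
                try:
                    cached.append(
                        (course, segment_comparisons(course, criteria, mask, cap=cap))
                    )
                except Exception as err:
                    raise RuntimeError(
                        f"gamma stage failed for course "
                        f"{course.manifest.patient_id!r}: {err}"
                    ) from err
            for x in percentile_grid:
                per_segment = []  # (mqp series, order fraction)
                for course, scs in cached:
                    for sc in scs:
                        series = series_from_comparisons(sc, x)
                        order = course.manifest.rect_orders.get(sc.segment)
                        per_segment.append((series, order))
                for thr in thresholds:
                    cfg = DecisionConfig(thr, run_length, window)
                    labels = [
                        classify_outcome(
                            evaluate_trigger(s, cfg), order, cfg,
                            evaluable=is_evaluable(s, cfg),
                        )
                        for s, order in per_segment
                    ]
                    counts = score_cohort(labels)
                    rows.append(
                        {
                            "dta": dta,
                            "dhu": dhu,
                            "percentile": x,
                            "threshold": thr,
                            "tp": counts.tp,
                            "tn": counts.tn,
                            "fp": counts.fp,
                            "fn": counts.fn,
                            "n_non_evaluable": counts.n_non_evaluable,
                            "tpf": np.nan if counts.tpf is None else counts.tpf,
                            "fpf": np.nan if counts.fpf is None else counts.fpf,
                        }
                    )
    return pd.DataFrame(rows)


def select_optimum(table: pd.DataFrame) -> ParameterSet:
    """Operating point maximizing Youden's J = TPF − FPF.

    Ties break deterministically: higher TPF, then more negative threshold,
    then smaller DTA, smaller dHU, smaller percentile.  Rows with undefined
    rates are excluded; an all-undefined table is an error.
    """
    ok = table.dropna(subset=["tpf", "fpf"])
    if ok.empty:
        raise ValueError("no table rows with defined TPF and FPF")
    j = ok["tpf"] - ok["fpf"]
    key = list(
        zip(j, ok["tpf"], -ok["threshold"], -ok["dta"], -ok["dhu"], -ok["percentile"])
    )
    best = ok.iloc[max(range(len(key)), key=key.__getitem__)]
    return ParameterSet(
        dta=float(best["dta"]),
        dhu=float(best["dhu"]),
        percentile=float(best["percentile"]),
        threshold=float(best["threshold"]),
        tp=int(best["tp"]),
        tn=int(best["tn"]),
        fp=int(best["fp"]),
        fn=int(best["fn"]),
        tpf=float(best["tpf"]),
        fpf=float(best["fpf"]),
    )
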