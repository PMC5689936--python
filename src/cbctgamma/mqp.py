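"""Failed-pixel statistics and the match quality parameter (MQP).

Voxels with gamma > 1 form the *failed-pixel histogram*; anatomy mismatch
shifts it right.  The x-th percentile of that histogram, gamma_x, summarizes
one comparison, and the match quality parameter for fraction i is

    MQP_{x,i} = gamma_{x,ref} - gamma_{x,i}

where the reference comparison is the first vs. second CBCT of the plan
segment, and comparison i is the first CBCT vs. the CBCT at fraction i.
MQP is 0 for the reference comparison by construction and becomes negative
as the match deteriorates.  A replan starts a new segment with a fresh
reference, so the MQP resets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gamma import GammaCriteria, GammaMap, gamma_map
from .grids import Mask3D
from .io import Course
from .masking import build_analysis_mask


@dataclass
class FailedGammaSet:
    """Sorted gamma values > 1 from one comparison's masked voxels."""

    values: np.ndarray
    n_masked: int
    cap: float

    @property
    def n_failed(self) -> int:
        return int(self.values.size)


def failed_gammas(gmap: GammaMap) -> FailedGammaSet:
    """Extract and sort masked gamma values strictly greater than 1.

    gamma == 1.0 is a PASS; failure is strict.  A warning is emitted when
    more than 10% of the failed values sit at the cap (percentile saturation).
    """
    vals = gmap.masked_values()
    failed = np.sort(vals[vals > 1.0])
    if failed.size:
        saturated = np.count_nonzero(failed >= gmap.cap - 1e-12) / failed.size
        if saturated > 0.10:
            warnings.warn(
                f"{saturated:.0%} of failed gamma values saturate at cap={gmap.cap}; "
                "percentiles may be clipped — consider a larger cap",
                stacklevel=2,
            )
    return FailedGammaSet(failed, n_masked=int(vals.size), cap=gmap.cap)


def percentile_of_failed(fs: FailedGammaSet, x: float) -> float:
    """x-th percentile of the failed set, linear interpolation between ranks.

    The rank convention is 1 + (n-1)*x/100 on the ascending values.  An empty
    failed set returns 1.0, the pass/fail boundary (a failure-free comparison
    sits exactly at the boundary, making MQP = 0 when both comparisons are
    failure-free).
    """
    if not 0 <= x <= 100:
        raise ValueError(f"percentile must be in [0, 100], got {x}")
    if fs.n_failed == 0:
        return 1.0
    return float(np.percentile(fs.values, x))


def mqp_value(gamma_ref_x: float, gamma_i_x: float) -> float:
    """MQP = gamma_x,ref − gamma_x,i; negative when the later match is worse."""
    return float(gamma_ref_x) - float(gamma_i_x)


@dataclass
class MQPRecord:
    fraction: int
    gamma_x: float
    mqp: float
    n_masked: int
    n_failed: int


@dataclass
class MQPSeries:
    """Per-segment MQP records, starting with the (zero) reference record."""

    segment: int
    reference_fraction: int
    percentile: float
    criteria: GammaCriteria
    gamma_ref_x: float | None = None
    records: list[MQPRecord] = field(default_factory=list)
    non_evaluable_reason: str | None = None

    @property
    def evaluable_records(self) -> list[MQPRecord]:
        return self.records

    def mqp_values(self) -> list[float]:
        return [r.mqp for r in self.records]

    def fractions(self) -> list[int]:
        return [r.fraction for r in self.records]


# -- two-stage construction: gamma percentile data once, series per percentile


@dataclass
class SegmentComparisons:
    """Cached failed-gamma sets for one plan segment at one gamma criteria."""

    segment: int
    reference_fraction: int
    criteria: GammaCriteria
    comparisons: list[tuple[int, FailedGammaSet]] = field(default_factory=list)
    non_evaluable_reason: str | None = None


def segment_comparisons(
    course: Course,
    criteria: GammaCriteria,
    mask: Mask3D,
    cap: float = 5.0,
) -> list[SegmentComparisons]:
    """Run the gamma stage once per comparison for every segment of a course.

    Within a segment the reference volume is its first CBCT; every later CBCT
    is compared against it.  Segments with fewer than two CBCTs cannot define
    a reference comparison and are marked non-evaluable rather than failing.
    """
    out: list[SegmentComparisons] = []
    for seg in course.manifest.segments:
        entries = course.manifest.segment_entries(seg)
        sc = SegmentComparisons(seg, entries[0].fraction, criteria)
        if len(entries) < 2:
            sc.non_evaluable_reason = "segment has < 2 CBCTs (no reference comparison)"
            out.append(sc)
            continue
        ref = course.volume(entries[0].fraction)
        for entry in entries[1:]:
            ev = course.volume(entry.fraction)
            gmap = gamma_map(ref, ev, criteria, mask, cap=cap)
            sc.comparisons.append((entry.fraction, failed_gammas(gmap)))
        out.append(sc)
    return out


def series_from_comparisons(sc: SegmentComparisons, x: float) -> MQPSeries:
    """Build the MQP series at percentile ``x`` from cached comparisons."""
    series = MQPSeries(sc.segment, sc.reference_fraction, x, sc.criteria,
                       non_evaluable_reason=sc.non_evaluable_reason)
    if sc.non_evaluable_reason is not None or not sc.comparisons:
        return series
    gamma_ref = percentile_of_failed(sc.comparisons[0][1], x)
    series.gamma_ref_x = gamma_ref
    for fraction, fs in sc.comparisons:
        gx = percentile_of_failed(fs, x)
        series.records.append(
            MQPRecord(fraction, gx, mqp_value(gamma_ref, gx), fs.n_masked, fs.n_failed)
        )
    return series


def build_mqp_series(
    course: Course,
    criteria: GammaCriteria,
    x: float = 80.0,
    mask: Mask3D | None = None,
    margin_mm: float = 10.0,
    cap: float = 5.0,
) -> list[MQPSeries]:
    """Full course → one MQP series per plan segment.

    If no analysis mask is given it is built from the course's external and
    CTV masks (external + ``margin_mm``, z-limited by the CTV).
    """
    if mask is None:
        if course.external is None or course.ctv is None:
            raise ValueError("course has no masks; pass an analysis mask explicitly")
        mask = build_analysis_mask(course.external, course.ctv, margin_mm)
    return [
        series_from_comparisons(sc, x)
        for sc in segment_comparisons(course, criteria, mask, cap=cap)
    ]


def series_to_frame(series_list: list[MQPSeries]) -> pd.DataFrame:
    """Flatten MQP series to a table: segment, fraction, n_masked, n_failed,
    gamma_x, mqp."""
    rows = []
    for s in series_list:
        for r in s.records:
            rows.append(
                {
                    "segment": s.segment,
                    "fraction": r.fraction,
                    "n_masked": r.n_masked,
                    "n_failed": r.n_failed,
                    "gamma_x": r.gamma_x,
                    "mqp": r.mqp,
                }
            )
    return pd.DataFrame(rows, columns=["segment", "fraction", "n_masked",
                                       "n_failed", "gamma_x", "mqp"])
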