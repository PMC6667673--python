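"""Reliability and accuracy metrics for angular-velocity gait detection.

Reliability is the number of angular-velocity zero crossings per stride
(the concept needs exactly one per direction: one neg-to-pos near
heel-strike, one pos-to-neg near toe-off; more means unreliable).

Accuracy is the timing offset between a detected event and its force-based
reference event, expressed as a percentage of the gait cycle the reference
event belongs to; negative means the detection was early.  Offsets
aggregate in two stages — strides to a subject mean, subject means to a
group mean and standard deviation — so subjects with more strides do not
dominate the group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .grf_events import EventKind, GaitEvent, Stride
from .signals import Direction, TimeSeries, find_sign_changes

__all__ = [
    "StrideCrossingCount",
    "TimingOffset",
    "count_crossings_per_stride",
    "timing_offset_pct",
    "match_events",
    "aggregate_condition",
]

#: Matching window: a detected event may sit at most this fraction of the
#: reference stride away from its reference event.
MATCH_WINDOW_FRACTION = 0.5


@dataclass(frozen=True)
class StrideCrossingCount:
    stride: Stride
    n_pos_to_neg: int
    n_neg_to_pos: int

    @property
    def n_total(self) -> int:
        return self.n_pos_to_neg + self.n_neg_to_pos


@dataclass(frozen=True)
class TimingOffset:
    kind: EventKind
    limb: str
    detected_time: float
    reference_time: float
    stride_duration: float
    offset_pct: float


def count_crossings_per_stride(
    omega: TimeSeries, strides: list[Stride]
) -> list[StrideCrossingCount]:
    """Zero crossings of ``omega`` binned into [hs, next_hs) stride windows."""
    crossings = find_sign_changes(omega)
    out = []
    for stride in strides:
        inside = [c for c in crossings if stride.contains(c.time)]
        out.append(
            StrideCrossingCount(
                stride=stride,
                n_pos_to_neg=sum(c.direction is Direction.POS_TO_NEG for c in inside),
                n_neg_to_pos=sum(c.direction is Direction.NEG_TO_POS for c in inside),
            )
        )
    return out


def timing_offset_pct(detected_t: float, reference_t: float, stride_duration: float) -> float:
    """Timing offset as % of gait cycle; negative = detected early."""
    if stride_duration <= 0:
        raise InvalidParameterError("stride_duration must be > 0")
    return 100.0 * (detected_t - reference_t) / stride_duration


def _containing_stride(t: float, strides: list[Stride], limb: str) -> Stride | None:
    for s in strides:
        if s.limb == limb and s.contains(t):
            return s
    return None


def match_events(
    detected: list[GaitEvent],
    reference: list[GaitEvent],
    strides: list[Stride],
) -> tuple[list[TimingOffset], list[GaitEvent], list[GaitEvent]]:
    """Pair detected with reference events of the same limb and kind.

    Greedy nearest-in-time matching: candidate pairs are considered in
    order of increasing |time difference| and accepted while both events
    are unused and the difference stays within half the duration of the
    stride containing the reference event (reference events outside any
    stride are unmatchable).  Returns the matched timing offsets plus the
    leftover detected and reference events.
    """
    offsets: list[TimingOffset] = []
    used_det: set[int] = set()
    used_ref: set[int] = set()
    pairs: list[tuple[float, int, int, Stride]] = []
    for ri, ref in enumerate(reference):
        stride = _containing_stride(ref.time, strides, ref.limb)
        if stride is None:
            continue
        for di, det in enumerate(detected):
            if det.limb != ref.limb or det.kind is not ref.kind:
                continue
            dt = abs(det.time - ref.time)
            if dt <= MATCH_WINDOW_FRACTION * stride.duration:
                pairs.append((dt, di, ri, stride))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    for dt, di, ri, stride in pairs:
        if di in used_det or ri in used_ref:
            continue
        used_det.add(di)
        used_ref.add(ri)
        det, ref = detected[di], reference[ri]
        offsets.append(
            TimingOffset(
                kind=ref.kind,
                limb=ref.limb,
                detected_time=det.time,
                reference_time=ref.time,
                stride_duration=stride.duration,
                offset_pct=timing_offset_pct(det.time, ref.time, stride.duration),
            )
        )
    offsets.sort(key=lambda o: o.reference_time)
    extra_det = [d for i, d in enumerate(detected) if i not in used_det]
    extra_ref = [r for i, r in enumerate(reference) if i not in used_ref]
    return offsets, extra_det, extra_ref


def aggregate_condition(per_stride: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Two-stage aggregation of per-stride values.

    ``per_stride`` needs columns ``subject``, ``condition`` and the value
    column.  Stage one averages strides within each subject-condition;
    stage two averages subject means within each condition and takes their
    sample standard deviation (reported as NaN for a single subject).
    Returns one row per condition with ``mean``, ``sd`` and ``n_subjects``.
    """
    required = {"subject", "condition", value}
    if not required.issubset(per_stride.columns):
        raise InvalidParameterError(f"per_stride must have columns {sorted(required)}")
    if per_stride.empty:
        raise InvalidParameterError("empty per-stride table")
    subj = (
        per_stride.groupby(["condition", "subject"], sort=True)[value]
        .mean()
        .reset_index()
    )
    grp = subj.groupby("condition", sort=True)[value].agg(
        mean="mean", sd=lambda v: v.std(ddof=1), n_subjects="count"
    )
    return grp.reset_index()
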