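"""Reference gait events from the vertical ground reaction force.

Heel-strike: each rising crossing of a 400 N trigger starts a backward scan
through the *unfiltered* force; the heel-strike is the first sample, going
backward, that is at or below 0 N, or that exceeds its successor while being
below 10 N (a local bump of the near-zero noise just before contact).  The
400 N trigger is deliberately high so that light touches of the wrong belt
of a split-belt treadmill during swing never start a scan; it is
subject-dependent and therefore a parameter.

Toe-off: the force is first smoothed with a zero-lag second-order 20 Hz
Butterworth filter (heel-strike impact oscillations would otherwise
re-cross the threshold); starting 100 ms after each heel-strike, toe-off is
the first sample below 10 N.

Strides pair consecutive same-limb heel-strikes with the unique toe-off
between them and are the normalisation unit for all timing metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import InvalidParameterError
from .signals import TimeSeries, lowpass_zero_lag

__all__ = [
    "EventKind",
    "GaitEvent",
    "Stride",
    "GrfEventParams",
    "detect_heelstrikes",
    "detect_toeoffs",
    "detect_events",
    "build_strides",
]

log = logging.getLogger(__name__)


class EventKind(str, Enum):
    HEEL_STRIKE = "heel_strike"
    TOE_OFF = "toe_off"


@dataclass(frozen=True, order=True)
class GaitEvent:
    time: float
    kind: EventKind
    limb: str = ""
    source: str = "reference"


@dataclass(frozen=True)
class Stride:
    """One gait cycle [hs_time, next_hs_time) of a limb with its toe-off."""

    limb: str
    hs_time: float
    to_time: float
    next_hs_time: float

    def __post_init__(self) -> None:
        if not (self.hs_time < self.to_time < self.next_hs_time):
            raise InvalidParameterError(
                f"stride events out of order: {self.hs_time}, {self.to_time}, {self.next_hs_time}"
            )

    @property
    def duration(self) -> float:
        return self.next_hs_time - self.hs_time

    def contains(self, t: float) -> bool:
        return self.hs_time <= t < self.next_hs_time


@dataclass(frozen=True)
class GrfEventParams:
    """Thresholds of the force-based reference detection (units: N, s)."""

    trigger_n: float = 400.0
    noise_floor_n: float = 10.0
    toeoff_blank_s: float = 0.100
    filter_order: int = 2
    filter_cutoff_hz: float = 20.0


def detect_heelstrikes(
    grf_v: TimeSeries, params: GrfEventParams = GrfEventParams(), limb: str = ""
) -> list[GaitEvent]:
    """Heel-strike reference events from the raw vertical GRF.

    One scan per contiguous supra-trigger run, starting at the run's first
    sample.  Scans that reach the start of the record without a match are
    skipped with a warning; multiple scans resolving to the same sample
    collapse to one event.
    """
    f = grf_v.values
    above = f > params.trigger_n
    onsets = np.nonzero(above & ~np.concatenate(([True], above[:-1])))[0]
    if above.size and above[0]:
        # a record starting above the trigger has no observable onset
        log.warning("GRF record starts above the %g N trigger; first contact skipped", params.trigger_n)
    times = grf_v.times()
    found: list[int] = []
    for onset in onsets:
        hit = -1
        for i in range(onset - 1, -1, -1):
            if f[i] <= 0.0:
                hit = i
                break
            if f[i] > f[i + 1] and f[i] < params.noise_floor_n:
                hit = i
                break
        if hit < 0:
            log.warning("backward scan from t=%.3f s reached record start; event skipped", times[onset])
            continue
        if not found or found[-1] != hit:
            found.append(hit)
    return [
        GaitEvent(time=float(times[i]), kind=EventKind.HEEL_STRIKE, limb=limb, source="reference")
        for i in found
    ]


def detect_toeoffs(
    grf_v: TimeSeries,
    heelstrikes: list[GaitEvent],
    params: GrfEventParams = GrfEventParams(),
) -> list[GaitEvent]:
    """Toe-off reference events on the low-pass filtered vertical GRF.

    For each heel-strike, the first sample at or after HS + 100 ms whose
    filtered force drops below 10 N, restricted to before the next
    heel-strike; strides with no such sample are flagged incomplete and
    produce no toe-off.
    """
    if not heelstrikes:
        return []
    hs_sorted = sorted(heelstrikes)
    filt = lowpass_zero_lag(grf_v, params.filter_order, params.filter_cutoff_hz)
    f = filt.values
    times = filt.times()
    out: list[GaitEvent] = []
    for i, hs in enumerate(hs_sorted):
        t_start = hs.time + params.toeoff_blank_s
        t_stop = hs_sorted[i + 1].time if i + 1 < len(hs_sorted) else np.inf
        j0 = int(np.ceil((t_start - filt.t0) * filt.rate - 1e-9))
        if j0 >= f.size:
            log.info("stride starting at %.3f s incomplete: record ends in stance", hs.time)
            continue
        below = np.nonzero(f[j0:] < params.noise_floor_n)[0]
        if below.size == 0 or times[j0 + below[0]] >= t_stop:
            log.info("stride starting at %.3f s incomplete: no toe-off before next heel-strike", hs.time)
            continue
        j = j0 + int(below[0])
        out.append(GaitEvent(time=float(times[j]), kind=EventKind.TOE_OFF, limb=hs.limb, source="reference"))
    return out


def detect_events(
    grf_v: TimeSeries, params: GrfEventParams = GrfEventParams(), limb: str = ""
) -> list[GaitEvent]:
    """Heel-strikes and toe-offs of one belt, merged in time order."""
    hs = detect_heelstrikes(grf_v, params, limb=limb)
    to = detect_toeoffs(grf_v, hs, params)
    return sorted(hs + to)


def build_strides(
    heelstrikes: list[GaitEvent], toeoffs: list[GaitEvent]
) -> list[Stride]:
    """Pair consecutive same-limb heel-strikes with the toe-off in between.

    Heel-strike pairs without a unique interior toe-off are dropped (with a
    logged count); toe-offs outside any pair are ignored.
    """
    strides: list[Stride] = []
    dropped = 0
    limbs = sorted({e.limb for e in heelstrikes})
    for limb in limbs:
        hs = sorted(e.time for e in heelstrikes if e.limb == limb)
        to = sorted(e.time for e in toeoffs if e.limb == limb)
        for a, b in zip(hs[:-1], hs[1:]):
            interior = [t for t in to if a < t < b]
            if len(interior) != 1:
                dropped += 1
                continue
            strides.append(Stride(limb=limb, hs_time=a, to_time=interior[0], next_hs_time=b))
    if dropped:
        log.info("dropped %d heel-strike pairs without a unique toe-off", dropped)
    return sorted(strides, key=lambda s: (s.limb, s.hs_time))
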