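"""Causal stance/swing event detection from segment angular velocity.

A sign change of the sagittal angular velocity of a lower-limb segment is
the candidate event: negative-to-positive marks a heel-strike (the limb
starts rotating backward over the planted foot), positive-to-negative a
toe-off.  Raw IMU-derived velocities produce extra crossings — impact
ringing after heel-strike, a near-zero dip of the shank in mid-stance,
thigh/shank counter-rotation around toe-off — so each candidate is gated by
up to four rules, evaluated in a fixed order:

1. **Event timer** — reject any candidate within a per-segment blocking
   time of the limb's last accepted event (150 ms shank, 200 ms leg,
   250 ms extended leg).
2. **Heel-strike rule** — reject a candidate of the same kind as the limb's
   last accepted event, so heel-strike and toe-off must alternate.
3. **Opposite-leg rule** (toe-off only) — require a heel-strike of the
   opposite limb newer than this limb's own last heel-strike and not later
   than the candidate: walking always passes through double support.
4. **Segment-angle rule** (toe-off only) — the reference angle is latched
   each time the angular velocity rises above -50 deg/s (late swing);
   toe-off is allowed only after the segment angle has advanced at least
   15 deg in the stance direction since the latch.  This blocks toe-off
   detections from small oscillations while standing.

The machine starts in standing with heel-strike as the initial condition:
both limbs are treated as having struck the ground at stream start, so the
first accepted event of a limb is a toe-off.  A limb's own initial virtual
heel-strike counts as double support for the *opposite* limb's first
toe-off but never against newer real strikes.  Simultaneous left/right
candidates are processed left first.

Processing is strictly causal: every decision uses only samples and
accepted events up to the candidate's own sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidParameterError
from .grf_events import EventKind, GaitEvent
from .signals import Direction, SignChange, TimeSeries, find_sign_changes, lowpass_causal

__all__ = [
    "RuleConfig",
    "DetectionResult",
    "default_config",
    "detect_bilateral",
]

log = logging.getLogger(__name__)

#: Per-segment blocking times (ms); one value per segment, kept as small as
#: safety allows so a stumble heel-strike can be picked up quickly.
EVENT_TIMER_MS = {"shank": 150.0, "leg": 200.0, "extended_leg": 250.0}


@dataclass(frozen=True)
class RuleConfig:
    """Detector parameters for one segment.

    ``unsupported`` marks segments (the thigh) whose velocity profile has
    too many crossings for any of the rule sets; the config is constructible
    for experimentation but flagged.
    """

    segment: str = "shank"
    event_timer_ms: float = 150.0
    use_heelstrike_rule: bool = True
    use_opposite_leg_rule: bool = True
    use_segment_angle_rule: bool = False
    angle_delta_deg: float = 15.0
    arming_velocity_dps: float = -50.0
    prefilter_cutoff_hz: float | None = None
    prefilter_order: int = 2
    unsupported: bool = False

    def __post_init__(self) -> None:
        if self.event_timer_ms < 0:
            raise InvalidParameterError("event_timer_ms must be >= 0")
        if self.angle_delta_deg <= 0:
            raise InvalidParameterError("angle_delta_deg must be > 0")


def default_config(segment: str) -> RuleConfig:
    """The hand-tuned rule set of a segment.

    shank: 150 ms timer, heel-strike and opposite-leg rules;
    leg: 200 ms timer, heel-strike and opposite-leg rules;
    extended_leg: 250 ms timer, heel-strike rule only (its toe-off can
    precede the opposite heel-strike, so the opposite-leg rule would starve
    it); thigh: no usable rule set — returned with all rules off and the
    ``unsupported`` flag raised.
    """
    if segment == "thigh":
        log.warning("the thigh segment has no reliable rule set; config flagged unsupported")
        return RuleConfig(
            segment="thigh",
            event_timer_ms=0.0,
            use_heelstrike_rule=False,
            use_opposite_leg_rule=False,
            unsupported=True,
        )
    if segment not in EVENT_TIMER_MS:
        raise InvalidParameterError(f"unknown segment {segment!r}")
    return RuleConfig(
        segment=segment,
        event_timer_ms=EVENT_TIMER_MS[segment],
        use_heelstrike_rule=True,
        use_opposite_leg_rule=(segment != "extended_leg"),
    )


@dataclass
class DetectionResult:
    """Accepted events plus every rejected candidate with the rule that
    rejected it (audit trail of the rule layer)."""

    limb: str
    events: list[GaitEvent] = field(default_factory=list)
    rejected: list[tuple[SignChange, str]] = field(default_factory=list)
    config: RuleConfig = field(default_factory=RuleConfig)


class _LimbState:
    """Mutable per-limb detector state (standing start, heel-strike set)."""

    def __init__(self, t_start: float) -> None:
        self.last_kind: EventKind = EventKind.HEEL_STRIKE
        self.last_time: float = -np.inf  # virtual event: never blocks the timer
        # own_hs is what this limb compares against in the opposite-leg rule;
        # hs_broadcast is what the *other* limb reads.  The initial virtual
        # heel-strike is broadcast (standing = double support) but does not
        # count as this limb's own real strike.
        self.own_hs: float = -np.inf
        self.hs_broadcast: float = t_start

    def accept(self, event: GaitEvent) -> None:
        self.last_kind = event.kind
        self.last_time = event.time
        if event.kind is EventKind.HEEL_STRIKE:
            self.own_hs = event.time
            self.hs_broadcast = event.time


def _latch_table(
    omega: TimeSeries, angle: TimeSeries | None, arming_velocity: float
) -> tuple[np.ndarray, np.ndarray]:
    """Times and reference angles latched at each upward crossing of the
    arming velocity (re-latched on every crossing)."""
    w = omega.values
    up = np.nonzero((w[:-1] <= arming_velocity) & (w[1:] > arming_velocity))[0] + 1
    t = omega.times()[up]
    ref = np.interp(t, angle.times(), angle.values)
    return t, ref


def _candidate_kind(c: SignChange) -> EventKind:
    return EventKind.HEEL_STRIKE if c.direction is Direction.NEG_TO_POS else EventKind.TOE_OFF


def detect_bilateral(
    omega_left: TimeSeries,
    omega_right: TimeSeries,
    angle_left: TimeSeries | None = None,
    angle_right: TimeSeries | None = None,
    config: RuleConfig = RuleConfig(),
) -> tuple[DetectionResult, DetectionResult]:
    """Run the rule-gated detector on both limbs over a merged clock.

    ``omega_*`` are segment angular velocities (deg/s); ``angle_*`` are the
    matching segment angles (deg), required only when the segment-angle rule
    is enabled.  Returns one :class:`DetectionResult` per limb.
    """
    if not omega_left.same_clock(omega_right):
        raise ConfigurationError("left/right angular velocities must share a clock")
    if config.use_segment_angle_rule:
        if angle_left is None or angle_right is None:
            raise ConfigurationError("segment-angle rule enabled but angles missing")
        if not angle_left.same_clock(omega_left) or not angle_right.same_clock(omega_right):
            raise ConfigurationError("angle series must share the velocity clock")

    omegas = {"left": omega_left, "right": omega_right}
    angles = {"left": angle_left, "right": angle_right}
    if config.prefilter_cutoff_hz is not None:
        omegas = {
            k: lowpass_causal(v, config.prefilter_order, config.prefilter_cutoff_hz)
            for k, v in omegas.items()
        }

    t_start = omega_left.t0
    states = {limb: _LimbState(t_start) for limb in ("left", "right")}
    results = {limb: DetectionResult(limb=limb, config=config) for limb in ("left", "right")}

    latches: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if config.use_segment_angle_rule:
        for limb in ("left", "right"):
            latches[limb] = _latch_table(omegas[limb], angles[limb], config.arming_velocity_dps)

    # merged candidate stream in detection order (the sample at which the
    # flip becomes observable), left before right within a sample
    merged: list[tuple[float, int, str, SignChange]] = []
    for rank, limb in enumerate(("left", "right")):
        for c in find_sign_changes(omegas[limb]):
            merged.append((c.time, rank, limb, c))
    merged.sort(key=lambda item: (item[3].index, item[1]))

    timer_s = config.event_timer_ms / 1000.0
    for tc, _, limb, cand in merged:
        own = states[limb]
        opp = states["right" if limb == "left" else "left"]
        kind = _candidate_kind(cand)
        rejecting: str | None = None

        if tc - own.last_time < timer_s:
            rejecting = "event_timer"
        elif config.use_heelstrike_rule and kind is own.last_kind:
            rejecting = "heelstrike_rule"
        elif (
            config.use_opposite_leg_rule
            and kind is EventKind.TOE_OFF
            and not (own.own_hs < opp.hs_broadcast <= tc)
        ):
            rejecting = "opposite_leg_rule"
        elif config.use_segment_angle_rule and kind is EventKind.TOE_OFF:
            lt, lref = latches[limb]
            k = int(np.searchsorted(lt, tc, side="right")) - 1
            if k < 0:
                rejecting = "segment_angle_rule"
            else:
                a_now = float(
                    np.interp(tc, angles[limb].times(), angles[limb].values)
                )
                if a_now - lref[k] < config.angle_delta_deg:
                    rejecting = "segment_angle_rule"

        if rejecting is None:
            event = GaitEvent(time=tc, kind=kind, limb=limb, source="detector")
            own.accept(event)
            results[limb].events.append(event)
        else:
            results[limb].rejected.append((cand, rejecting))

    return results["left"], results["right"]
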