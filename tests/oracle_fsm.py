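"""Independent brute-force reference for the rule-gated detector.

A literal sample-by-sample finite-state machine, written separately from the
package's candidate-stream implementation: it walks both limbs over the
merged sample clock, tracks effective signs (zeros inherit the previous
nonzero sign), keeps its own latch history for the segment-angle rule, and
applies the four rules in the documented order.  Used to cross-check
`gaitseg.detector.detect_bilateral` event for event.
"""

from __future__ import annotations

import math

import numpy as np

from gaitseg.detector import RuleConfig
from gaitseg.signals import TimeSeries, lowpass_causal

LIMBS = ("left", "right")


class _Limb:
    def __init__(self, omega: TimeSeries, angle: TimeSeries | None, t_start: float) -> None:
        self.w = omega.values
        self.t = omega.times()
        self.angle = angle
        self.prev_sign = 0
        self.zero_run_start: int | None = None
        self.last_kind = "heel_strike"
        self.last_time = -math.inf
        self.own_hs = -math.inf
        self.hs_readable = t_start  # virtual strike at stream start
        self.latches: list[tuple[float, float]] = []
        self.accepted: list[tuple[float, str]] = []
        self.rejected: list[tuple[float, str, str]] = []

    def angle_at(self, tc: float) -> float:
        return float(np.interp(tc, self.angle.times(), self.angle.values))


def oracle_detect(
    omega_left: TimeSeries,
    omega_right: TimeSeries,
    angle_left: TimeSeries | None,
    angle_right: TimeSeries | None,
    cfg: RuleConfig,
) -> dict[str, dict[str, list]]:
    if cfg.prefilter_cutoff_hz is not None:
        omega_left = lowpass_causal(omega_left, cfg.prefilter_order, cfg.prefilter_cutoff_hz)
        omega_right = lowpass_causal(omega_right, cfg.prefilter_order, cfg.prefilter_cutoff_hz)
    t_start = omega_left.t0
    limbs = {
        "left": _Limb(omega_left, angle_left, t_start),
        "right": _Limb(omega_right, angle_right, t_start),
    }
    n = len(omega_left)
    timer = cfg.event_timer_ms / 1000.0

    # initialise sign trackers from sample 0
    for st in limbs.values():
        s0 = int(np.sign(st.w[0]))
        st.prev_sign = s0
        st.zero_run_start = 0 if s0 == 0 else None

    for i in range(1, n):
        for limb in LIMBS:
            st = limbs[limb]
            opp = limbs["right" if limb == "left" else "left"]
            w_i = st.w[i]
            s_i = int(np.sign(w_i))

            # segment-angle latch: velocity rising above the arming threshold
            # between i-1 and i latches the angle at sample i (never applies
            # to a candidate found at this same sample: its time is earlier)
            latch_now = (
                cfg.use_segment_angle_rule
                and st.w[i - 1] <= cfg.arming_velocity_dps < w_i
            )

            if s_i == 0:
                if st.zero_run_start is None:
                    st.zero_run_start = i
            else:
                flipped = st.prev_sign != 0 and s_i != st.prev_sign
                if flipped:
                    if st.w[i - 1] == 0.0 and st.zero_run_start is not None:
                        tc = st.t[st.zero_run_start]
                    else:
                        frac = st.w[i - 1] / (st.w[i - 1] - w_i)
                        tc = st.t[i - 1] + frac * (st.t[1] - st.t[0])
                    kind = "heel_strike" if s_i > 0 else "toe_off"
                    verdict = _apply_rules(cfg, st, opp, tc, kind, timer)
                    if verdict is None:
                        st.accepted.append((tc, kind))
                        st.last_kind = kind
                        st.last_time = tc
                        if kind == "heel_strike":
                            st.own_hs = tc
                            st.hs_readable = tc
                    else:
                        st.rejected.append((tc, kind, verdict))
                st.prev_sign = s_i
                st.zero_run_start = None

            if latch_now:
                st.latches.append((st.t[i], st.angle_at(st.t[i])))

    return {
        limb: {"accepted": st.accepted, "rejected": st.rejected}
        for limb, st in limbs.items()
    }


def _apply_rules(cfg: RuleConfig, st: _Limb, opp: _Limb, tc: float, kind: str, timer: float) -> str | None:
    if tc - st.last_time < timer:
        return "event_timer"
    if cfg.use_heelstrike_rule and kind == st.last_kind:
        return "heelstrike_rule"
    if cfg.use_opposite_leg_rule and kind == "toe_off":
        if not (st.own_hs < opp.hs_readable <= tc):
            return "opposite_leg_rule"
    if cfg.use_segment_angle_rule and kind == "toe_off":
        usable = [(lt, ref) for lt, ref in st.latches if lt <= tc]
        if not usable:
            return "segment_angle_rule"
        _, ref = usable[-1]
        if st.angle_at(tc) - ref < cfg.angle_delta_deg:
            return "segment_angle_rule"
    return None
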