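"""Rule-gated event detector: rule semantics, oracle equality, causality."""

import numpy as np
import pytest

from gaitseg.detector import RuleConfig, default_config, detect_bilateral
from gaitseg.errors import ConfigurationError, InvalidParameterError
from gaitseg.grf_events import EventKind
from gaitseg.signals import TimeSeries, find_sign_changes

from conftest import series
from oracle_fsm import oracle_detect

RATE = 133.0

NO_RULES = RuleConfig(
    event_timer_ms=0.0,
    use_heelstrike_rule=False,
    use_opposite_leg_rule=False,
    use_segment_angle_rule=False,
)


def bilateral_gait_omega(n_strides=10, stride=1.1, rate=RATE, pos_frac=0.6, amp=100.0):
    """Clean square-wave-like bilateral angular velocity (smoothed edges)."""
    t = np.arange(int(n_strides * stride * rate)) / rate
    def omega(phase_off):
        ph = (t / stride + phase_off) % 1.0
        return amp * np.where(ph < pos_frac, 1.0, -1.5) * (
            0.6 + 0.4 * np.sin(2 * np.pi * ph)**2
        )
    left = series(omega(0.0), rate=rate, units="deg/s")
    right = series(omega(0.5), rate=rate, units="deg/s")
    return left, right


def integrate(omega: TimeSeries) -> TimeSeries:
    vals = np.concatenate(([0.0], np.cumsum(omega.values[1:]) * omega.dt))
    return omega.with_values(vals, units="deg")


class TestDefaultConfig:
    @pytest.mark.parametrize(
        "segment,timer,opp",
        [("shank", 150.0, True), ("leg", 200.0, True), ("extended_leg", 250.0, False)],
    )
    def test_per_segment_rules(self, segment, timer, opp):
        cfg = default_config(segment)
        assert cfg.event_timer_ms == timer
        assert cfg.use_heelstrike_rule
        assert cfg.use_opposite_leg_rule is opp
        assert not cfg.unsupported

    def test_thigh_flagged_unsupported(self):
        cfg = default_config("thigh")
        assert cfg.unsupported
        assert not cfg.use_heelstrike_rule

    def test_unknown_segment_rejected(self):
        with pytest.raises(InvalidParameterError):
            default_config("pelvis")


class TestRuleSemantics:
    def test_clean_gait_one_event_pair_per_stride(self):
        left, right = bilateral_gait_omega(n_strides=30)
        res_l, res_r = detect_bilateral(left, right, config=default_config("shank"))
        for res in (res_l, res_r):
            hs = [e for e in res.events if e.kind is EventKind.HEEL_STRIKE]
            to = [e for e in res.events if e.kind is EventKind.TOE_OFF]
            assert 29 <= len(hs) <= 30 and 29 <= len(to) <= 30
            kinds = [e.kind for e in res.events]
            assert all(a is not b for a, b in zip(kinds, kinds[1:]))

    def test_event_timer_rejects_post_event_blip(self):
        left, right = bilateral_gait_omega(n_strides=20)
        lv = left.values.copy()
        stride_n = int(1.1 * RATE)
        hs_idx = int(0.0 * RATE)  # neg->pos at phase 0 of each stride
        for k in range(1, 20):
            i = k * stride_n + int(0.05 * RATE)  # 50 ms after heel-strike
            lv[i : i + 3] = -40.0  # ~20 ms negative blip
        dirty = left.with_values(lv)
        cfg = default_config("shank")
        clean_res = detect_bilateral(left, right, config=cfg)[0]
        dirty_res = detect_bilateral(dirty, right, config=cfg)[0]
        assert len(dirty_res.events) == len(clean_res.events)
        assert any(rule == "event_timer" for _, rule in dirty_res.rejected)

    def test_standing_oscillation_produces_no_toeoff(self):
        # +/-20 deg/s sway never reaches the -50 deg/s arming threshold and
        # the angle excursion stays below 15 deg
        t = np.arange(int(60 * RATE)) / RATE
        w = 20.0 * np.sin(2 * np.pi * 0.8 * t)
        omega = series(w, rate=RATE, units="deg/s")
        angle = integrate(omega)
        cfg = RuleConfig(
            event_timer_ms=150.0,
            use_heelstrike_rule=True,
            use_opposite_leg_rule=False,
            use_segment_angle_rule=True,
        )
        res_l, res_r = detect_bilateral(omega, omega, angle, angle, cfg)
        for res in (res_l, res_r):
            assert not any(e.kind is EventKind.TOE_OFF for e in res.events)

    def test_segment_angle_rule_allows_walking_toeoff(self):
        left, right = bilateral_gait_omega(n_strides=10)
        al, ar = integrate(left), integrate(right)
        cfg = RuleConfig(
            event_timer_ms=150.0,
            use_heelstrike_rule=True,
            use_opposite_leg_rule=True,
            use_segment_angle_rule=True,
        )
        res_l, _ = detect_bilateral(left, right, al, ar, cfg)
        assert sum(e.kind is EventKind.TOE_OFF for e in res_l.events) >= 8

    def test_opposite_leg_rule_enforces_double_support(self):
        left, right = bilateral_gait_omega(n_strides=20)
        res_l, res_r = detect_bilateral(left, right, config=default_config("leg"))
        events = {"left": res_l.events, "right": res_r.events}
        for limb, opp in (("left", "right"), ("right", "left")):
            for to in (e for e in events[limb] if e.kind is EventKind.TOE_OFF):
                own_prior_hs = [
                    e.time
                    for e in events[limb]
                    if e.kind is EventKind.HEEL_STRIKE and e.time < to.time
                ]
                if not own_prior_hs:
                    continue  # bootstrap toe-off against the virtual strike
                assert any(
                    own_prior_hs[-1] < e.time <= to.time
                    for e in events[opp]
                    if e.kind is EventKind.HEEL_STRIKE
                )

    def test_angle_rule_without_angles_rejected(self):
        left, right = bilateral_gait_omega(n_strides=3)
        cfg = RuleConfig(use_segment_angle_rule=True)
        with pytest.raises(ConfigurationError):
            detect_bilateral(left, right, config=cfg)


class TestStructuralProperties:
    def test_no_rules_reproduces_raw_crossings(self):
        rng = np.random.default_rng(5)
        left = series(rng.normal(size=500), rate=RATE)
        right = series(rng.normal(size=500), rate=RATE)
        res_l, res_r = detect_bilateral(left, right, config=NO_RULES)
        for res, omega in ((res_l, left), (res_r, right)):
            raw = find_sign_changes(omega)
            assert [e.time for e in res.events] == [c.time for c in raw]
            assert res.rejected == []

    def test_determinism(self):
        left, right = bilateral_gait_omega(n_strides=8)
        a = detect_bilateral(left, right, config=default_config("leg"))
        b = detect_bilateral(left, right, config=default_config("leg"))
        assert [e.time for e in a[0].events] == [e.time for e in b[0].events]
        assert [r for _, r in a[1].rejected] == [r for _, r in b[1].rejected]

    def test_causality_under_truncation(self):
        left, right = bilateral_gait_omega(n_strides=12)
        cfg = default_config("shank")
        full_l, _ = detect_bilateral(left, right, config=cfg)
        n_half = len(left) // 2
        t_cut = left.t0 + (n_half - 1) * left.dt
        half = lambda s: s.with_values(s.values[:n_half])
        half_l, _ = detect_bilateral(half(left), half(right), config=cfg)
        expected = [e.time for e in full_l.events if e.time < t_cut - left.dt]
        got = [e.time for e in half_l.events if e.time < t_cut - left.dt]
        assert got == expected

    def test_prefilter_reduces_noise_crossings(self):
        rng = np.random.default_rng(9)
        left, right = bilateral_gait_omega(n_strides=10)
        noisy = lambda s: s.with_values(s.values + rng.normal(0, 30, len(s)))
        nl, nr = noisy(left), noisy(right)
        plain = detect_bilateral(nl, nr, config=NO_RULES)
        filt = detect_bilateral(
            nl, nr, config=RuleConfig(
                event_timer_ms=0.0, use_heelstrike_rule=False,
                use_opposite_leg_rule=False, prefilter_cutoff_hz=4.0,
            )
        )
        assert len(filt[0].events) < len(plain[0].events)


class TestAgainstOracle:
    @pytest.mark.parametrize("segment", ["shank", "leg", "extended_leg"])
    def test_matches_bruteforce_fsm_on_noisy_gait(self, segment):
        rng = np.random.default_rng(hash(segment) % 2**31)
        left, right = bilateral_gait_omega(n_strides=12)
        nl = left.with_values(left.values + rng.normal(0, 15, len(left)))
        nr = right.with_values(right.values + rng.normal(0, 15, len(right)))
        al, ar = integrate(nl), integrate(nr)
        cfg = default_config(segment)
        cfg = RuleConfig(**{**cfg.__dict__, "use_segment_angle_rule": True})
        res_l, res_r = detect_bilateral(nl, nr, al, ar, cfg)
        ref = oracle_detect(nl, nr, al, ar, cfg)
        for limb, res in (("left", res_l), ("right", res_r)):
            assert [(e.time, e.kind.value) for e in res.events] == ref[limb]["accepted"]
            assert [(c.time, r) for c, r in res.rejected] == [
                (t, r) for t, _, r in ref[limb]["rejected"]
            ]
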