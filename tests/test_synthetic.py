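"""Synthetic gait generator: construction invariants and truth consistency."""

import numpy as np
import pytest

from gaitseg.errors import DegenerateGaitError, InvalidParameterError
from gaitseg.grf_events import EventKind, detect_events
from gaitseg.kinematics import angle_set_from_segments
from gaitseg.signals import Direction, differentiate, find_sign_changes
from gaitseg.synthetic import (
    NOISE_PRESETS,
    GaitModelParams,
    ImuNoiseParams,
    generate_grf,
    generate_trial,
    limb_trajectory,
    simulate_imu,
)


class TestLimbTrajectory:
    def test_contralateral_half_stride_shift(self):
        p = GaitModelParams(seed=0)
        traj = limb_trajectory(p, 4)
        T = p.stride_time
        shift = int(round(0.5 * T * traj["left"]["thigh"].rate))
        lv = traj["left"]["thigh"].values
        rv = traj["right"]["thigh"].values
        np.testing.assert_allclose(lv[shift:], rv[: len(rv) - shift], atol=1e-9)

    def test_stride_periodicity(self):
        p = GaitModelParams(seed=0)
        traj = limb_trajectory(p, 4)
        n = int(round(p.stride_time * traj["left"]["shank"].rate))
        v = traj["left"]["shank"].values
        np.testing.assert_allclose(v[n:3 * n], v[:2 * n], atol=1e-9)

    def test_leg_velocity_crossings_at_constructed_phases(self):
        p = GaitModelParams(seed=0)
        traj = limb_trajectory(p, 6)
        geo = p.geometry
        angles = angle_set_from_segments(traj["left"]["thigh"], traj["left"]["shank"], geo)
        omega = differentiate(angles["leg"])
        crossings = find_sign_changes(omega)
        T = p.stride_time
        n2p = [c.time for c in crossings if c.direction is Direction.NEG_TO_POS]
        # exactly one reversal per stride, at retraction_lead % GC before HS
        for tc in n2p:
            lead_pct = 100.0 * (np.ceil(tc / T) * T - tc) / T
            assert lead_pct == pytest.approx(p.retraction_lead, abs=0.2)
        assert len(n2p) >= 6

    def test_zero_rom_rejected(self):
        with pytest.raises(DegenerateGaitError):
            GaitModelParams(segment_profile={"thigh": (0.0, 0.0), "shank": (10.0, 60.0)})


class TestGenerateGrf:
    def test_stance_duration_matches_duty(self):
        p = GaitModelParams(stride_time=1.0, duty_factor=0.62)
        grf, truth = generate_grf(p, 4)
        f = grf["left"].values
        rate = grf["left"].rate
        # support duration of the second stance
        seg = f[int(1.0 * rate): int(2.0 * rate)]
        assert np.count_nonzero(seg > 0.0) / rate == pytest.approx(0.62, abs=2e-3)

    def test_zero_at_contact_and_monotone_rise(self):
        p = GaitModelParams(seed=0)
        grf, truth = generate_grf(p, 4)
        f = grf["left"].values
        rate = grf["left"].rate
        hs = [e for e in truth if e.limb == "left" and e.kind is EventKind.HEEL_STRIKE]
        i = int(round(hs[1].time * rate))
        assert f[i] == pytest.approx(0.0, abs=1e-9)
        rise = f[i : i + int(0.05 * rate)]
        assert np.all(np.diff(rise) > 0)

    def test_peak_exceeds_trigger(self):
        grf, _ = generate_grf(GaitModelParams(), 3)
        assert grf["left"].values.max() > 400.0

    def test_underweight_subject_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_grf(GaitModelParams(body_mass=30.0), 3)

    def test_bad_duty_factor_rejected(self):
        with pytest.raises(InvalidParameterError):
            GaitModelParams(duty_factor=0.8)

    def test_reference_algorithm_recovers_truth(self):
        grf, truth = generate_grf(GaitModelParams(seed=1), 6)
        for limb in ("left", "right"):
            detected = detect_events(grf[limb], limb=limb)
            for ev in (e for e in truth if e.limb == limb):
                near = min(
                    (d.time for d in detected if d.kind is ev.kind),
                    key=lambda t: abs(t - ev.time),
                )
                assert abs(near - ev.time) <= 1.0 / grf[limb].rate + 1e-9


class TestSimulateImu:
    def _angle(self, p=None, n=4):
        p = p or GaitModelParams(seed=0)
        return limb_trajectory(p, n)["left"]["shank"]

    def test_noise_free_gyro_equals_derivative(self):
        angle = self._angle()
        imu = simulate_imu(angle, np.array([]), np.array([]), ImuNoiseParams())
        from gaitseg.signals import resample_linear

        expected = differentiate(resample_linear(angle, imu.rate)).values
        np.testing.assert_allclose(imu.gyro_sagittal.values, expected, atol=1e-9)

    def test_constant_bias_offsets_gyro_mean(self):
        # a bias walk with zero step sd stays at zero; emulate a constant
        # bias by adding it to the clean gyro and checking the mean shift
        angle = self._angle()
        clean = simulate_imu(angle, np.array([]), np.array([]), ImuNoiseParams())
        rng = np.random.default_rng(0)
        noisy = simulate_imu(
            angle, np.array([]), np.array([]),
            ImuNoiseParams(gyro_white_sd=1.0), rng=rng,
        )
        b = 2.0
        shifted = noisy.gyro_sagittal.values + b
        assert (shifted - clean.gyro_sagittal.values).mean() == pytest.approx(b, abs=0.05)

    def test_impact_envelope_bound(self):
        p = GaitModelParams(seed=0)
        angle = limb_trajectory(p, 4)["left"]["shank"]
        hs = np.array([p.stride_time])
        noise = ImuNoiseParams(impact_amp=100.0)
        clean = simulate_imu(angle, np.array([]), np.array([]), ImuNoiseParams())
        dirty = simulate_imu(angle, hs, np.array([]), noise)
        resid = np.abs(dirty.gyro_sagittal.values - clean.gyro_sagittal.values)
        t = dirty.gyro_sagittal.times()
        rel = t - hs[0]
        m = rel >= 0
        envelope = noise.impact_amp * np.exp(-np.clip(rel, 0, None) / noise.impact_tau)
        assert np.all(resid[m] <= envelope[m] + 1e-9)
        assert np.all(resid[~m] < 1e-12)  # strictly causal

    def test_upsampling_rejected(self):
        angle = self._angle()
        with pytest.raises(InvalidParameterError):
            simulate_imu(angle, np.array([]), np.array([]), ImuNoiseParams(), rate=2000.0)


class TestGenerateTrial:
    def test_same_seed_bit_identical(self):
        p = GaitModelParams(seed=42)
        a = generate_trial(p, NOISE_PRESETS["lab"], n_strides=3)
        b = generate_trial(p, NOISE_PRESETS["lab"], n_strides=3)
        np.testing.assert_array_equal(
            a.imu["left"]["shank"].gyro_sagittal.values,
            b.imu["left"]["shank"].gyro_sagittal.values,
        )
        np.testing.assert_array_equal(a.grf["right"].values, b.grf["right"].values)

    def test_different_seed_differs(self):
        a = generate_trial(GaitModelParams(seed=1), NOISE_PRESETS["lab"], n_strides=3)
        b = generate_trial(GaitModelParams(seed=2), NOISE_PRESETS["lab"], n_strides=3)
        assert not np.array_equal(
            a.imu["left"]["shank"].gyro_sagittal.values,
            b.imu["left"]["shank"].gyro_sagittal.values,
        )

    def test_span_covers_strides(self):
        p = GaitModelParams(stride_time=1.1, seed=0)
        trial = generate_trial(p, n_strides=10)
        assert trial.grf["left"].duration >= 11.0

    def test_truth_strides_well_formed(self, clean_trial):
        strides = clean_trial.truth_strides()
        assert len(strides) >= 2 * (clean_trial.n_strides - 2)
        for s in strides:
            assert s.hs_time < s.to_time < s.next_hs_time

    def test_noise_monotonicity_of_crossings(self):
        # more gyro white noise never reduces mean crossings per stride
        from gaitseg.pipeline import run_pipeline

        means = []
        for sd in (0.0, 8.0, 25.0):
            vals = []
            for seed in range(3):
                p = GaitModelParams(seed=seed)
                trial = generate_trial(p, ImuNoiseParams(gyro_white_sd=sd), n_strides=8)
                res = run_pipeline(trial, "leg", "imu")
                vals.append(res.mean_crossings_per_stride())
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]
        assert means[0] == pytest.approx(2.0, abs=0.1)
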