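"""Synthetic bilateral gait trials with ground-truth events.

The generator emulates the statistical structure the detector assumes in
treadmill walking: periodic thigh/shank angle trajectories across speeds
0.5-2.1 m/s and slopes of +/-10 deg, a two-belt vertical ground reaction
force with double support, IMU noise (white noise, bias random walk,
heel-strike impact ringing), and swing-leg retraction — the kinematic
reversal of the limb slightly *before* ground contact.

Trajectory model
----------------
All segment angles of a limb follow one shared periodic stride-phase shape
``g(phi)`` whose derivative is a piecewise half-sine: positive from the
kinematic reversal (at phase ``-retraction_lead`` relative to heel-strike)
up to the kinematic toe-off (at the stance/stride duty fraction), negative
through swing, with exactly two transversal zeros per stride.  Each segment
gets its own offset and range of motion.  Because the virtual leg and the
extended leg are monotone compositions of thigh and shank, *every* segment
— biological or virtual — then has exactly one neg-to-pos and one
pos-to-neg angular-velocity crossing per stride at the constructed phases.
This is a stylised idealisation: real thigh and shank profiles differ in
shape (the real thigh reverses well before the shank and shows extra
crossings), so passing tests certify the pipeline, not human biomechanics.

Ground truth
------------
Heel-strike truth is the analytic contact onset.  Toe-off truth is the
10 N downward crossing of the 20 Hz zero-lag-filtered noise-free force —
the force-based reference definition applied to the clean trace — because
the filtered-force crossing, not the analytic contact end, is what a force
reference can ever report.  Kinematic truth (the constructed reversal
times) is stored separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateGaitError, InvalidParameterError
from .grf_events import EventKind, GaitEvent, GrfEventParams, Stride, build_strides
from .imu_fusion import DEFAULT_IMU_RATE, ImuChannels
from .kinematics import (
    SegmentAngleSet,
    SegmentGeometry,
    _unit_vec,
    angle_set_from_segments,
    segment_lengths_from_height,
)
from .signals import TimeSeries, differentiate, lowpass_zero_lag, resample_linear

__all__ = [
    "GaitModelParams",
    "ImuNoiseParams",
    "SyntheticTrial",
    "NOISE_PRESETS",
    "STANDARD_CONDITIONS",
    "limb_trajectory",
    "generate_grf",
    "simulate_imu",
    "generate_trial",
]

G0 = 9.81  # m/s^2

GRF_RATE = 1000.0  # Hz, instrumented treadmill
MOCAP_RATE = 200.0  # Hz, marker cameras

#: Study-like speed/slope grid: five level speeds plus the steepest
#: incline/decline at the middle speed.
STANDARD_CONDITIONS: tuple[tuple[float, float], ...] = (
    (0.5, 0.0),
    (0.9, 0.0),
    (1.3, 0.0),
    (1.7, 0.0),
    (2.1, 0.0),
    (1.3, +10.0),
    (1.3, -10.0),
)

#: Per-segment (offset deg, range-of-motion deg) at the 1.3 m/s reference
#: speed.  Offsets follow the positive-posterior convention: a segment is at
#: its most anterior (minimum angle) at the kinematic reversal just before
#: heel-strike and at its most posterior (maximum) around toe-off.
DEFAULT_SEGMENT_PROFILE: dict[str, tuple[float, float]] = {
    "thigh": (-5.0, 40.0),
    "shank": (20.0, 65.0),
}

_REF_SPEED = 1.3  # m/s


def _stride_time_for_speed(speed: float) -> float:
    """Stride time shrinks with speed (~1.55 s at 0.5 m/s, ~0.86 s at 2.1)."""
    return 1.05 * (_REF_SPEED / speed) ** 0.42


def _duty_for_speed(speed: float) -> float:
    """Duty factor (stance fraction) decreases mildly with speed."""
    return float(np.clip(0.62 - 0.055 * np.log(speed / _REF_SPEED), 0.52, 0.73))


@dataclass(frozen=True)
class GaitModelParams:
    """Parameters of the stylised gait model.

    ``retraction_lead`` is the kinematic reversal lead before force-based
    heel-strike, in % of the gait cycle; 4% sits in the middle of the
    swing-leg-retraction band typically observed in unimpaired walking.
    ``stride_time`` / ``duty_factor`` default to speed-derived values.
    """

    speed: float = 1.3
    slope: float = 0.0
    stride_time: float | None = None
    duty_factor: float | None = None
    height: float = 1.78
    body_mass: float = 69.5
    retraction_lead: float = 4.0
    segment_profile: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_PROFILE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise InvalidParameterError("speed must be > 0")
        if self.stride_time is None:
            object.__setattr__(self, "stride_time", _stride_time_for_speed(self.speed))
        if self.duty_factor is None:
            object.__setattr__(self, "duty_factor", _duty_for_speed(self.speed))
        if self.stride_time <= 0:
            raise InvalidParameterError("stride_time must be > 0")
        if not 0.5 < self.duty_factor < 0.75:
            raise InvalidParameterError(
                f"duty_factor {self.duty_factor} outside the walking range (0.5, 0.75)"
            )
        if not 0.0 < self.retraction_lead < 100.0 * (1.0 - self.duty_factor):
            raise InvalidParameterError("retraction_lead must lie inside the swing phase")
        for seg, (_, rom) in self.segment_profile.items():
            if rom <= 0:
                raise DegenerateGaitError(f"{seg}: zero range of motion")

    @property
    def geometry(self) -> SegmentGeometry:
        return segment_lengths_from_height(self.height)


@dataclass(frozen=True)
class ImuNoiseParams:
    """IMU error model: white noise, bias random walk, impact ringing.

    The impact is a damped sinusoid ``amp * exp(-t/tau) * sin(2 pi f t)``
    added to the gyro after each own-limb heel-strike (half amplitude after
    opposite-limb strikes — the shock travels through the body).
    ``lever_arm_m`` is the IMU's distance from the proximal joint; it scales
    the motion (tangential + centripetal) terms that corrupt the
    accelerometer inclination during swing.
    """

    gyro_white_sd: float = 0.0  # deg/s per sample
    gyro_bias_walk_sd: float = 0.0  # deg/s per sqrt(s)
    accel_white_sd: float = 0.0  # g per sample
    impact_amp: float = 0.0  # deg/s
    impact_freq: float = 20.0  # Hz
    impact_tau: float = 0.05  # s
    lever_arm_m: float = 0.0  # m

    def __post_init__(self) -> None:
        for name in ("gyro_white_sd", "gyro_bias_walk_sd", "accel_white_sd", "impact_amp", "impact_tau", "lever_arm_m"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


NOISE_PRESETS: dict[str, ImuNoiseParams] = {
    "none": ImuNoiseParams(),
    "lab": ImuNoiseParams(
        gyro_white_sd=3.0,
        gyro_bias_walk_sd=0.05,
        accel_white_sd=0.03,
        impact_amp=80.0,
    ),
    "worst": ImuNoiseParams(
        gyro_white_sd=10.0,
        gyro_bias_walk_sd=0.15,
        accel_white_sd=0.08,
        impact_amp=160.0,
        lever_arm_m=0.20,
    ),
}

_LIMBS = ("left", "right")
_LIMB_PHASE = {"left": 0.0, "right": 0.5}


def _quintic_coeffs(f0: float, f1: float, a0: float, a1: float) -> np.ndarray:
    """Quintic on [0, 1] with end values f0, f1, zero end slopes, and end
    second derivatives a0, a1 (all six Hermite conditions)."""
    A = np.zeros((6, 6))
    A[0, 0] = 1.0  # f(0)
    A[1, :] = 1.0  # f(1)
    A[2, 1] = 1.0  # f'(0)
    A[3, :] = np.arange(6)  # f'(1)
    A[4, 2] = 2.0  # f''(0)
    A[5, :] = np.arange(6) * (np.arange(6) - 1)  # f''(1)
    return np.linalg.solve(A, np.array([f0, f1, 0.0, 0.0, a0, a1]))


def _shape(phase: np.ndarray, phi1: float, L1: float) -> np.ndarray:
    """Normalised stride-phase shape: 0 at the reversal (phi1), 1 at the
    kinematic toe-off, built from two quintic arcs whose junction
    curvatures match, so the derivative is C1-continuous with exactly two
    transversal zeros per cycle (verified over the walking parameter grid).
    """
    L2 = 1.0 - L1
    s = np.mod(phase - phi1, 1.0)
    # junction curvature shared by both arcs (geometric mean of the two
    # half-cosine arc curvatures), expressed in each arc's normalised x
    a_rise = 0.5 * np.pi**2 * (L1 / L2)
    a_fall = 0.5 * np.pi**2 * (L2 / L1)
    cr = _quintic_coeffs(0.0, 1.0, a_rise, -a_rise)
    cf = _quintic_coeffs(1.0, 0.0, -a_fall, a_fall)
    rising = s < L1
    xr = np.clip(s, 0.0, L1) / L1
    xf = (np.clip(s, L1, 1.0) - L1) / L2
    out = np.where(
        rising,
        np.polynomial.polynomial.polyval(xr, cr),
        np.polynomial.polynomial.polyval(xf, cf),
    )
    return out


def _segment_angles_at(
    params: GaitModelParams, t: np.ndarray, limb: str
) -> dict[str, np.ndarray]:
    """Analytic thigh and shank angle samples (deg) of one limb."""
    T = params.stride_time
    rho = params.retraction_lead / 100.0
    phi1 = 1.0 - rho  # reversal phase (kinematic heel-strike lead)
    L1 = params.duty_factor + rho  # rising (stance-direction) arc length
    phase = t / T + _LIMB_PHASE[limb]
    g = _shape(phase, phi1, L1)
    speed_scale = 0.65 + 0.35 * params.speed / _REF_SPEED
    out = {}
    for seg, (offset, rom) in params.segment_profile.items():
        offset_c = offset + 0.5 * params.slope  # slope tilts the mean posture
        out[seg] = offset_c + rom * speed_scale * (g - 0.5)
    return out


def limb_trajectory(
    params: GaitModelParams, n_strides: int, rate: float = GRF_RATE
) -> dict[str, dict[str, TimeSeries]]:
    """Noise-free thigh and shank angle series for both limbs.

    The contralateral limb is the same trajectory shifted by half a stride;
    every angle is periodic with the stride time.  Returns
    ``{limb: {segment: TimeSeries}}`` covering ``(n_strides + 1)`` strides
    so the last gait cycle of each limb closes.
    """
    if n_strides < 1:
        raise InvalidParameterError("n_strides must be >= 1")
    duration = (n_strides + 1) * params.stride_time
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    out: dict[str, dict[str, TimeSeries]] = {}
    for limb in _LIMBS:
        raw = _segment_angles_at(params, t, limb)
        out[limb] = {
            seg: TimeSeries(values=v, rate=rate, t0=0.0, label=f"{limb}_{seg}_angle", units="deg")
            for seg, v in raw.items()
        }
    return out


def _grf_hump(s: np.ndarray) -> np.ndarray:
    """Double-hump stance force shape on s in [0, 1], unit peak."""
    raw = np.sin(np.pi * s) + 0.42 * np.sin(3.0 * np.pi * s)
    return raw / _GRF_PEAK_FACTOR


_s_dense = np.linspace(0.0, 1.0, 4001)
_GRF_PEAK_FACTOR = float(np.max(np.sin(np.pi * _s_dense) + 0.42 * np.sin(3.0 * np.pi * _s_dense)))
del _s_dense

#: Peak vertical force as a multiple of body weight during walking.
GRF_PEAK_BW = 1.1


def _hs_times(params: GaitModelParams, n_strides: int, limb: str) -> np.ndarray:
    T = params.stride_time
    first = (1.0 - _LIMB_PHASE[limb]) % 1.0 * T if _LIMB_PHASE[limb] else 0.0
    times = first + T * np.arange(n_strides + 2)
    return times[times <= (n_strides + 1) * T + 1e-12]


def generate_grf(
    params: GaitModelParams, n_strides: int
) -> tuple[dict[str, TimeSeries], list[GaitEvent]]:
    """Per-belt vertical GRF plus ground-truth heel-strike/toe-off events.

    Each stance is a smooth double-hump from zero at contact onset to zero
    at contact end (duration = duty_factor * stride_time, peak about 1.1
    body weight); the belts are offset by half a stride.  The peak must
    exceed the 400 N reference trigger, i.e. body mass above about 37 kg.
    """
    if n_strides < 1:
        raise InvalidParameterError("n_strides must be >= 1")
    peak = GRF_PEAK_BW * params.body_mass * G0
    if peak <= GrfEventParams().trigger_n * 1.05:
        raise InvalidParameterError(
            f"peak force {peak:.0f} N too close to the {GrfEventParams().trigger_n:.0f} N trigger; "
            "increase body_mass or lower the trigger"
        )
    T = params.stride_time
    stance = params.duty_factor * T
    duration = (n_strides + 1) * T
    n = int(round(duration * GRF_RATE)) + 1
    t = np.arange(n) / GRF_RATE
    grf: dict[str, TimeSeries] = {}
    events: list[GaitEvent] = []
    for limb in _LIMBS:
        f = np.zeros(n)
        hs = _hs_times(params, n_strides, limb)
        for h in hs:
            i0 = int(np.ceil(h * GRF_RATE - 1e-9))
            i1 = min(n - 1, int(np.floor((h + stance) * GRF_RATE + 1e-9)))
            if i1 <= i0:
                continue
            s = (t[i0 : i1 + 1] - h) / stance
            f[i0 : i1 + 1] += peak * _grf_hump(np.clip(s, 0.0, 1.0))
        series = TimeSeries(values=f, rate=GRF_RATE, t0=0.0, label=f"grf_{limb}_N", units="N")
        grf[limb] = series
        # truth only for contacts whose force rise is actually in the record
        # (the trigger crossing sits in the first ~15% of stance)
        hs_obs = hs[hs + 0.3 * stance <= duration + 1e-9]
        events.extend(
            GaitEvent(time=float(h), kind=EventKind.HEEL_STRIKE, limb=limb, source="truth")
            for h in hs_obs
        )
        events.extend(_toeoff_truth(series, hs_obs, stance))
    return grf, sorted(events)


def _toeoff_truth(grf: TimeSeries, hs_times: np.ndarray, stance: float) -> list[GaitEvent]:
    """Toe-off truth: sub-sample 10 N downward crossing of the 20 Hz
    zero-lag-filtered clean force at the end of each stance."""
    p = GrfEventParams()
    filt = lowpass_zero_lag(grf, p.filter_order, p.filter_cutoff_hz)
    f = filt.values
    t = filt.times()
    out: list[GaitEvent] = []
    for h in hs_times:
        # search the last quarter of stance for the downward 10 N crossing
        j0 = int((h + 0.5 * stance) * grf.rate)
        j1 = min(f.size - 1, int((h + 1.25 * stance) * grf.rate))
        if j1 <= j0 + 1:
            continue
        seg = f[j0 : j1 + 1]
        below = np.nonzero((seg[:-1] >= p.noise_floor_n) & (seg[1:] < p.noise_floor_n))[0]
        if below.size == 0:
            continue
        k = j0 + int(below[0])
        frac = (f[k] - p.noise_floor_n) / (f[k] - f[k + 1])
        out.append(
            GaitEvent(
                time=float(t[k] + frac / grf.rate),
                kind=EventKind.TOE_OFF,
                limb=grf.label.split("_")[1] if "_" in grf.label else "",
                source="truth",
            )
        )
    return out


def simulate_imu(
    angle: TimeSeries,
    own_hs_times: np.ndarray,
    opp_hs_times: np.ndarray,
    noise: ImuNoiseParams = ImuNoiseParams(),
    rate: float = DEFAULT_IMU_RATE,
    rng: np.random.Generator | None = None,
) -> ImuChannels:
    """IMU channels consistent with a segment angle trajectory.

    The gyro is the numerical derivative of the angle resampled to the IMU
    rate, plus white noise, a bias random walk, and impact ringing after
    each heel-strike.  The accelerometer reads the gravity components of
    the angle plus lever-arm motion terms and white noise.  Requesting a
    rate above the source rate is rejected (the truth cannot be upsampled).
    """
    if rate > angle.rate:
        raise InvalidParameterError("IMU rate must not exceed the source angle rate")
    rng = np.random.default_rng(0) if rng is None else rng
    base = resample_linear(angle, rate)
    t = base.times()
    dt = base.dt
    gyro_clean = differentiate(base).values
    th = np.radians(base.values)

    gyro = gyro_clean.copy()
    if noise.gyro_white_sd > 0:
        gyro = gyro + rng.normal(0.0, noise.gyro_white_sd, t.size)
    if noise.gyro_bias_walk_sd > 0:
        gyro = gyro + np.cumsum(rng.normal(0.0, noise.gyro_bias_walk_sd * np.sqrt(dt), t.size))
    if noise.impact_amp > 0:
        for hs, amp in [(h, noise.impact_amp) for h in own_hs_times] + [
            (h, 0.5 * noise.impact_amp) for h in opp_hs_times
        ]:
            rel = t - hs
            m = (rel >= 0) & (rel < 6.0 * noise.impact_tau)
            gyro[m] += amp * np.exp(-rel[m] / noise.impact_tau) * np.sin(
                2.0 * np.pi * noise.impact_freq * rel[m]
            )

    omega_rad = np.radians(gyro_clean)
    alpha_rad = np.gradient(omega_rad, dt)
    axial = np.cos(th) + noise.lever_arm_m / G0 * omega_rad**2
    anterior = np.sin(th) + noise.lever_arm_m / G0 * alpha_rad
    if noise.accel_white_sd > 0:
        axial = axial + rng.normal(0.0, noise.accel_white_sd, t.size)
        anterior = anterior + rng.normal(0.0, noise.accel_white_sd, t.size)

    mk = lambda v, lbl, un: TimeSeries(values=v, rate=rate, t0=base.t0, label=lbl, units=un)
    return ImuChannels(
        gyro_sagittal=mk(gyro, f"{angle.label}_gyro", "deg/s"),
        accel_axial=mk(axial, f"{angle.label}_accel_axial", "g"),
        accel_anterior=mk(anterior, f"{angle.label}_accel_anterior", "g"),
    )


@dataclass
class SyntheticTrial:
    """A full simulated treadmill trial: angles, markers, IMU, GRF, truth."""

    params: GaitModelParams
    noise: ImuNoiseParams
    n_strides: int
    geometry: SegmentGeometry
    angles: dict[str, SegmentAngleSet]
    markers: dict[str, dict[str, TimeSeries]]
    imu: dict[str, dict[str, ImuChannels]]
    grf: dict[str, TimeSeries]
    truth_events: list[GaitEvent]
    kinematic_truth: list[GaitEvent]

    def truth_strides(self) -> list[Stride]:
        hs = [e for e in self.truth_events if e.kind is EventKind.HEEL_STRIKE]
        to = [e for e in self.truth_events if e.kind is EventKind.TOE_OFF]
        return build_strides(hs, to)

    def truth_hs_times(self, limb: str) -> np.ndarray:
        return np.array(
            [e.time for e in self.truth_events if e.limb == limb and e.kind is EventKind.HEEL_STRIKE]
        )


def _marker_tracks(
    params: GaitModelParams, n_strides: int
) -> dict[str, dict[str, TimeSeries]]:
    """Hip/knee/ankle sagittal marker tracks (m) at the camera rate.

    The hip stays fixed over the treadmill (belt-frame idealisation: no
    pelvis translation or bobbing); knee and ankle follow the segment
    vectors.
    """
    geo = params.geometry
    duration = (n_strides + 1) * params.stride_time
    n = int(round(duration * MOCAP_RATE)) + 1
    t = np.arange(n) / MOCAP_RATE
    hip_y0 = geo.thigh_len + geo.shank_len + 0.05
    out: dict[str, dict[str, TimeSeries]] = {}
    for limb in _LIMBS:
        ang = _segment_angles_at(params, t, limb)
        tx, ty = _unit_vec(ang["thigh"], geo.walking_dir)
        sx, sy = _unit_vec(ang["shank"], geo.walking_dir)
        hip_x = np.zeros(n)
        hip_y = np.full(n, hip_y0)
        knee_x = hip_x + geo.thigh_len * tx
        knee_y = hip_y + geo.thigh_len * ty
        ankle_x = knee_x + geo.shank_len * sx
        ankle_y = knee_y + geo.shank_len * sy
        mk = lambda v, lbl: TimeSeries(values=v, rate=MOCAP_RATE, t0=0.0, label=lbl, units="m")
        out[limb] = {
            "hip_x": mk(hip_x, f"{limb}_hip_x"),
            "hip_y": mk(hip_y, f"{limb}_hip_y"),
            "knee_x": mk(knee_x, f"{limb}_knee_x"),
            "knee_y": mk(knee_y, f"{limb}_knee_y"),
            "ankle_x": mk(ankle_x, f"{limb}_ankle_x"),
            "ankle_y": mk(ankle_y, f"{limb}_ankle_y"),
        }
    return out


def _kinematic_truth(params: GaitModelParams, n_strides: int) -> list[GaitEvent]:
    """Constructed reversal times: neg-to-pos at HS - retraction_lead,
    pos-to-neg at the kinematic toe-off phase."""
    T = params.stride_time
    rho = params.retraction_lead / 100.0
    duration = (n_strides + 1) * T
    out: list[GaitEvent] = []
    for limb in _LIMBS:
        for h in _hs_times(params, n_strides, limb):
            t_rev = h - rho * T
            t_kto = h + params.duty_factor * T
            if 0.0 <= t_rev <= duration:
                out.append(GaitEvent(time=t_rev, kind=EventKind.HEEL_STRIKE, limb=limb, source="kinematic_truth"))
            if 0.0 <= t_kto <= duration:
                out.append(GaitEvent(time=t_kto, kind=EventKind.TOE_OFF, limb=limb, source="kinematic_truth"))
    return sorted(out)


def generate_trial(
    params: GaitModelParams,
    noise: ImuNoiseParams = ImuNoiseParams(),
    n_strides: int = 30,
    imu_rate: float = DEFAULT_IMU_RATE,
) -> SyntheticTrial:
    """Compose trajectories, GRF, markers and IMU streams into one trial.

    Fully reproducible from ``params.seed``: the IMU noise streams are
    drawn from per-(limb, segment) child generators of that seed.
    """
    traj = limb_trajectory(params, n_strides)
    grf, truth = generate_grf(params, n_strides)
    markers = _marker_tracks(params, n_strides)
    geo = params.geometry

    angles = {
        limb: angle_set_from_segments(traj[limb]["thigh"], traj[limb]["shank"], geo, limb=limb)
        for limb in _LIMBS
    }

    hs = {
        limb: np.array(
            [e.time for e in truth if e.limb == limb and e.kind is EventKind.HEEL_STRIKE]
        )
        for limb in _LIMBS
    }
    children = np.random.SeedSequence(params.seed).spawn(4)
    imu: dict[str, dict[str, ImuChannels]] = {}
    k = 0
    for limb in _LIMBS:
        opp = "right" if limb == "left" else "left"
        imu[limb] = {}
        for seg in ("thigh", "shank"):
            rng = np.random.default_rng(children[k])
            k += 1
            imu[limb][seg] = simulate_imu(
                traj[limb][seg], hs[limb], hs[opp], noise, rate=imu_rate, rng=rng
            )

    return SyntheticTrial(
        params=params,
        noise=noise,
        n_strides=n_strides,
        geometry=geo,
        angles=angles,
        markers=markers,
        imu=imu,
        grf=grf,
        truth_events=truth,
        kinematic_truth=_kinematic_truth(params, n_strides),
    )
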