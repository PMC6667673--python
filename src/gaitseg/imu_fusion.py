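"""Gyro + accelerometer fusion into a segment angle (scalar Kalman filter).

The filter state is the single sagittal segment angle, in degrees.  Each
step integrates the gyro over one sample interval (prediction, variance
grows by ``q``) and corrects against the inclination computed from the two
accelerometer components (update, measurement variance ``r``).  The default
covariances, q = 5e-5 deg^2 per step and r = 7 deg^2, strongly trust the
gyro on short time scales while the accelerometer slowly pins the absolute
angle, which is the standard trade-off for walking where the accelerometer
reads gravity plus substantial motion artefact.

The filter state deliberately excludes a gyro-bias component: one process
and one measurement covariance describe the scalar-angle model completely,
and the slow accelerometer correction already bounds the effect of a
constant bias (a bias b settles to a constant offset of about
``b * dt * (1 - K) / K`` for steady-state gain K, not a drift).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, InsufficientDataError, InvalidParameterError
from .signals import TimeSeries

__all__ = [
    "ImuChannels",
    "KalmanParams",
    "accel_inclination",
    "kalman_fuse",
    "kalman_gain_history",
]

#: IMU sampling rate used throughout unless stated otherwise (Hz).
DEFAULT_IMU_RATE = 133.0

#: Acceleration magnitude (in g) below which the inclination is undefined
#: (near free fall); such samples hold the previous value.
FREEFALL_G = 0.05


@dataclass(frozen=True)
class ImuChannels:
    """One IMU's sagittal channels: gyro (deg/s) and two accelerometer
    components in g units — axial (along the segment, +1 g when hanging
    vertically at rest) and anterior (perpendicular, in the plane)."""

    gyro_sagittal: TimeSeries
    accel_axial: TimeSeries
    accel_anterior: TimeSeries

    def __post_init__(self) -> None:
        if not self.gyro_sagittal.same_clock(self.accel_axial) or not self.gyro_sagittal.same_clock(self.accel_anterior):
            raise AlignmentError("IMU channels must share a clock")

    @property
    def rate(self) -> float:
        return self.gyro_sagittal.rate


@dataclass(frozen=True)
class KalmanParams:
    """Scalar-state Kalman covariances (deg^2) and initial conditions.

    ``initial_angle=None`` self-starts from the first accelerometer
    inclination sample; ``initial_var=None`` defaults to ``r``, which makes
    the early updates behave like recursive averaging of the accelerometer
    (fast initial convergence, ~1/n error decay).
    """

    q: float = 5e-5
    r: float = 7.0
    initial_angle: float | None = None
    initial_var: float | None = None

    def __post_init__(self) -> None:
        if self.q <= 0 or self.r <= 0:
            raise InvalidParameterError("q and r must be > 0")


def accel_inclination(accel_axial: TimeSeries, accel_anterior: TimeSeries) -> TimeSeries:
    """Segment inclination (deg) from the gravity direction in the
    accelerometer frame: atan2(anterior, axial).

    Samples where both components are near zero (free fall) carry no
    attitude information and hold the previous valid value (a leading run of
    such samples holds the first valid one; an all-invalid signal is
    rejected).
    """
    if not accel_axial.same_clock(accel_anterior):
        raise AlignmentError("accelerometer channels must share a clock")
    ax = accel_axial.values
    an = accel_anterior.values
    ang = np.degrees(np.arctan2(an, ax))
    ok = np.hypot(ax, an) >= FREEFALL_G
    if not ok.any():
        raise InsufficientDataError("no valid accelerometer samples (free fall)")
    # forward-fill invalid samples with the last valid inclination
    idx = np.where(ok, np.arange(ok.size), -1)
    idx = np.maximum.accumulate(idx)
    first_valid = int(np.argmax(ok))
    idx = np.where(idx >= 0, idx, first_valid)
    return accel_axial.with_values(ang[idx], label="accel_inclination", units="deg")


def _gain_sequence(n: int, params: KalmanParams) -> np.ndarray:
    """Per-step Kalman gains.  The error covariance recursion does not
    depend on the data, so the gains can be precomputed for n steps."""
    p = params.r if params.initial_var is None else params.initial_var
    gains = np.empty(n)
    for k in range(n):
        p_pred = p + params.q
        gains[k] = p_pred / (p_pred + params.r)
        p = (1.0 - gains[k]) * p_pred
    return gains


def kalman_gain_history(n: int, params: KalmanParams) -> np.ndarray:
    """Expose the (data-independent) gain sequence, mainly for diagnostics."""
    return _gain_sequence(n, params)


def kalman_fuse(imu: ImuChannels, params: KalmanParams = KalmanParams()) -> TimeSeries:
    """Fuse gyro and accelerometer channels into a segment angle series.

    Sample 0 is the initial state (no update applied); from sample 1 on,
    each step predicts the angle with trapezoidal gyro integration
    (``angle += (gyro[k-1] + gyro[k]) / 2 * dt``; rectangle rules would
    shift every zero crossing by half a sample) and corrects toward the
    accelerometer inclination with the precomputed Kalman gain.
    """
    if len(imu.gyro_sagittal) < 2:
        raise InsufficientDataError("Kalman fusion needs >= 2 samples")
    z = accel_inclination(imu.accel_axial, imu.accel_anterior).values
    gyro = imu.gyro_sagittal.values
    dt = imu.gyro_sagittal.dt
    n = gyro.size
    gains = _gain_sequence(n - 1, params)
    theta = np.empty(n)
    theta[0] = z[0] if params.initial_angle is None else params.initial_angle
    x = theta[0]
    for k in range(1, n):
        x = x + 0.5 * (gyro[k - 1] + gyro[k]) * dt
        x = x + gains[k - 1] * (z[k] - x)
        theta[k] = x
    return imu.gyro_sagittal.with_values(theta, label="fused_angle", units="deg")
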