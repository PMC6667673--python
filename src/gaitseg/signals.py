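"""Uniformly sampled time series and the signal primitives used throughout.

Every stream in the pipeline — segment angles, angular velocities, vertical
ground reaction force, raw IMU channels — is carried as a :class:`TimeSeries`:
a 1-D array of samples with a start time and a strictly positive sampling
rate.  The module provides the four primitives the gait pipeline is built
from: zero-lag and causal Butterworth low-pass filtering, linear resampling,
numerical differentiation, and sub-sample zero-crossing localisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InsufficientDataError, InvalidParameterError, LoadError

__all__ = [
    "TimeSeries",
    "SignChange",
    "Direction",
    "lowpass_zero_lag",
    "lowpass_causal",
    "resample_linear",
    "differentiate",
    "find_sign_changes",
    "unwrap_degrees",
    "read_timeseries_csv",
    "write_timeseries_csv",
]


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled scalar signal.

    Sample ``i`` is taken at time ``t0 + i / rate``.  Instances are frozen;
    operations return new series.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise InvalidParameterError(f"rate must be > 0, got {self.rate}")
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).ravel()
        )
        if self.values.size == 0:
            raise InsufficientDataError("a TimeSeries needs at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise LoadError(f"non-finite samples in series {self.label!r}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        return (len(self) - 1) / self.rate

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate

    def with_values(self, values: np.ndarray, **meta) -> "TimeSeries":
        """New series on the same clock with different samples."""
        out = replace(self, values=np.asarray(values, dtype=float))
        return replace(out, **meta) if meta else out

    def slice_time(self, t_start: float, t_stop: float) -> "TimeSeries":
        """Sub-series covering [t_start, t_stop] (inclusive sample bounds)."""
        i0 = max(0, int(np.ceil((t_start - self.t0) * self.rate - 1e-9)))
        i1 = min(len(self) - 1, int(np.floor((t_stop - self.t0) * self.rate + 1e-9)))
        if i1 < i0:
            raise InsufficientDataError("empty time slice")
        return replace(self, values=self.values[i0 : i1 + 1], t0=self.t0 + i0 / self.rate)

    def same_clock(self, other: "TimeSeries", tol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and abs(self.rate - other.rate) <= tol * max(1.0, self.rate)
            and abs(self.t0 - other.t0) <= tol
        )


class Direction(str, Enum):
    NEG_TO_POS = "neg_to_pos"
    POS_TO_NEG = "pos_to_neg"


@dataclass(frozen=True)
class SignChange:
    """A zero crossing of a signal, localised between two samples.

    ``time`` is sub-sample (linear interpolation between the bracketing
    samples).  ``index`` is the index of the first sample on the new side.
    """

    time: float
    direction: Direction
    index: int


def _require_min_samples(x: TimeSeries, n: int, what: str) -> None:
    if len(x) < n:
        raise InsufficientDataError(
            f"{what} needs >= {n} samples, series {x.label!r} has {len(x)}"
        )


def _butter(order: int, cutoff: float, rate: float):
    if order < 1:
        raise InvalidParameterError(f"filter order must be >= 1, got {order}")
    if not cutoff < rate / 2:
        raise InvalidParameterError(
            f"cutoff {cutoff} Hz must be below Nyquist {rate / 2} Hz"
        )
    if cutoff <= 0:
        raise InvalidParameterError(f"cutoff must be > 0, got {cutoff}")
    return sps.butter(order, cutoff, btype="low", fs=rate)


def lowpass_zero_lag(x: TimeSeries, order: int, cutoff: float) -> TimeSeries:
    """Zero-phase Butterworth low-pass (forward-backward application).

    ``order`` is the single-pass design order; the forward-backward pass
    doubles the effective attenuation, so a sinusoid exactly at ``cutoff``
    comes out with amplitude 1/2 rather than 1/sqrt(2).  Standard odd
    reflection padding of length ``3 * order`` is used at the edges.
    """
    b, a = _butter(order, cutoff, x.rate)
    _require_min_samples(x, 3 * order + 1, "zero-lag filtering")
    y = sps.filtfilt(b, a, x.values, padlen=3 * order)
    return x.with_values(y)


def lowpass_causal(x: TimeSeries, order: int, cutoff: float) -> TimeSeries:
    """Single forward-pass Butterworth low-pass (causal, introduces lag).

    Used only as an optional on-line pre-filter ahead of the detector.  The
    filter state is initialised to the first sample so a constant input is
    passed through without a start-up transient.
    """
    b, a = _butter(order, cutoff, x.rate)
    _require_min_samples(x, 3 * order + 1, "causal filtering")
    zi = sps.lfilter_zi(b, a) * x.values[0]
    y, _ = sps.lfilter(b, a, x.values, zi=zi)
    return x.with_values(y)


def resample_linear(x: TimeSeries, new_rate: float) -> TimeSeries:
    """Linear interpolation onto a uniform grid at ``new_rate``.

    The new grid starts at ``t0`` and never extends past the original span;
    the first original sample is always preserved, the last one whenever the
    span is a whole number of new sampling intervals.
    """
    if new_rate <= 0:
        raise InvalidParameterError(f"new_rate must be > 0, got {new_rate}")
    _require_min_samples(x, 2, "resampling")
    if abs(new_rate - x.rate) <= 1e-12 * x.rate:
        return x
    n_new = int(np.floor(x.duration * new_rate * (1 + 1e-12))) + 1
    t_new = x.t0 + np.arange(n_new) / new_rate
    y = np.interp(t_new, x.times(), x.values)
    return replace(x, values=y, rate=float(new_rate))


def differentiate(x: TimeSeries) -> TimeSeries:
    """Numerical time derivative: central differences in the interior,
    one-sided at the first and last sample.  Same length and rate."""
    _require_min_samples(x, 3, "differentiation")
    d = np.gradient(x.values, x.dt)
    units = f"{x.units}/s" if x.units else "1/s"
    label = f"d({x.label})/dt" if x.label else "derivative"
    return x.with_values(d, units=units, label=label)


def unwrap_degrees(x: TimeSeries) -> TimeSeries:
    """Remove +/-360 deg jumps from an angle series (degrees in, degrees out)."""
    return x.with_values(np.degrees(np.unwrap(np.radians(x.values))))


def _effective_signs(values: np.ndarray) -> np.ndarray:
    """Sample signs with exact zeros inheriting the previous nonzero sign.

    Leading zeros (no previous sign) keep sign 0 and can never produce a
    crossing on their own.
    """
    s = np.sign(values).astype(int)
    idx = np.where(s != 0, np.arange(s.size), -1)
    idx = np.maximum.accumulate(idx)
    return np.where(idx >= 0, s[np.clip(idx, 0, None)], 0)


def find_sign_changes(x: TimeSeries) -> list[SignChange]:
    """All zero crossings of ``x``, in time order.

    Exact-zero samples carry the previous nonzero sign, so a signal that
    touches zero and returns does not register a crossing, and a run of zeros
    followed by the opposite sign yields exactly one crossing timed at the
    first zero of the run.  Elsewhere the crossing time is the linear
    interpolation between the bracketing samples.
    """
    v = x.values
    s = _effective_signs(v)
    out: list[SignChange] = []
    t = x.times()
    flips = np.nonzero((s[1:] != s[:-1]) & (s[:-1] != 0) & (s[1:] != 0))[0] + 1
    for i in flips:
        direction = Direction.NEG_TO_POS if s[i] > 0 else Direction.POS_TO_NEG
        if v[i - 1] == 0.0:
            # run of zeros: time the crossing at the run's first zero sample
            j = i - 1
            while j > 0 and v[j - 1] == 0.0:
                j -= 1
            tc = t[j]
        else:
            frac = v[i - 1] / (v[i - 1] - v[i])
            tc = t[i - 1] + frac * x.dt
        out.append(SignChange(time=float(tc), direction=direction, index=int(i)))
    return out


# ---------------------------------------------------------------------------
# CSV interchange: header `time_s,<label>`, one sample per row, uniform grid.

_UNIFORM_TOL_S = 1e-6


def _infer_rate(time_s: np.ndarray, where: str) -> tuple[float, float]:
    if time_s.size < 2:
        raise InsufficientDataError(f"{where}: need >= 2 rows to infer a rate")
    dt = np.diff(time_s)
    if np.any(~np.isfinite(time_s)):
        raise LoadError(f"{where}: non-finite time stamps")
    if np.max(np.abs(dt - dt[0])) > _UNIFORM_TOL_S:
        raise LoadError(f"{where}: non-uniform sampling (tolerance {_UNIFORM_TOL_S} s)")
    if dt[0] <= 0:
        raise LoadError(f"{where}: time stamps must be strictly increasing")
    return 1.0 / float(dt[0]), float(time_s[0])


def read_timeseries_csv(path: str | Path, column: str | None = None) -> TimeSeries:
    """Read one signal from a `time_s,<label>` CSV.  NaN samples are rejected."""
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise LoadError(f"{path}: missing 'time_s' column")
    data_cols = [c for c in df.columns if c != "time_s"]
    if column is None:
        if len(data_cols) != 1:
            raise LoadError(f"{path}: expected one data column, found {data_cols}")
        column = data_cols[0]
    elif column not in df.columns:
        raise LoadError(f"{path}: no column {column!r}")
    rate, t0 = _infer_rate(df["time_s"].to_numpy(float), str(path))
    vals = df[column].to_numpy(float)
    if np.any(~np.isfinite(vals)):
        raise LoadError(f"{path}: NaN/inf samples in column {column!r}")
    return TimeSeries(values=vals, rate=rate, t0=t0, label=column)


def write_timeseries_csv(path: str | Path, series: TimeSeries | Iterable[TimeSeries]) -> None:
    """Write one or several series sharing a clock to a `time_s,...` CSV."""
    series = [series] if isinstance(series, TimeSeries) else list(series)
    ref = series[0]
    for s in series[1:]:
        if not ref.same_clock(s):
            raise InvalidParameterError("all series written together must share a clock")
    cols = {"time_s": ref.times()}
    for i, s in enumerate(series):
        cols[s.label or f"ch{i}"] = s.values
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")
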