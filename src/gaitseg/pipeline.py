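"""End-to-end processing: raw streams -> angular velocity -> events -> metrics.

Two measurement paths feed the same detector:

* **mocap** — marker tracks are linearly upsampled to the force-plate rate
  (1 kHz), low-pass filtered (zero-lag, 4th order, 10 Hz), converted to
  thigh/shank angles, composed into the virtual segments, and differentiated.
* **imu** — per-segment gyro/accelerometer channels are fused into angles by
  the scalar Kalman filter (133 Hz), composed into the virtual segments, and
  differentiated.

The virtual-segment angular velocity is always obtained by differentiating
the composed angle (matching the reference processing), not by combining
segment velocities analytically; the two agree to numerical tolerance.

The force-based reference events and strides come from the trial's belt
forces; detector events are matched against them to produce timing offsets
in % gait cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detector import DetectionResult, RuleConfig, default_config, detect_bilateral
from .errors import ConfigurationError
from .grf_events import EventKind, GaitEvent, GrfEventParams, Stride, build_strides, detect_events
from .imu_fusion import KalmanParams, kalman_fuse
from .kinematics import angle_set_from_segments, segment_angle_from_markers
from .metrics import (
    StrideCrossingCount,
    TimingOffset,
    count_crossings_per_stride,
    match_events,
)
from .signals import TimeSeries, differentiate, lowpass_zero_lag, resample_linear, unwrap_degrees
from .synthetic import GRF_RATE, SyntheticTrial

__all__ = [
    "PipelineResult",
    "mocap_segment_series",
    "imu_segment_series",
    "reference_events_and_strides",
    "run_pipeline",
]

log = logging.getLogger(__name__)

_LIMBS = ("left", "right")

MOCAP_FILTER_ORDER = 4
MOCAP_FILTER_CUTOFF_HZ = 10.0


def mocap_segment_series(
    trial: SyntheticTrial, segment: str
) -> dict[str, tuple[TimeSeries, TimeSeries]]:
    """Per-limb (angle, angular velocity) of ``segment`` from marker data."""
    out: dict[str, tuple[TimeSeries, TimeSeries]] = {}
    for limb in _LIMBS:
        mk = trial.markers[limb]
        filt = {
            name: lowpass_zero_lag(
                resample_linear(ts, GRF_RATE), MOCAP_FILTER_ORDER, MOCAP_FILTER_CUTOFF_HZ
            )
            for name, ts in mk.items()
        }
        thigh = segment_angle_from_markers(
            (filt["hip_x"], filt["hip_y"]), (filt["knee_x"], filt["knee_y"]), trial.geometry
        )
        shank = segment_angle_from_markers(
            (filt["knee_x"], filt["knee_y"]), (filt["ankle_x"], filt["ankle_y"]), trial.geometry
        )
        angles = angle_set_from_segments(
            unwrap_degrees(thigh), unwrap_degrees(shank), trial.geometry, limb=limb
        )
        angle = angles[segment]
        out[limb] = (angle, differentiate(angle))
    return out


def imu_segment_series(
    trial: SyntheticTrial, segment: str, kalman: KalmanParams = KalmanParams()
) -> dict[str, tuple[TimeSeries, TimeSeries]]:
    """Per-limb (angle, angular velocity) of ``segment`` from IMU fusion."""
    out: dict[str, tuple[TimeSeries, TimeSeries]] = {}
    for limb in _LIMBS:
        thigh = kalman_fuse(trial.imu[limb]["thigh"], kalman)
        shank = kalman_fuse(trial.imu[limb]["shank"], kalman)
        angles = angle_set_from_segments(thigh, shank, trial.geometry, limb=limb)
        angle = angles[segment]
        out[limb] = (angle, differentiate(angle))
    return out


def reference_events_and_strides(
    trial: SyntheticTrial, params: GrfEventParams = GrfEventParams()
) -> tuple[list[GaitEvent], list[Stride]]:
    """Force-based reference events and the strides they define."""
    events: list[GaitEvent] = []
    for limb in _LIMBS:
        events.extend(detect_events(trial.grf[limb], params, limb=limb))
    events.sort()
    hs = [e for e in events if e.kind is EventKind.HEEL_STRIKE]
    to = [e for e in events if e.kind is EventKind.TOE_OFF]
    return events, build_strides(hs, to)


@dataclass
class PipelineResult:
    """Everything one evaluation run produces."""

    segment: str
    source: str
    config: RuleConfig
    series: dict[str, tuple[TimeSeries, TimeSeries]]
    detections: dict[str, DetectionResult]
    reference_events: list[GaitEvent]
    strides: list[Stride]
    offsets: list[TimingOffset] = field(default_factory=list)
    extra_detected: list[GaitEvent] = field(default_factory=list)
    missed_reference: list[GaitEvent] = field(default_factory=list)
    crossing_counts: dict[str, list[StrideCrossingCount]] = field(default_factory=dict)

    def offsets_pct(self, kind: EventKind) -> np.ndarray:
        return np.array([o.offset_pct for o in self.offsets if o.kind is kind])

    def mean_crossings_per_stride(self) -> float:
        counts = [c.n_total for cc in self.crossing_counts.values() for c in cc]
        return float(np.mean(counts)) if counts else float("nan")

    def detected_events(self) -> list[GaitEvent]:
        return sorted(e for d in self.detections.values() for e in d.events)

    def summary_frame(self) -> pd.DataFrame:
        """Tidy per-(kind) summary: offset mean/sd in % gait cycle plus
        reliability (mean crossings per stride)."""
        rows = []
        for kind in (EventKind.HEEL_STRIKE, EventKind.TOE_OFF):
            v = self.offsets_pct(kind)
            rows.append(
                {
                    "segment": self.segment,
                    "source": self.source,
                    "statistic": f"{kind.value}_offset_pct",
                    "n": v.size,
                    "mean": float(v.mean()) if v.size else np.nan,
                    "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
                }
            )
        rows.append(
            {
                "segment": self.segment,
                "source": self.source,
                "statistic": "crossings_per_stride",
                "n": sum(len(c) for c in self.crossing_counts.values()),
                "mean": self.mean_crossings_per_stride(),
                "sd": np.nan,
            }
        )
        return pd.DataFrame(rows)


def run_pipeline(
    trial: SyntheticTrial,
    segment: str = "leg",
    source: str = "imu",
    config: RuleConfig | None = None,
    kalman: KalmanParams = KalmanParams(),
    grf_params: GrfEventParams = GrfEventParams(),
) -> PipelineResult:
    """Run one trial through the full detection and evaluation chain."""
    if source == "mocap":
        if not trial.markers:
            raise ConfigurationError("trial has no marker data for the mocap source")
        series = mocap_segment_series(trial, segment)
    elif source == "imu":
        if not trial.imu:
            raise ConfigurationError("trial has no IMU data for the imu source")
        series = imu_segment_series(trial, segment, kalman)
    else:
        raise ConfigurationError(f"unknown source {source!r} (imu | mocap)")

    cfg = default_config(segment) if config is None else config
    res_l, res_r = detect_bilateral(
        series["left"][1], series["right"][1], series["left"][0], series["right"][0], cfg
    )
    detections = {"left": res_l, "right": res_r}

    reference, strides = reference_events_and_strides(trial, grf_params)
    if not strides:
        log.warning("no complete reference strides in trial; empty evaluation")
        return PipelineResult(
            segment=segment,
            source=source,
            config=cfg,
            series=series,
            detections=detections,
            reference_events=reference,
            strides=[],
        )

    detected = sorted(res_l.events + res_r.events)
    # only reference events inside complete strides are scoreable
    scoreable = [
        e
        for e in reference
        if any(s.limb == e.limb and s.contains(e.time) for s in strides)
    ]
    offsets, extra, missed = match_events(detected, scoreable, strides)
    crossings = {
        limb: count_crossings_per_stride(
            series[limb][1], [s for s in strides if s.limb == limb]
        )
        for limb in _LIMBS
    }
    return PipelineResult(
        segment=segment,
        source=source,
        config=cfg,
        series=series,
        detections=detections,
        reference_events=reference,
        strides=strides,
        offsets=offsets,
        extra_detected=extra,
        missed_reference=missed,
        crossing_counts=crossings,
    )
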