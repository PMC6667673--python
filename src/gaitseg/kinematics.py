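"""Sagittal segment angles and the virtual leg / extended-leg constructions.

Angle convention
----------------
A segment is the vector from its proximal to its distal endpoint in the
sagittal plane (x horizontal along the walking direction, y vertical up).
Its angle is measured from the downward vertical and is positive when the
distal endpoint lies *posterior* to the proximal one (opposite the walking
direction).  Under this convention the limb rotates forward over the planted
foot during stance, so every segment's angular velocity is positive in
stance and negative in swing — the sign structure the detector relies on.

The virtual leg is the vector sum ``thigh_vec + shank_vec`` (hip to ankle);
the extended leg is ``2 * thigh_vec + shank_vec``, which doubles the thigh's
influence.  Both are computed from segment angles plus anthropometric
lengths so the same code serves the marker-based and the IMU-based paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, DegenerateGeometryError, InvalidParameterError
from .signals import TimeSeries

__all__ = [
    "SegmentGeometry",
    "SegmentAngleSet",
    "SEGMENTS",
    "segment_lengths_from_height",
    "segment_angle_from_markers",
    "virtual_leg_angle",
    "extended_leg_angle",
    "angle_set_from_segments",
]

#: Segment names, in the order thigh weight increases for the virtual ones.
SEGMENTS = ("thigh", "shank", "leg", "extended_leg")

#: Thigh and shank length as a fraction of body height (Winter's
#: anthropometric tables; both segments taken equal).
SEGMENT_LENGTH_FRACTION = 0.245


@dataclass(frozen=True)
class SegmentGeometry:
    """Anthropometric segment lengths and walking direction.

    ``walking_dir`` is +1 when the subject walks toward +x, -1 toward -x.
    """

    thigh_len: float
    shank_len: float
    walking_dir: int = +1

    def __post_init__(self) -> None:
        if self.thigh_len <= 0 or self.shank_len <= 0:
            raise InvalidParameterError("segment lengths must be positive")
        if self.walking_dir not in (+1, -1):
            raise InvalidParameterError("walking_dir must be +1 or -1")


@dataclass(frozen=True)
class SegmentAngleSet:
    """The four segment angle series of one limb, sharing a clock."""

    thigh: TimeSeries
    shank: TimeSeries
    leg: TimeSeries
    extended_leg: TimeSeries
    limb: str = ""

    def __post_init__(self) -> None:
        for name in ("shank", "leg", "extended_leg"):
            if not self.thigh.same_clock(getattr(self, name)):
                raise AlignmentError(f"{name} angle series not on the thigh clock")

    def __getitem__(self, segment: str) -> TimeSeries:
        if segment not in SEGMENTS:
            raise InvalidParameterError(f"unknown segment {segment!r}")
        return getattr(self, segment)


def segment_lengths_from_height(height: float, walking_dir: int = +1) -> SegmentGeometry:
    """Thigh and shank length from body height (each 24.5% of height)."""
    if height <= 0:
        raise InvalidParameterError(f"height must be > 0, got {height}")
    L = SEGMENT_LENGTH_FRACTION * height
    return SegmentGeometry(thigh_len=L, shank_len=L, walking_dir=walking_dir)


def _check_aligned(*series: TimeSeries) -> None:
    ref = series[0]
    for s in series[1:]:
        if not ref.same_clock(s):
            raise AlignmentError("input series must share rate, origin and length")


def segment_angle_from_markers(
    proximal_xy: tuple[TimeSeries, TimeSeries],
    distal_xy: tuple[TimeSeries, TimeSeries],
    geometry: SegmentGeometry,
) -> TimeSeries:
    """Sagittal segment angle from a proximal and a distal marker track.

    Returns the angle of the proximal->distal vector from the downward
    vertical, positive-posterior, in degrees, range (-180, 180].
    """
    px, py = proximal_xy
    dx_, dy_ = distal_xy
    _check_aligned(px, py, dx_, dy_)
    vx = dx_.values - px.values
    vy = dy_.values - py.values
    if np.any(np.hypot(vx, vy) < 1e-12):
        raise DegenerateGeometryError("coincident proximal/distal markers")
    ang = np.degrees(np.arctan2(-geometry.walking_dir * vx, -vy))
    return px.with_values(ang, label="segment_angle", units="deg")


def _unit_vec(angle_deg: np.ndarray, walking_dir: int) -> tuple[np.ndarray, np.ndarray]:
    """Sagittal unit vector of a segment at the given convention angle."""
    a = np.radians(angle_deg)
    return -walking_dir * np.sin(a), -np.cos(a)


def _composite_angle(
    thigh: TimeSeries,
    shank: TimeSeries,
    geometry: SegmentGeometry,
    thigh_weight: float,
    label: str,
) -> TimeSeries:
    _check_aligned(thigh, shank)
    tx, ty = _unit_vec(thigh.values, geometry.walking_dir)
    sx, sy = _unit_vec(shank.values, geometry.walking_dir)
    wx = thigh_weight * geometry.thigh_len * tx + geometry.shank_len * sx
    wy = thigh_weight * geometry.thigh_len * ty + geometry.shank_len * sy
    ang = np.degrees(np.arctan2(-geometry.walking_dir * wx, -wy))
    return thigh.with_values(ang, label=label, units="deg")


def virtual_leg_angle(
    thigh: TimeSeries, shank: TimeSeries, geometry: SegmentGeometry
) -> TimeSeries:
    """Angle of the virtual leg, the vector sum thigh_vec + shank_vec.

    With equal segment lengths this is exactly the bisector (a + b) / 2 of
    the two segment angles whenever they differ by less than 180 deg.
    """
    return _composite_angle(thigh, shank, geometry, 1.0, "leg_angle")


def extended_leg_angle(
    thigh: TimeSeries, shank: TimeSeries, geometry: SegmentGeometry
) -> TimeSeries:
    """Angle of the extended virtual leg, 2 * thigh_vec + shank_vec."""
    return _composite_angle(thigh, shank, geometry, 2.0, "extended_leg_angle")


def angle_set_from_segments(
    thigh: TimeSeries, shank: TimeSeries, geometry: SegmentGeometry, limb: str = ""
) -> SegmentAngleSet:
    """Bundle thigh/shank angles with their two virtual compositions."""
    return SegmentAngleSet(
        thigh=thigh,
        shank=shank,
        leg=virtual_leg_angle(thigh, shank, geometry),
        extended_leg=extended_leg_angle(thigh, shank, geometry),
        limb=limb,
    )
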