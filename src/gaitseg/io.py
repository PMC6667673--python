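"""Trial bundle I/O: CSV streams, events JSON, and the bundle manifest.

A trial on disk is a directory with a ``manifest.json`` naming the streams:

* ``grf.csv`` — ``time_s,grf_left_N,grf_right_N`` at the force-plate rate;
* ``markers_<limb>.csv`` — ``time_s,hip_x,hip_y,knee_x,knee_y,ankle_x,ankle_y``
  in meters at the camera rate;
* ``imu_<limb>_<segment>.csv`` — ``time_s,gyro_dps,accel_axial_g,accel_anterior_g``;
* ``truth_events.json`` — optional ground-truth event list.

The manifest records the declared rates and the subject geometry; declared
rates are cross-checked against the time stamps on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detector import RuleConfig
from .errors import LoadError
from .grf_events import EventKind, GaitEvent
from .imu_fusion import ImuChannels
from .kinematics import SegmentGeometry
from .signals import TimeSeries, _infer_rate
from .synthetic import GaitModelParams, ImuNoiseParams, SyntheticTrial

__all__ = [
    "write_trial",
    "load_bundle",
    "write_events_json",
    "read_events_json",
    "rule_config_from_yaml",
]

_LIMBS = ("left", "right")
_MARKER_COLS = ("hip_x", "hip_y", "knee_x", "knee_y", "ankle_x", "ankle_y")
_IMU_COLS = ("gyro_dps", "accel_axial_g", "accel_anterior_g")

_RATE_TOL = 1e-3  # relative


def write_events_json(path: str | Path, events: list[GaitEvent]) -> None:
    payload = [
        {"kind": e.kind.value, "limb": e.limb, "time_s": e.time, "source": e.source}
        for e in sorted(events)
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_events_json(path: str | Path) -> list[GaitEvent]:
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise LoadError(f"{path}: cannot read events JSON ({exc})") from exc
    return sorted(
        GaitEvent(
            time=float(e["time_s"]),
            kind=EventKind(e["kind"]),
            limb=e.get("limb", ""),
            source=e.get("source", "detector"),
        )
        for e in payload
    )


def rule_config_from_yaml(path: str | Path) -> RuleConfig:
    """Detector configuration from a YAML mapping of RuleConfig fields."""
    import yaml

    try:
        data = yaml.safe_load(Path(path).read_text())
    except OSError as exc:
        raise LoadError(f"{path}: cannot read config ({exc})") from exc
    if not isinstance(data, dict):
        raise LoadError(f"{path}: config must be a mapping")
    known = set(RuleConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise LoadError(f"{path}: unknown config keys {sorted(unknown)}")
    return RuleConfig(**data)


def _read_multicolumn(path: Path, cols: tuple[str, ...]) -> dict[str, TimeSeries]:
    df = pd.read_csv(path)
    missing = {"time_s", *cols} - set(df.columns)
    if missing:
        raise LoadError(f"{path}: missing columns {sorted(missing)}")
    rate, t0 = _infer_rate(df["time_s"].to_numpy(float), str(path))
    out = {}
    for c in cols:
        v = df[c].to_numpy(float)
        if np.any(~np.isfinite(v)):
            raise LoadError(f"{path}: NaN/inf in column {c!r}")
        out[c] = TimeSeries(values=v, rate=rate, t0=t0, label=c)
    return out


def _check_rate(declared: float, actual: float, what: str) -> None:
    if abs(actual - declared) > _RATE_TOL * declared:
        raise LoadError(f"{what}: declared rate {declared} Hz but time stamps give {actual:.6g} Hz")


def write_trial(trial: SyntheticTrial, outdir: str | Path, subject: str = "synthetic-01") -> Path:
    """Write a trial as a CSV/JSON bundle; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    grf_df = pd.DataFrame(
        {
            "time_s": trial.grf["left"].times(),
            "grf_left_N": trial.grf["left"].values,
            "grf_right_N": trial.grf["right"].values,
        }
    )
    grf_df.to_csv(outdir / "grf.csv", index=False, float_format="%.6g")

    for limb in _LIMBS:
        mk = trial.markers[limb]
        pd.DataFrame(
            {"time_s": mk["hip_x"].times(), **{c: mk[c].values for c in _MARKER_COLS}}
        ).to_csv(outdir / f"markers_{limb}.csv", index=False, float_format="%.9g")
        for seg in ("thigh", "shank"):
            ch = trial.imu[limb][seg]
            pd.DataFrame(
                {
                    "time_s": ch.gyro_sagittal.times(),
                    "gyro_dps": ch.gyro_sagittal.values,
                    "accel_axial_g": ch.accel_axial.values,
                    "accel_anterior_g": ch.accel_anterior.values,
                }
            ).to_csv(outdir / f"imu_{limb}_{seg}.csv", index=False, float_format="%.9g")

    write_events_json(outdir / "truth_events.json", trial.truth_events)
    write_events_json(outdir / "kinematic_truth.json", trial.kinematic_truth)

    manifest = {
        "schema": "gaitseg-trial/1",
        "subject": subject,
        "condition": {"speed_mps": trial.params.speed, "slope_deg": trial.params.slope},
        "n_strides": trial.n_strides,
        "geometry": {
            "thigh_len_m": trial.geometry.thigh_len,
            "shank_len_m": trial.geometry.shank_len,
            "walking_dir": trial.geometry.walking_dir,
        },
        "rates_hz": {
            "grf": trial.grf["left"].rate,
            "markers": trial.markers["left"]["hip_x"].rate,
            "imu": trial.imu["left"]["thigh"].rate,
        },
        "params": {
            "stride_time_s": trial.params.stride_time,
            "duty_factor": trial.params.duty_factor,
            "retraction_lead_pct": trial.params.retraction_lead,
            "height_m": trial.params.height,
            "body_mass_kg": trial.params.body_mass,
            "seed": trial.params.seed,
        },
        "files": {
            "grf": "grf.csv",
            **{f"markers_{limb}": f"markers_{limb}.csv" for limb in _LIMBS},
            **{
                f"imu_{limb}_{seg}": f"imu_{limb}_{seg}.csv"
                for limb in _LIMBS
                for seg in ("thigh", "shank")
            },
            "truth_events": "truth_events.json",
            "kinematic_truth": "kinematic_truth.json",
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def load_bundle(manifest_path: str | Path) -> SyntheticTrial:
    """Load a trial bundle back into memory, cross-checking declared rates.

    The returned trial carries the loaded marker, IMU and force streams plus
    any stored truth events; the analytic angle sets are not reconstructed
    (``angles`` is empty).
    """
    manifest_path = Path(manifest_path)
    try:
        manifest = json.loads(manifest_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise LoadError(f"{manifest_path}: cannot read manifest ({exc})") from exc
    root = manifest_path.parent
    files = manifest.get("files", {})
    rates = manifest.get("rates_hz", {})

    def _path(key: str) -> Path:
        if key not in files:
            raise LoadError(f"{manifest_path}: manifest lists no {key!r} stream")
        p = root / files[key]
        if not p.exists():
            raise LoadError(f"{manifest_path}: missing file for {key!r}: {p}")
        return p

    grf_cols = _read_multicolumn(_path("grf"), ("grf_left_N", "grf_right_N"))
    grf = {
        "left": grf_cols["grf_left_N"],
        "right": grf_cols["grf_right_N"],
    }
    if "grf" in rates:
        _check_rate(rates["grf"], grf["left"].rate, "grf")

    markers: dict[str, dict[str, TimeSeries]] = {}
    imu: dict[str, dict[str, ImuChannels]] = {}
    for limb in _LIMBS:
        markers[limb] = _read_multicolumn(_path(f"markers_{limb}"), _MARKER_COLS)
        if "markers" in rates:
            _check_rate(rates["markers"], markers[limb]["hip_x"].rate, f"markers_{limb}")
        imu[limb] = {}
        for seg in ("thigh", "shank"):
            cols = _read_multicolumn(_path(f"imu_{limb}_{seg}"), _IMU_COLS)
            if "imu" in rates:
                _check_rate(rates["imu"], cols["gyro_dps"].rate, f"imu_{limb}_{seg}")
            imu[limb][seg] = ImuChannels(
                gyro_sagittal=cols["gyro_dps"],
                accel_axial=cols["accel_axial_g"],
                accel_anterior=cols["accel_anterior_g"],
            )

    truth: list[GaitEvent] = []
    if "truth_events" in files and (root / files["truth_events"]).exists():
        truth = read_events_json(root / files["truth_events"])
    kin: list[GaitEvent] = []
    if "kinematic_truth" in files and (root / files["kinematic_truth"]).exists():
        kin = read_events_json(root / files["kinematic_truth"])

    geo = manifest.get("geometry", {})
    geometry = SegmentGeometry(
        thigh_len=geo.get("thigh_len_m", 0.245 * 1.78),
        shank_len=geo.get("shank_len_m", 0.245 * 1.78),
        walking_dir=int(geo.get("walking_dir", +1)),
    )
    p = manifest.get("params", {})
    cond = manifest.get("condition", {})
    params = GaitModelParams(
        speed=cond.get("speed_mps", 1.3),
        slope=cond.get("slope_deg", 0.0),
        stride_time=p.get("stride_time_s"),
        duty_factor=p.get("duty_factor"),
        height=p.get("height_m", 1.78),
        body_mass=p.get("body_mass_kg", 69.5),
        retraction_lead=p.get("retraction_lead_pct", 4.0),
        seed=p.get("seed", 0),
    )
    return SyntheticTrial(
        params=params,
        noise=ImuNoiseParams(),
        n_strides=int(manifest.get("n_strides", 0)),
        geometry=geometry,
        angles={},
        markers=markers,
        imu=imu,
        grf=grf,
        truth_events=truth,
        kinematic_truth=kin,
    )
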