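"""Per-frame processing of captured motion streams.

The optical tracker delivers object translations in millimetres and rotations
as exponential maps at a nominal 200 Hz. Before the poses can drive a scene
they pass through the offline replay of the acquisition chain:

1. occlusion gaps are filled by interpolation (short gaps only),
2. a single-pole low-pass smoother removes rig vibration,
3. translations are scaled to scene units (cm) and rotations converted to
   quaternions,
4. a force monitor raises a warning event whenever the applied instrument
   force exceeds the critical-force threshold (default 20 N).

All operations are pure: they return new streams and never mutate inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FileFormatError, InvalidArgumentError
from .geom import (
    RigidTransform,
    expmap_to_quaternion,
    geodesic_angle,
    quat_slerp,
    quaternion_to_expmap,
)

__all__ = [
    "RawPose",
    "MotionFrame",
    "MotionStream",
    "ScenePose",
    "ForceTrace",
    "WarningEvent",
    "GapRecord",
    "convert_frame",
    "convert_stream",
    "lowpass",
    "lowpass_gain",
    "fill_occlusions",
    "detect_orientation_flips",
    "monitor_force",
    "CRITICAL_FORCE_N",
    "MM_TO_CM",
]

#: critical instrument force (N): loads above this risk injuring the
#: vertebral endplate / spinal cord, so the simulator warns the trainee
CRITICAL_FORCE_N = 20.0

#: default scene scale: capture positions arrive in mm, the scene uses cm
MM_TO_CM = 0.1


@dataclass(frozen=True)
class RawPose:
    """As-captured pose: translation (mm) + exponential-map rotation (rad)."""

    translation: np.ndarray
    rotation_vector: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))
        object.__setattr__(
            self, "rotation_vector", np.asarray(self.rotation_vector, dtype=float).reshape(3)
        )


@dataclass(frozen=True)
class ScenePose:
    """Scene-ready pose: translation in scene units (cm) + unit quaternion."""

    translation: np.ndarray
    rotation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float).reshape(4))


@dataclass
class MotionFrame:
    frame_index: int
    timestamp: float
    poses: dict[str, RawPose] = field(default_factory=dict)
    marker_visibility: dict[str, bool] = field(default_factory=dict)


@dataclass
class MotionStream:
    """Ordered capture frames plus the nominal acquisition rate (Hz)."""

    frames: list[MotionFrame]
    nominal_rate: float = 200.0

    def __post_init__(self):
        if not self.frames:
            raise InvalidArgumentError("motion stream must be non-empty")
        if not self.nominal_rate > 0:
            raise InvalidArgumentError("nominal rate must be positive")
        ts = [f.timestamp for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise InvalidArgumentError("timestamps must be strictly increasing")

    def objects(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.frames:
            for name in f.poses:
                seen.setdefault(name)
        return list(seen)

    # -- CSV interchange ---------------------------------------------------
    # dialect: frame,time_s,object,tx_mm,ty_mm,tz_mm,rx,ry,rz,visible_markers
    # (rotations are exponential maps in radians; a missing pose is a row
    # with empty pose fields; visible_markers is a ';'-joined name list)

    CSV_COLUMNS = [
        "frame", "time_s", "object",
        "tx_mm", "ty_mm", "tz_mm", "rx", "ry", "rz", "visible_markers",
    ]

    def to_csv(self, path) -> None:
        rows = []
        all_objects = sorted(self.objects())
        for f in self.frames:
            objects = all_objects if all_objects else [""]
            for obj in objects:
                pose = f.poses.get(obj)
                vis = ";".join(sorted(k for k, v in f.marker_visibility.items() if v))
                if pose is None:
                    rows.append([f.frame_index, f.timestamp, obj, "", "", "", "", "", "", vis])
                else:
                    rows.append(
                        [f.frame_index, f.timestamp, obj,
                         *(f"{v:.9g}" for v in pose.translation),
                         *(f"{v:.9g}" for v in pose.rotation_vector), vis]
                    )
        df = pd.DataFrame(rows, columns=self.CSV_COLUMNS)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, nominal_rate: float = 200.0) -> "MotionStream":
        try:
            df = pd.read_csv(path, dtype={"object": str, "visible_markers": str})
        except Exception as e:  # pragma: no cover - pandas error variety
            raise FileFormatError(f"{path}: cannot parse capture CSV: {e}") from e
        missing = [c for c in cls.CSV_COLUMNS if c not in df.columns]
        if missing:
            raise FileFormatError(f"{path}: capture CSV missing columns {missing}")
        frames: dict[int, MotionFrame] = {}
        for _, row in df.iterrows():
            idx = int(row["frame"])
            fr = frames.setdefault(idx, MotionFrame(idx, float(row["time_s"])))
            obj = row["object"]
            if isinstance(obj, str) and obj:
                if pd.notna(row["tx_mm"]):
                    fr.poses[obj] = RawPose(
                        [row["tx_mm"], row["ty_mm"], row["tz_mm"]],
                        [row["rx"], row["ry"], row["rz"]],
                    )
            vis = row["visible_markers"]
            if isinstance(vis, str) and vis:
                for name in vis.split(";"):
                    fr.marker_visibility[name] = True
        ordered = [frames[k] for k in sorted(frames)]
        return cls(ordered, nominal_rate=nominal_rate)


@dataclass
class ForceTrace:
    """Applied instrument force samples (timestamps s, forces N)."""

    timestamps: np.ndarray
    forces: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float).ravel()
        self.forces = np.asarray(self.forces, dtype=float).ravel()
        if len(self.timestamps) != len(self.forces):
            raise InvalidArgumentError("timestamps and forces differ in length")
        if np.any(self.forces < 0):
            raise InvalidArgumentError("forces must be non-negative")
        if np.any(np.diff(self.timestamps) <= 0):
            raise InvalidArgumentError("force timestamps must be strictly increasing")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.timestamps, "force_N": self.forces}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "ForceTrace":
        df = pd.read_csv(path)
        if "time_s" not in df.columns or "force_N" not in df.columns:
            raise FileFormatError(f"{path}: force CSV needs columns time_s,force_N")
        return cls(df["time_s"].to_numpy(), df["force_N"].to_numpy())


@dataclass(frozen=True)
class WarningEvent:
    """Critical-force excursion: stamped at the first sample over threshold."""

    timestamp: float
    force: float
    threshold: float
    message: str


@dataclass(frozen=True)
class GapRecord:
    """An occlusion gap for one object: frame indices with no pose."""

    object_name: str
    start_frame: int
    end_frame: int  # inclusive
    length: int
    reason: str  # "filled", "too-long", "boundary"


def convert_frame(frame: MotionFrame, scale: float = MM_TO_CM) -> dict[str, ScenePose]:
    """Scale translations into scene units and convert rotations to quaternions."""
    out: dict[str, ScenePose] = {}
    for name, pose in frame.poses.items():
        out[name] = ScenePose(pose.translation * scale, expmap_to_quaternion(pose.rotation_vector))
    return out


def convert_stream(
    stream: MotionStream, scale: float = MM_TO_CM
) -> list[tuple[int, float, dict[str, ScenePose]]]:
    """Apply :func:`convert_frame` to every frame of a stream."""
    return [(f.frame_index, f.timestamp, convert_frame(f, scale)) for f in stream.frames]


def lowpass_gain(alpha: float, omega: float) -> float:
    """Magnitude response of the one-pole smoother ``y_k = (1-a) y_{k-1} + a x_k``
    at normalized angular frequency ``omega`` (rad/sample)."""
    return alpha / np.sqrt(1.0 - 2.0 * (1.0 - alpha) * np.cos(omega) + (1.0 - alpha) ** 2)


def lowpass(stream: MotionStream, alpha: float) -> MotionStream:
    """Single-pole exponential smoothing of every object's pose track.

    Translations are smoothed componentwise; rotations are smoothed by
    spherical interpolation toward the previous *filtered* orientation with
    the same factor, which keeps them on the unit-quaternion manifold (a
    componentwise filter on exponential maps is not rotation-consistent).
    ``alpha = 1`` is the identity; the DC gain is exactly 1. Frames with a
    missing pose leave the filter state untouched.
    """
    if not (0.0 < alpha <= 1.0):
        raise InvalidArgumentError(f"alpha must be in (0, 1], got {alpha}")
    state_t: dict[str, np.ndarray] = {}
    state_q: dict[str, np.ndarray] = {}
    new_frames: list[MotionFrame] = []
    for f in stream.frames:
        poses: dict[str, RawPose] = {}
        for name, pose in f.poses.items():
            q = expmap_to_quaternion(pose.rotation_vector)
            if name not in state_t:
                ft, fq = pose.translation.copy(), q
            else:
                ft = state_t[name] + alpha * (pose.translation - state_t[name])
                fq = quat_slerp(state_q[name], q, alpha)
            state_t[name], state_q[name] = ft, fq
            poses[name] = RawPose(ft, quaternion_to_expmap(fq))
        new_frames.append(
            MotionFrame(f.frame_index, f.timestamp, poses, dict(f.marker_visibility))
        )
    return MotionStream(new_frames, nominal_rate=stream.nominal_rate)


def fill_occlusions(
    stream: MotionStream, max_gap: int
) -> tuple[MotionStream, list[GapRecord]]:
    """Reconstruct short occlusion gaps by interpolation.

    For every object, runs of frames without a pose that are flanked by
    observed frames and no longer than ``max_gap`` are filled by linear
    interpolation of translation and spherical-linear interpolation of
    rotation (parameterized by timestamp). Longer gaps and gaps touching a
    stream boundary are left unmodified and reported. Originally present
    frames are never altered, which also makes the operation idempotent.
    """
    if max_gap < 0:
        raise InvalidArgumentError("max_gap must be >= 0")
    new_frames = [
        MotionFrame(f.frame_index, f.timestamp, dict(f.poses), dict(f.marker_visibility))
        for f in stream.frames
    ]
    gaps: list[GapRecord] = []
    for obj in stream.objects():
        present = [i for i, f in enumerate(new_frames) if obj in f.poses]
        if not present:
            continue
        # leading/trailing gaps: no extrapolation
        if present[0] > 0:
            gaps.append(
                GapRecord(obj, new_frames[0].frame_index,
                          new_frames[present[0] - 1].frame_index, present[0], "boundary")
            )
        if present[-1] < len(new_frames) - 1:
            gaps.append(
                GapRecord(obj, new_frames[present[-1] + 1].frame_index,
                          new_frames[-1].frame_index,
                          len(new_frames) - 1 - present[-1], "boundary")
            )
        for a, b in zip(present, present[1:]):
            gap_len = b - a - 1
            if gap_len == 0:
                continue
            if gap_len > max_gap:
                gaps.append(
                    GapRecord(obj, new_frames[a + 1].frame_index,
                              new_frames[b - 1].frame_index, gap_len, "too-long")
                )
                continue
            pa, pb = new_frames[a].poses[obj], new_frames[b].poses[obj]
            qa = expmap_to_quaternion(pa.rotation_vector)
            qb = expmap_to_quaternion(pb.rotation_vector)
            ta, tb = new_frames[a].timestamp, new_frames[b].timestamp
            for k in range(a + 1, b):
                u = (new_frames[k].timestamp - ta) / (tb - ta)
                trans = (1.0 - u) * pa.translation + u * pb.translation
                rot = quaternion_to_expmap(quat_slerp(qa, qb, u))
                new_frames[k].poses[obj] = RawPose(trans, rot)
            gaps.append(
                GapRecord(obj, new_frames[a + 1].frame_index,
                          new_frames[b - 1].frame_index, gap_len, "filled")
            )
    return MotionStream(new_frames, nominal_rate=stream.nominal_rate), gaps


def detect_orientation_flips(
    stream: MotionStream, angle_threshold: float = np.pi / 2
) -> list[int]:
    """Frames whose orientation jumps by more than ``angle_threshold`` radians.

    Marker occlusion can make the tracker re-solve an object upside-down;
    such frames show a large geodesic rotation distance to the previous
    observed frame of the same object. Returns sorted unique frame indices.
    """
    if not (0.0 < angle_threshold <= np.pi):
        raise InvalidArgumentError("angle_threshold must be in (0, pi]")
    flagged: set[int] = set()
    for obj in stream.objects():
        prev_q = None
        for f in stream.frames:
            pose = f.poses.get(obj)
            if pose is None:
                continue
            q = expmap_to_quaternion(pose.rotation_vector)
            if prev_q is not None and geodesic_angle(prev_q, q) > angle_threshold:
                flagged.add(f.frame_index)
            prev_q = q
    return sorted(flagged)


def monitor_force(
    trace: ForceTrace, threshold: float = CRITICAL_FORCE_N
) -> list[WarningEvent]:
    """Warn once per contiguous excursion of the force above the threshold.

    The comparison is strictly greater-than: a sample exactly at the critical
    force does not warn. Each event is stamped at the first exceeding sample
    of its excursion (one event per excursion avoids flooding the trainee
    with repeated warnings).
    """
    if not threshold > 0:
        raise InvalidArgumentError("threshold must be positive")
    events: list[WarningEvent] = []
    above = False
    for t, fval in zip(trace.timestamps, trace.forces):
        if fval > threshold and not above:
            events.append(
                WarningEvent(
                    timestamp=float(t),
                    force=float(fval),
                    threshold=float(threshold),
                    message=(
                        f"applied force {fval:.2f} N exceeds critical force "
                        f"{threshold:.2f} N"
                    ),
                )
            )
            above = True
        elif fval <= threshold:
            above = False
    return events


def pose_to_transform(pose: RawPose) -> RigidTransform:
    """View a raw pose as the rigid transform it encodes."""
    return RigidTransform(expmap_to_quaternion(pose.rotation_vector), pose.translation)
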