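"""Offline replay of the acquisition -> conversion -> scene-input chain.

One configured run takes a captured motion CSV through occlusion filling,
low-pass smoothing and scene conversion, optionally composes the registration
transform so the virtual model lands where the physical object is, evaluates
the critical-force monitor on an instrument force trace, and writes a
scene-pose CSV, a warning log and a machine-readable JSON run report.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .errors import ConfigError, MrsimError
from .motion import (
    CRITICAL_FORCE_N,
    MM_TO_CM,
    ForceTrace,
    MotionStream,
    convert_frame,
    detect_orientation_flips,
    fill_occlusions,
    lowpass,
    monitor_force,
)
from .registration import Correspondence, register_captured
from .vsk import read_vsk

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


class RunConfig(BaseModel):
    """Validated run configuration (YAML/JSON friendly).

    All parameters are echoed into the run report for auditability.
    """

    capture: Path
    out_dir: Path
    vsk: Path | None = None
    correspondence: Path | None = None
    force_trace: Path | None = None
    scale: float = Field(default=MM_TO_CM, gt=0)
    alpha: float = Field(default=1.0, gt=0, le=1.0)
    max_gap: int = Field(default=3, ge=0)
    force_threshold: float = Field(default=CRITICAL_FORCE_N, gt=0)
    flip_threshold: float = Field(default=math.pi / 2, gt=0, le=math.pi)
    nominal_rate: float = Field(default=200.0, gt=0)
    seed: int = 0
    log_level: str = "INFO"

    @field_validator("log_level")
    @classmethod
    def _known_level(cls, v: str) -> str:
        if v.upper() not in {"DEBUG", "INFO", "WARNING", "ERROR"}:
            raise ValueError(f"unknown log level {v!r}")
        return v.upper()

    def validate_inputs(self) -> None:
        """Fail before any stage runs if a referenced input is missing."""
        for name in ("capture", "vsk", "correspondence", "force_trace"):
            p = getattr(self, name)
            if p is not None and not Path(p).is_file():
                raise ConfigError(f"{name} file not found: {p}")
        if (self.vsk is None) != (self.correspondence is None):
            raise ConfigError("vsk and correspondence must be given together")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full offline pipeline; returns the run report dict.

    Stages: occlusion filling -> low-pass filtering -> flip detection ->
    scene conversion (with the registration transform composed in when a
    tracking model + correspondence are configured) -> force monitoring.
    Partial outputs are removed if any stage fails.
    """
    config.validate_inputs()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = [out_dir / "scene_poses.csv", out_dir / "warnings.log", out_dir / "report.json"]
    try:
        return _run_stages(config, out_dir)
    except MrsimError:
        for p in outputs:
            p.unlink(missing_ok=True)
        raise


def _run_stages(config: RunConfig, out_dir: Path) -> dict:
    stream = MotionStream.from_csv(config.capture, nominal_rate=config.nominal_rate)

    reg = None
    if config.vsk is not None:
        model = read_vsk(config.vsk)
        corr = Correspondence.read_csv(config.correspondence)
        reg = register_captured(model.marker_set, corr)
        log.info("registration rms residual: %.6g", reg.rms_residual)

    filled, gaps = fill_occlusions(stream, config.max_gap)
    smoothed = lowpass(filled, config.alpha)
    flips = detect_orientation_flips(smoothed, config.flip_threshold)

    rows = []
    for frame in smoothed.frames:
        for obj, pose in convert_frame(frame, config.scale).items():
            q, t = pose.rotation, pose.translation
            if reg is not None:
                from .geom import RigidTransform

                scene = RigidTransform(q, t).compose(
                    RigidTransform(
                        reg.transform.rotation, reg.transform.translation * config.scale
                    )
                )
                q, t = scene.rotation, scene.translation
            rows.append(
                [frame.frame_index, frame.timestamp, obj,
                 *(f"{v:.9g}" for v in t), *(f"{v:.9g}" for v in q)]
            )
    pd.DataFrame(
        rows,
        columns=["frame", "time_s", "object", "tx_cm", "ty_cm", "tz_cm",
                 "qw", "qx", "qy", "qz"],
    ).to_csv(out_dir / "scene_poses.csv", index=False)

    warnings_events = []
    if config.force_trace is not None:
        trace = ForceTrace.from_csv(config.force_trace)
        warnings_events = monitor_force(trace, config.force_threshold)

    with open(out_dir / "warnings.log", "w") as fh:
        for g in gaps:
            if g.reason != "filled":
                fh.write(
                    f"GAP object={g.object_name} frames {g.start_frame}-{g.end_frame} "
                    f"({g.reason})\n"
                )
        for fi in flips:
            fh.write(f"FLIP frame={fi}\n")
        for ev in warnings_events:
            fh.write(f"FORCE t={ev.timestamp:.4f}s {ev.message}\n")

    report = {
        "mrsim_version": __version__,
        "config": json.loads(config.model_dump_json()),
        "n_frames": len(smoothed.frames),
        "objects": smoothed.objects(),
        "gaps_filled": sum(1 for g in gaps if g.reason == "filled"),
        "gaps_unresolved": sum(1 for g in gaps if g.reason != "filled"),
        "flips_detected": len(flips),
        "force_warnings": len(warnings_events),
        "registration_rms": None if reg is None else reg.rms_residual,
        "first_warning": None
        if not warnings_events
        else {"time_s": warnings_events[0].timestamp, "force_N": warnings_events[0].force},
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
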