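"""Tracking-model (VSK-style) XML generation, parsing and validation.

A rigid tracking model is a single free *root* segment with six degrees of
freedom plus a set of retro-reflective markers whose coordinates are given
relative to that root. The optical tracker imports the file and is then able
to follow the physical object without any manual calibration session.

The documented dialect (formal schema in ``docs/vsk-dialect.md``) keeps the
four elements a real subject file carries — ``Parameters``, ``Segment``,
``MarkerSet`` and ``Radius`` — plus a ``version`` attribute and an explicit
``units="mm"`` tag. Reads are lenient (foreign elements are preserved as
opaque payload) while writes are strict and byte-reproducible: numbers use a
fixed 6-decimal format, UTF-8, LF line endings.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FileFormatError, TrackabilityError
from .registration import DEFAULT_MARKER_RADIUS, MarkerSet, _is_collinear

__all__ = ["TrackingModel", "write_vsk", "read_vsk", "validate_model"]

log = logging.getLogger(__name__)

DIALECT_VERSION = "1.0"
ROOT_JOINT_KIND = "Free"
ROOT_DOF = 6


@dataclass
class TrackingModel:
    """Rigid tracking model: free 6-DOF root segment + root-relative markers."""

    marker_set: MarkerSet
    root_name: str = "root"
    joint_kind: str = ROOT_JOINT_KIND
    degrees_of_freedom: int = ROOT_DOF
    source_mesh_name: str | None = None
    #: foreign XML elements found on read, kept verbatim (lenient read policy)
    extras: list[str] = field(default_factory=list)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrackingModel):
            return NotImplemented
        return (
            self.root_name == other.root_name
            and self.joint_kind == other.joint_kind
            and self.degrees_of_freedom == other.degrees_of_freedom
            and self.source_mesh_name == other.source_mesh_name
            and self.marker_set.names == other.marker_set.names
            and np.allclose(self.marker_set.positions, other.marker_set.positions, atol=1e-9)
            and abs(self.marker_set.radius - other.marker_set.radius) < 1e-9
        )


def _fmt(v: float) -> str:
    return f"{float(v):.6f}"


def write_vsk(model: TrackingModel, destination) -> str:
    """Serialize a tracking model to the documented XML dialect.

    Refuses models with fewer than three markers (not trackable). Returns the
    document text; ``destination`` may be a path or None to only render.
    """
    ms = model.marker_set
    if len(ms) < 3:
        raise TrackabilityError(
            f"model has {len(ms)} markers; a minimum of three is required for tracking"
        )
    lines = ['<?xml version="1.0" encoding="UTF-8"?>']
    attrs = f'version="{DIALECT_VERSION}" units="mm"'
    if model.source_mesh_name:
        attrs += f' source_mesh="{model.source_mesh_name}"'
    lines.append(f"<KinematicModel {attrs}>")
    lines.append("  <Parameters>")
    for name, pos in zip(ms.names, ms.positions):
        for axis, v in zip("xyz", pos):
            lines.append(f'    <Parameter name="{name}_{axis}" value="{_fmt(v)}"/>')
    lines.append("  </Parameters>")
    lines.append(
        f'  <Segment name="{model.root_name}" joint="{model.joint_kind}"'
        f' dof="{model.degrees_of_freedom}"/>'
    )
    lines.append("  <MarkerSet>")
    for name, pos in zip(ms.names, ms.positions):
        pos_s = " ".join(_fmt(v) for v in pos)
        lines.append(f'    <Marker name="{name}" segment="{model.root_name}" position="{pos_s}"/>')
    lines.append("  </MarkerSet>")
    lines.append(f'  <Radius value="{_fmt(ms.radius)}"/>')
    lines.append("</KinematicModel>")
    text = "\n".join(lines) + "\n"
    if destination is not None:
        Path(destination).write_bytes(text.encode("utf-8"))
    return text


def _byte_offset(text: str, line: int, col: int) -> int:
    parts = text.split("\n")
    return sum(len(p.encode("utf-8")) + 1 for p in parts[: line - 1]) + col


def read_vsk(source) -> TrackingModel:
    """Parse a tracking-model XML file (lenient).

    Unknown elements are preserved verbatim in ``model.extras``; a missing
    ``Radius`` falls back to the documented default (0.5) with a logged
    warning; a missing ``MarkerSet`` is a schema error.
    """
    path = Path(source)
    text = path.read_text(encoding="utf-8")
    try:
        root = ET.fromstring(text)
    except ET.ParseError as e:
        line, col = e.position
        raise FileFormatError(
            f"{path}: malformed XML at byte offset {_byte_offset(text, line, col)}"
            f" (line {line}, column {col}): {e.msg if hasattr(e, 'msg') else e}"
        ) from e

    seg = root.find("Segment")
    root_name = seg.get("name", "root") if seg is not None else "root"
    joint = seg.get("joint", ROOT_JOINT_KIND) if seg is not None else ROOT_JOINT_KIND
    dof = int(seg.get("dof", ROOT_DOF)) if seg is not None else ROOT_DOF

    marker_el = root.find("MarkerSet")
    if marker_el is None:
        raise FileFormatError(f"{path}: missing required element at /KinematicModel/MarkerSet")
    names, positions = [], []
    for m in marker_el.findall("Marker"):
        name = m.get("name")
        pos_s = m.get("position")
        if name is None or pos_s is None:
            raise FileFormatError(
                f"{path}: Marker element missing name/position at /KinematicModel/MarkerSet/Marker"
            )
        names.append(name)
        positions.append([float(v) for v in pos_s.split()])

    radius_el = root.find("Radius")
    if radius_el is None or radius_el.get("value") is None:
        radius = DEFAULT_MARKER_RADIUS
        log.warning("%s: missing Radius element; using default %.1f", path, radius)
    else:
        radius = float(radius_el.get("value"))

    known = {"Parameters", "Segment", "MarkerSet", "Radius"}
    extras = [
        ET.tostring(child, encoding="unicode").strip()
        for child in root
        if child.tag not in known
    ]

    return TrackingModel(
        marker_set=MarkerSet(names, np.array(positions, dtype=float).reshape(-1, 3), radius=radius),
        root_name=root_name,
        joint_kind=joint,
        degrees_of_freedom=dof,
        source_mesh_name=root.get("source_mesh"),
        extras=extras,
    )


def validate_model(model: TrackingModel) -> list[str]:
    """Diagnostic check; returns a list of violations (empty = trackable).

    Checks the minimum-three-markers rule, collinearity of the marker
    configuration, duplicate names, marker radius, and the free 6-DOF root.
    """
    violations: list[str] = []
    ms = model.marker_set
    if len(ms) < 3:
        violations.append(f"insufficient markers (min 3, got {len(ms)})")
    if len(set(ms.names)) != len(ms.names):
        violations.append("duplicate marker names")
    if len(ms) >= 3 and _is_collinear(ms.positions):
        violations.append("collinear marker configuration")
    if not ms.radius > 0:
        violations.append(f"non-positive marker radius ({ms.radius})")
    if model.joint_kind != ROOT_JOINT_KIND or model.degrees_of_freedom != ROOT_DOF:
        violations.append(
            f"root joint must be free with 6 degrees of freedom "
            f"(got {model.joint_kind}/{model.degrees_of_freedom})"
        )
    return violations
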