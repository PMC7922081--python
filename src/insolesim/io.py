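"""Readers and writers for the package's on-disk formats.

Recording file (TSV):
    ``@key value`` metadata lines (fs, size, side, task, surface_mm2, bw_N),
    ``#``-prefixed geometry header lines (first one names the columns:
    sensor_id, center_x, center_y, width, height, region), then one
    tab-separated row of pressures per frame, columns in geometry order.

Layout file: JSON with name, insole_size, sensor_side_mm and a sensor list.

Marker file: CSV with ``@label`` / ``@fs`` comment lines and a
``frame,t,x,y,z`` header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import geometry
from .core import (
    FormatError,
    InsoleLayout,
    MarkerTrajectory,
    PressureRecording,
    SensorGeometry,
    check_no_overlap,
    check_unique_ids,
)

_GEOM_COLUMNS = ("sensor_id", "center_x", "center_y", "width", "height", "region")

_META_KEYS = {
    "fs": float,
    "size": str,
    "side": str,
    "task": str,
    "surface_mm2": float,
    "bw_N": float,
}


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def write_recording(rec: PressureRecording, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"@fs {_fmt(rec.fs)}",
        f"@size {rec.insole_size}",
        f"@side {rec.side}",
        f"@task {rec.task}",
        f"@surface_mm2 {_fmt(rec.total_surface_mm2)}",
        f"@bw_N {_fmt(rec.body_weight_N)}",
        "# " + "\t".join(_GEOM_COLUMNS),
    ]
    for s in rec.sensors:
        lines.append(
            "# "
            + "\t".join(
                [
                    str(s.sensor_id),
                    _fmt(s.center_x),
                    _fmt(s.center_y),
                    _fmt(s.width),
                    _fmt(s.height),
                    s.region,
                ]
            )
        )
    for row in rec.pressures:
        lines.append("\t".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_recording(path: str | Path) -> PressureRecording:
    path = Path(path)
    meta: dict[str, object] = {}
    sensors: list[SensorGeometry] = []
    rows: list[list[float]] = []
    saw_geom_header = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("@"):
            try:
                key, value = line[1:].split(None, 1)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed metadata line") from exc
            if key not in _META_KEYS:
                raise FormatError(f"{path}:{lineno}: unknown metadata key @{key}")
            meta[key] = _META_KEYS[key](value.strip())
        elif line.startswith("#"):
            body = line[1:].strip()
            if not saw_geom_header:
                if tuple(body.split("\t")) != _GEOM_COLUMNS:
                    raise FormatError(
                        f"{path}:{lineno}: geometry header must name columns "
                        f"{' '.join(_GEOM_COLUMNS)}"
                    )
                saw_geom_header = True
                continue
            parts = body.split("\t")
            if len(parts) != len(_GEOM_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: geometry line has {len(parts)} fields, "
                    f"expected {len(_GEOM_COLUMNS)}"
                )
            try:
                sensors.append(
                    SensorGeometry(
                        sensor_id=int(parts[0]),
                        center_x=float(parts[1]),
                        center_y=float(parts[2]),
                        width=float(parts[3]),
                        height=float(parts[4]),
                        region=parts[5],
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad geometry values") from exc
        else:
            parts = line.split("\t")
            if len(parts) != len(sensors):
                raise FormatError(
                    f"{path}:{lineno}: frame row has {len(parts)} values but the "
                    f"header declares {len(sensors)} sensors"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric pressure value") from exc
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise FormatError(f"{path}: missing metadata lines: {missing}")
    if not sensors:
        raise FormatError(f"{path}: no sensor geometry header found")
    pressures = (
        np.array(rows, dtype=float)
        if rows
        else np.empty((0, len(sensors)), dtype=float)
    )
    return PressureRecording(
        sensors=sensors,
        pressures=pressures,
        fs=meta["fs"],
        insole_size=meta["size"],
        side=meta["side"],
        task=meta["task"],
        total_surface_mm2=meta["surface_mm2"],
        body_weight_N=meta["bw_N"],
    )


def write_layout(layout: InsoleLayout, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "name": layout.name,
        "insole_size": layout.insole_size,
        "sensor_side_mm": layout.sensor_side_mm,
        "sensors": [
            {"id": s.sensor_id, "cx": s.center_x, "cy": s.center_y, "region": s.region}
            for s in layout.sensors
        ],
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_layout(path: str | Path) -> InsoleLayout:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    try:
        side = float(payload["sensor_side_mm"])
        sensors = [
            SensorGeometry(
                sensor_id=int(s["id"]),
                center_x=float(s["cx"]),
                center_y=float(s["cy"]),
                width=side,
                height=side,
                region=s["region"],
            )
            for s in payload["sensors"]
        ]
        layout = InsoleLayout(
            name=str(payload["name"]),
            insole_size=str(payload["insole_size"]),
            sensors=sensors,
            sensor_side_mm=side,
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing layout field {exc}") from exc
    check_unique_ids(layout.sensors)
    check_no_overlap(layout.sensors)
    return layout


def write_marker(marker: MarkerTrajectory, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"@label {marker.label}",
        f"@fs {_fmt(marker.fs)}",
        "frame,t,x,y,z",
    ]
    for i, (x, y, z) in enumerate(marker.positions):
        t = i / marker.fs
        lines.append(f"{i},{_fmt(t)},{_fmt(x)},{_fmt(y)},{_fmt(z)}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_marker(path: str | Path) -> MarkerTrajectory:
    path = Path(path)
    label = None
    fs = None
    rows: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("@label"):
            label = line.split(None, 1)[1].strip()
        elif line.startswith("@fs"):
            fs = float(line.split(None, 1)[1])
        elif line.startswith("frame,"):
            continue
        else:
            parts = line.split(",")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected frame,t,x,y,z row")
            rows.append([float(parts[2]), float(parts[3]), float(parts[4])])
    if label is None or fs is None:
        raise FormatError(f"{path}: missing @label or @fs line")
    positions = np.array(rows, dtype=float) if rows else np.empty((0, 3))
    return MarkerTrajectory(label=label, positions=positions, fs=fs)


__all__ = [
    "read_recording",
    "write_recording",
    "read_layout",
    "write_layout",
    "read_marker",
    "write_marker",
]
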