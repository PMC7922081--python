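"""Simulation of the reduced insole on a high-resolution recording.

Each simulated sensor is fed the arithmetic mean of a disjoint group of
experimental sensors: by default its k = 3 nearest cells by center-to-center
distance, with global conflict resolution (a cell claimed by two simulated
sensors goes to the nearer one and the loser refills from its next-nearest);
alternatively all cells whose rectangle geometrically overlaps the simulated
square.  Groups are kept disjoint so no physical cell is double counted in
downstream loss-of-data maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry
from .core import InsoleLayout, PressureRecording, SensorGeometry, ValidationError


@dataclass
class GroupMap:
    """Assignment of experimental sensors to each simulated sensor."""

    groups: dict[int, list[int]]  # simulated sensor_id -> experimental sensor_ids
    method: str  # k_nearest | geometric_overlap
    k: int | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for sim_id, members in self.groups.items():
            if not members:
                raise ValidationError(f"simulated sensor {sim_id} has an empty group")
            dup = seen.intersection(members)
            if dup:
                raise ValidationError(
                    f"experimental sensors {sorted(dup)} belong to more than one group"
                )
            seen.update(members)

    @property
    def covered(self) -> set[int]:
        out: set[int] = set()
        for members in self.groups.values():
            out.update(members)
        return out


def assign_groups(
    layout: InsoleLayout,
    sensor_geometry: list[SensorGeometry],
    method: str = "k_nearest",
    k: int = 3,
) -> GroupMap:
    """Group experimental sensors under each simulated sensor."""
    if method == "k_nearest":
        return _assign_k_nearest(layout, sensor_geometry, k)
    if method == "geometric_overlap":
        return _assign_overlap(layout, sensor_geometry)
    raise ValueError(f"unknown grouping method {method!r}")


def _assign_k_nearest(
    layout: InsoleLayout, sensor_geometry: list[SensorGeometry], k: int
) -> GroupMap:
    n_exp = len(sensor_geometry)
    n_sim = layout.n_sensors
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k * n_sim > n_exp:
        raise ValidationError(
            f"k={k} with {n_sim} simulated sensors needs {k * n_sim} experimental "
            f"sensors, only {n_exp} available"
        )
    sim_centers = np.array([[s.center_x, s.center_y] for s in layout.sensors])
    exp_centers = np.array([[s.center_x, s.center_y] for s in sensor_geometry])
    dist = np.linalg.norm(sim_centers[:, None, :] - exp_centers[None, :, :], axis=2)
    # globally ascending (distance, simulated id, experimental id): each cell
    # ends up with its nearest claimant, losers refill from next-nearest
    order = sorted(
        ((dist[j, i], j, i) for j in range(n_sim) for i in range(n_exp)),
        key=lambda t: (t[0], layout.sensors[t[1]].sensor_id, sensor_geometry[t[2]].sensor_id),
    )
    groups: dict[int, list[int]] = {s.sensor_id: [] for s in layout.sensors}
    taken: set[int] = set()
    filled = 0
    for _, j, i in order:
        sim_id = layout.sensors[j].sensor_id
        exp_id = sensor_geometry[i].sensor_id
        if exp_id in taken or len(groups[sim_id]) >= k:
            continue
        groups[sim_id].append(exp_id)
        taken.add(exp_id)
        if len(groups[sim_id]) == k:
            filled += 1
            if filled == n_sim:
                break
    if any(len(m) < k for m in groups.values()):
        raise ValidationError("could not fill every group after conflict resolution")
    return GroupMap(groups=groups, method="k_nearest", k=k)


def _assign_overlap(
    layout: InsoleLayout, sensor_geometry: list[SensorGeometry]
) -> GroupMap:
    groups: dict[int, list[int]] = {s.sensor_id: [] for s in layout.sensors}
    for exp in sensor_geometry:
        best_key = None
        best_sim = None
        for sim in layout.sensors:
            area = geometry.rects_overlap_area(sim.center, sim.size, exp.center, exp.size)
            if area <= 0:
                continue
            d = float(np.hypot(sim.center_x - exp.center_x, sim.center_y - exp.center_y))
            key = (-area, d, sim.sensor_id)  # larger overlap, then nearer, then id
            if best_key is None or key < best_key:
                best_key, best_sim = key, sim.sensor_id
        if best_sim is not None:
            groups[best_sim].append(exp.sensor_id)
    empty = [sid for sid, members in groups.items() if not members]
    if empty:
        raise ValidationError(
            f"simulated sensors {empty} overlap no experimental sensor"
        )
    return GroupMap(groups=groups, method="geometric_overlap")


def simulate_recording(
    rec: PressureRecording, gmap: GroupMap, layout: InsoleLayout
) -> PressureRecording:
    """Reduced-insole recording: each simulated sensor reads the arithmetic
    mean of its group members, frame by frame; metadata is carried over."""
    id_to_col = {s.sensor_id: i for i, s in enumerate(rec.sensors)}
    if set(gmap.groups) != {s.sensor_id for s in layout.sensors}:
        raise ValidationError("group map does not match the layout's sensor ids")
    sim_pressures = np.empty((rec.n_frames, layout.n_sensors))
    for j, sim_sensor in enumerate(layout.sensors):
        members = gmap.groups[sim_sensor.sensor_id]
        try:
            cols = [id_to_col[m] for m in members]
        except KeyError as exc:
            raise ValidationError(
                f"group member {exc} not present in the recording"
            ) from exc
        sim_pressures[:, j] = rec.pressures[:, cols].mean(axis=1)
    return PressureRecording(
        sensors=list(layout.sensors),
        pressures=sim_pressures,
        fs=rec.fs,
        insole_size=rec.insole_size,
        side=rec.side,
        task=rec.task,
        total_surface_mm2=rec.total_surface_mm2,
        body_weight_N=rec.body_weight_N,
    )
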