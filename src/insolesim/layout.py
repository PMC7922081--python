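"""Reduced-sensor layout design from peak-pressure location statistics.

The reduced insole places 16 square 15 x 15 mm sensors at the experimental
sensor centers where the pressure peak occurs most often, under per-region
quotas (4 hindfoot: 2 medial + 2 lateral; 3 midfoot: 1 medial + 2 lateral;
9 forefoot, of which 2 on the toes) and geometric feasibility (sensor square
inside the footprint outline, minimum gap between accepted squares).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import geometry
from .core import (
    DEFAULT_N_SIMULATED,
    DEFAULT_SENSOR_SIDE_MM,
    InsoleLayout,
    PressureRecording,
    SensorGeometry,
    ValidationError,
)

#: region groups used for quotas; "forefoot" pools the medial and lateral
#: forefoot, "toes" is its own group
REGION_GROUPS: dict[str, tuple[str, ...]] = {
    "hindfoot_medial": ("hindfoot_medial",),
    "hindfoot_lateral": ("hindfoot_lateral",),
    "midfoot_medial": ("midfoot_medial",),
    "midfoot_lateral": ("midfoot_lateral",),
    "forefoot": ("forefoot_medial", "forefoot_lateral"),
    "toes": ("toes",),
}

DEFAULT_QUOTAS: dict[str, int] = {
    "hindfoot_medial": 2,
    "hindfoot_lateral": 2,
    "midfoot_medial": 1,
    "midfoot_lateral": 2,
    "forefoot": 7,
    "toes": 2,
}

#: group processing order (posterior to anterior, medial before lateral)
_GROUP_ORDER = (
    "hindfoot_medial",
    "hindfoot_lateral",
    "midfoot_medial",
    "midfoot_lateral",
    "forefoot",
    "toes",
)


@dataclass(frozen=True)
class LayoutConstraints:
    n_sensors: int = DEFAULT_N_SIMULATED
    sensor_side: float = DEFAULT_SENSOR_SIDE_MM
    quotas: tuple[tuple[str, int], ...] = tuple(DEFAULT_QUOTAS.items())
    min_gap: float = 2.0

    def __post_init__(self) -> None:
        q = dict(self.quotas)
        unknown = set(q) - set(REGION_GROUPS)
        if unknown:
            raise ValidationError(f"unknown region groups in quotas: {sorted(unknown)}")
        if any(v < 0 for v in q.values()):
            raise ValidationError("quotas must be >= 0")
        if sum(q.values()) != self.n_sensors:
            raise ValidationError(
                f"quotas sum to {sum(q.values())} but n_sensors is {self.n_sensors}"
            )
        if self.min_gap < 0:
            raise ValidationError("min_gap must be >= 0")

    @property
    def quota_map(self) -> dict[str, int]:
        return dict(self.quotas)


@dataclass
class PeakHistogram:
    """How often the spatial pressure peak fell on each experimental sensor."""

    counts: np.ndarray
    n_trials: int
    mode: str  # per_trial | per_frame
    geometry: list[SensorGeometry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValidationError("histogram counts must be >= 0")


def _same_geometry(a: list[SensorGeometry], b: list[SensorGeometry]) -> bool:
    if len(a) != len(b):
        return False
    return all(
        s.sensor_id == t.sensor_id
        and abs(s.center_x - t.center_x) < 1e-9
        and abs(s.center_y - t.center_y) < 1e-9
        for s, t in zip(a, b)
    )


def peak_location_histogram(
    recordings: list[PressureRecording], mode: str = "per_trial"
) -> PeakHistogram:
    """Count, per experimental sensor, how often it holds the pressure peak.

    ``per_trial``: one count per trial, on the sensor holding the trial's
    global maximum (ties to the lowest sensor_id).  ``per_frame``: one count
    per loaded frame, on the frame's argmax sensor.
    """
    if not recordings:
        raise ValidationError("peak_location_histogram requires at least one recording")
    if mode not in ("per_trial", "per_frame"):
        raise ValueError(f"unknown histogram mode {mode!r}")
    ref = recordings[0].sensors
    counts = np.zeros(len(ref), dtype=int)
    for rec in recordings:
        if not _same_geometry(rec.sensors, ref):
            raise ValidationError("recordings have mixed sensor geometries")
        if mode == "per_trial":
            if rec.pressures.size == 0 or rec.pressures.max() <= 0:
                continue
            flat = int(np.argmax(rec.pressures))  # row-major: earliest frame,
            counts[flat % rec.n_sensors] += 1  # lowest sensor_id on ties
        else:
            loaded = rec.pressures.max(axis=1) > 0
            if loaded.any():
                idx = np.argmax(rec.pressures[loaded], axis=1)
                np.add.at(counts, idx, 1)
    return PeakHistogram(
        counts=counts, n_trials=len(recordings), mode=mode, geometry=list(ref)
    )


def _candidate_feasible(
    cx: float,
    cy: float,
    side: float,
    insole_size: str,
    accepted: list[tuple[float, float]],
    min_gap: float,
) -> bool:
    if not geometry.rect_inside(cx, cy, side, side, insole_size):
        return False
    for ax, ay in accepted:
        if geometry.rect_gap((cx, cy), (side, side), (ax, ay), (side, side)) < min_gap:
            return False
    return True


def _rank_key(counts: np.ndarray, sensors: list[SensorGeometry]):
    # descending count; ties to lower y, then lower x
    def key(i: int):
        s = sensors[i]
        return (-counts[i], s.center_y, s.center_x)

    return key


def design_layout(
    hist: PeakHistogram,
    sensor_geometry: list[SensorGeometry],
    constraints: LayoutConstraints | None = None,
    insole_size: str | None = None,
    name: str = "designed",
) -> InsoleLayout:
    """Greedy constrained selection of simulated sensor centers.

    Per region group, candidates (experimental sensor centers) are ranked by
    descending histogram count (ties: lower y, then lower x) and accepted
    when their square stays inside the footprint and at ``min_gap`` from all
    previously accepted squares, until the group's quota is met.  If the
    greedy pass cannot fill a quota, a deterministic exhaustive repair over
    the group's best-ranked candidates is attempted before raising.
    """
    constraints = constraints or LayoutConstraints()
    if len(hist.counts) != len(sensor_geometry):
        raise ValidationError("histogram length does not match sensor geometry")
    if insole_size is None:
        raise ValueError("insole_size must be provided")
    side = constraints.sensor_side
    accepted: list[tuple[float, float]] = []
    chosen: list[SensorGeometry] = []
    sid = 0
    for group in _GROUP_ORDER:
        quota = constraints.quota_map.get(group, 0)
        if quota == 0:
            continue
        regions = REGION_GROUPS[group]
        cand = [i for i, s in enumerate(sensor_geometry) if s.region in regions]
        cand.sort(key=_rank_key(hist.counts, sensor_geometry))
        picked = _greedy_pick(
            cand, quota, sensor_geometry, side, insole_size, accepted, constraints.min_gap
        )
        if picked is None:
            picked = _exhaustive_pick(
                cand, quota, hist.counts, sensor_geometry, side, insole_size,
                accepted, constraints.min_gap,
            )
        if picked is None:
            raise ValidationError(
                f"quota of {quota} sensors unreachable in region group {group!r}"
            )
        for i in picked:
            s = sensor_geometry[i]
            accepted.append((s.center_x, s.center_y))
            chosen.append(
                SensorGeometry(
                    sensor_id=sid,
                    center_x=s.center_x,
                    center_y=s.center_y,
                    width=side,
                    height=side,
                    region=s.region,
                )
            )
            sid += 1
    return InsoleLayout(
        name=name, insole_size=insole_size, sensors=chosen, sensor_side_mm=side
    )


def _greedy_pick(cand, quota, sensors, side, insole_size, accepted, min_gap):
    local = list(accepted)
    picked = []
    for i in cand:
        s = sensors[i]
        if _candidate_feasible(s.center_x, s.center_y, side, insole_size, local, min_gap):
            picked.append(i)
            local.append((s.center_x, s.center_y))
            if len(picked) == quota:
                return picked
    return None


def _exhaustive_pick(
    cand, quota, counts, sensors, side, insole_size, accepted, min_gap, max_pool=12
):
    """Highest-total-count feasible subset among the best-ranked candidates."""
    pool = [
        i
        for i in cand
        if _candidate_feasible(
            sensors[i].center_x, sensors[i].center_y, side, insole_size, accepted, min_gap
        )
    ][:max_pool]
    best = None
    best_score = None
    for combo in itertools.combinations(pool, min(quota, len(pool))):
        if len(combo) < quota:
            break
        local = list(accepted)
        ok = True
        for i in combo:
            s = sensors[i]
            if not _candidate_feasible(s.center_x, s.center_y, side, insole_size, local, min_gap):
                ok = False
                break
            local.append((s.center_x, s.center_y))
        if not ok:
            continue
        score = sum(int(counts[i]) for i in combo)
        if best_score is None or score > best_score:
            best, best_score = list(combo), score
    return best


@lru_cache(maxsize=8)
def _canonical_histogram(insole_size: str) -> PeakHistogram:
    """Per-frame peak histogram over one noise-free trial of each task.

    This fixed, seedless reference drives the shipped default layouts, so
    they are a pure function of the package code.
    """
    from . import synthetic  # local import: layout <-> synthetic layering

    recs = []
    for task in ("gait", "drop", "lifting"):
        params = synthetic.TrialParams(
            task=task, insole_size=insole_size, noise_sd=0.0, seed=0, n_steps=3
        )
        rec, _, _ = synthetic.generate_trial(params)
        recs.append(rec)
    return peak_location_histogram(recs, mode="per_frame")


@lru_cache(maxsize=8)
def default_layout(insole_size: str) -> InsoleLayout:
    """The shipped 16-sensor layout for an insole size.

    The 38-39 layout is designed from the canonical histogram; larger sizes
    are affine-scaled from it, keeping the 15 mm sensor side.
    """
    geometry.validate_size(insole_size)
    base_size = "38-39"
    hist = _canonical_histogram(base_size)
    base = design_layout(
        hist,
        hist.geometry,
        LayoutConstraints(),
        insole_size=base_size,
        name=f"default-{base_size}",
    )
    if insole_size == base_size:
        return base
    scaled = scale_layout(base, insole_size)
    return InsoleLayout(
        name=f"default-{insole_size}",
        insole_size=insole_size,
        sensors=scaled.sensors,
        sensor_side_mm=scaled.sensor_side_mm,
    )


def scale_layout(layout: InsoleLayout, to_size: str) -> InsoleLayout:
    """Affine-scale sensor centers by the footprint length/width ratios;
    the sensor side is left unchanged."""
    geometry.validate_size(to_size)
    L0, W0 = geometry.size_dims(layout.insole_size)
    L1, W1 = geometry.size_dims(to_size)
    sensors = []
    for s in layout.sensors:
        cx = s.center_x * (W1 / W0)
        cy = s.center_y * (L1 / L0)
        sensors.append(
            SensorGeometry(
                sensor_id=s.sensor_id,
                center_x=cx,
                center_y=cy,
                width=s.width,
                height=s.height,
                region=geometry.region_of(cx, cy, to_size),
            )
        )
    return InsoleLayout(
        name=f"{layout.name}-scaled-{to_size}",
        insole_size=to_size,
        sensors=sensors,
        sensor_side_mm=layout.sensor_side_mm,
    )
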