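"""Shared data types: sensor geometry, pressure recordings, layouts, markers.

Units: pressure %BW/mm^2 (percent body weight per square millimetre),
distances mm, sampling rate Hz, vertical load %BW.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry

TASKS = ("gait", "drop", "lifting")
SIDES = ("left", "right")

DEFAULT_SENSOR_SIDE_MM = 15.0
DEFAULT_N_SIMULATED = 16


class ValidationError(ValueError):
    """A domain invariant was violated."""


class FormatError(ValueError):
    """An on-disk file does not follow the documented dialect."""


@dataclass(frozen=True)
class SensorGeometry:
    """One rectangular pressure cell: center position, size and region label."""

    sensor_id: int
    center_x: float  # mm, medial -> lateral
    center_y: float  # mm, posterior -> anterior
    width: float  # mm
    height: float  # mm
    region: str

    def __post_init__(self) -> None:
        if self.sensor_id < 0:
            raise ValidationError(f"sensor_id must be >= 0, got {self.sensor_id}")
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(
                f"sensor {self.sensor_id}: width/height must be > 0"
            )
        if self.region not in geometry.REGIONS:
            raise ValidationError(
                f"sensor {self.sensor_id}: unknown region {self.region!r}"
            )

    @property
    def area_mm2(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.center_x, self.center_y)

    @property
    def size(self) -> tuple[float, float]:
        return (self.width, self.height)


def check_no_overlap(sensors: list[SensorGeometry]) -> None:
    """Raise if any two sensor rectangles intersect with positive area."""
    for i, a in enumerate(sensors):
        for b in sensors[i + 1:]:
            if geometry.rects_overlap_area(a.center, a.size, b.center, b.size) > 0:
                raise ValidationError(
                    f"sensors {a.sensor_id} and {b.sensor_id} overlap"
                )


def check_unique_ids(sensors: list[SensorGeometry]) -> None:
    ids = [s.sensor_id for s in sensors]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sensor_id in sensor list")


@dataclass
class PressureRecording:
    """Time x sensor pressure matrix with per-sensor geometry and metadata."""

    sensors: list[SensorGeometry]
    pressures: np.ndarray  # [n_frames, n_sensors], %BW/mm^2
    fs: float  # Hz
    insole_size: str
    side: str
    task: str
    total_surface_mm2: float
    body_weight_N: float = 675.0

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.pressures.ndim != 2:
            raise ValidationError("pressures must be a 2-D [frames x sensors] array")
        if self.pressures.shape[1] != len(self.sensors):
            raise ValidationError(
                f"pressures has {self.pressures.shape[1]} columns but "
                f"{len(self.sensors)} sensors are declared"
            )
        if not np.all(np.isfinite(self.pressures)):
            raise ValidationError("pressures contain non-finite values")
        if np.any(self.pressures < 0):
            raise ValidationError("negative pressure after zero-offset subtraction")
        if self.fs <= 0:
            raise ValidationError("fs must be > 0")
        geometry.validate_size(self.insole_size)
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.task not in TASKS:
            raise ValidationError(f"task must be one of {TASKS}, got {self.task!r}")
        check_unique_ids(self.sensors)
        area_sum = sum(s.area_mm2 for s in self.sensors)
        if self.total_surface_mm2 < area_sum - 1e-6:
            raise ValidationError(
                f"total_surface_mm2 ({self.total_surface_mm2:.1f}) is smaller than "
                f"the summed sensor areas ({area_sum:.1f})"
            )

    @property
    def n_frames(self) -> int:
        return self.pressures.shape[0]

    @property
    def n_sensors(self) -> int:
        return len(self.sensors)

    @property
    def sensor_areas(self) -> np.ndarray:
        return np.array([s.area_mm2 for s in self.sensors])

    @property
    def sensor_centers(self) -> np.ndarray:
        """[n_sensors, 2] array of (x, y) centers in mm."""
        return np.array([[s.center_x, s.center_y] for s in self.sensors])

    def with_pressures(self, pressures: np.ndarray) -> "PressureRecording":
        return replace(self, pressures=pressures)

    def sensors_in_region(self, *regions: str) -> list[int]:
        """Column indices of sensors whose region label is in ``regions``."""
        return [i for i, s in enumerate(self.sensors) if s.region in regions]


@dataclass
class InsoleLayout:
    """A reduced set of square simulated sensors for one insole size."""

    name: str
    insole_size: str
    sensors: list[SensorGeometry] = field(default_factory=list)
    sensor_side_mm: float = DEFAULT_SENSOR_SIDE_MM

    def __post_init__(self) -> None:
        geometry.validate_size(self.insole_size)
        check_unique_ids(self.sensors)
        check_no_overlap(self.sensors)
        for s in self.sensors:
            if not geometry.rect_inside(
                s.center_x, s.center_y, s.width, s.height, self.insole_size
            ):
                raise ValidationError(
                    f"layout sensor {s.sensor_id} does not lie inside the "
                    f"{self.insole_size} footprint outline"
                )

    @property
    def n_sensors(self) -> int:
        return len(self.sensors)

    @property
    def sensorized_area_mm2(self) -> float:
        return sum(s.area_mm2 for s in self.sensors)

    def region_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sensors:
            counts[s.region] = counts.get(s.region, 0) + 1
        return counts


@dataclass
class MarkerTrajectory:
    """A labelled 3-D marker trajectory (positions in mm)."""

    label: str
    positions: np.ndarray  # [n_frames, 3]
    fs: float

    LABELS = ("L5", "heel_left", "heel_right")

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError("positions must be an [n_frames x 3] array")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("marker positions contain non-finite values")
        if self.fs <= 0:
            raise ValidationError("fs must be > 0")
        if self.label not in self.LABELS:
            raise ValidationError(
                f"label must be one of {self.LABELS}, got {self.label!r}"
            )

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def z(self) -> np.ndarray:
        return self.positions[:, 2]


@dataclass
class ZeroingProfile:
    """Per-sensor contact thresholds derived from an unloaded baseline."""

    thresholds: np.ndarray  # [n_sensors], %BW/mm^2

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.ndim != 1:
            raise ValidationError("thresholds must be a 1-D vector")
        if np.any(self.thresholds < 0) or not np.all(np.isfinite(self.thresholds)):
            raise ValidationError("thresholds must be finite and >= 0")
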