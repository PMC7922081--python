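"""Task window and phase detection from pressure and marker signals.

Gait: initial contact (IC) is the first instant the summed heel-region
pressure exceeds its zeroing threshold; toe-off (TO) the first following
instant the hallux signal drops back below its threshold.  Heel-marker
minima, when available, corroborate each IC.

Drop landing: the task starts when the hallux signal of the platform leg
goes below threshold, landing is the first whole-insole loading after the
airborne window, and the task ends two seconds after landing.

Lifting: phase boundaries come from the low-pass-filtered vertical L5
trajectory — two local minima bound the loaded phases, and the top plateau
between them (leave-and-peak) is emitted but flagged as excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import MarkerTrajectory, PressureRecording, ValidationError, ZeroingProfile
from .variables import butterworth_lowpass

#: default zeroing margin added to per-sensor baseline maxima, %BW/mm^2
#: (~3.4 kPa at a 675 N body weight, comparable to capacitive-cell
#: activation thresholds)
DEFAULT_ZEROING_MARGIN = 5e-4


@dataclass(frozen=True)
class TaskSegment:
    """A labelled, half-open frame window [start_frame, end_frame)."""

    label: str
    start_frame: int
    end_frame: int
    source: str  # pressure | marker | combined
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0 <= self.start_frame < self.end_frame:
            raise ValidationError(
                f"segment {self.label!r}: need 0 <= start < end, got "
                f"[{self.start_frame}, {self.end_frame})"
            )

    @property
    def excluded(self) -> bool:
        return "excluded" in self.flags


def zeroing_thresholds(
    baseline: PressureRecording, margin: float = DEFAULT_ZEROING_MARGIN
) -> ZeroingProfile:
    """Per-sensor threshold = maximum over the unloaded baseline + margin."""
    if margin < 0:
        raise ValidationError("margin must be >= 0")
    if baseline.n_frames == 0:
        maxima = np.zeros(baseline.n_sensors)
    else:
        maxima = baseline.pressures.max(axis=0)
    return ZeroingProfile(thresholds=maxima + margin)


def _region_signal(
    rec: PressureRecording, zp: ZeroingProfile, columns: list[int]
) -> tuple[np.ndarray, float]:
    """Summed pressure over a sensor subset and the matching summed threshold."""
    if not columns:
        raise ValidationError("no sensors found for the requested region")
    signal = rec.pressures[:, columns].sum(axis=1)
    threshold = float(zp.thresholds[columns].sum())
    return signal, threshold


def _first_sustained(mask: np.ndarray, min_frames: int = 3) -> int | None:
    """First index opening a run of at least ``min_frames`` true values
    (debounces isolated noise crossings; a shorter trailing run counts when
    it reaches the end of the signal)."""
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return None
    n = len(mask)
    for i in idx:
        run = mask[i: i + min_frames]
        if run.all() or (i + min_frames > n and mask[i:].all()):
            return int(i)
    return None


def heel_columns(rec: PressureRecording) -> list[int]:
    return rec.sensors_in_region("hindfoot_medial", "hindfoot_lateral")


def hallux_columns(rec: PressureRecording) -> list[int]:
    """Medial half of the toes region."""
    cols = rec.sensors_in_region("toes")
    if not cols:
        return cols
    xs = [rec.sensors[i].center_x for i in cols]
    midline = float(np.median(xs))
    hallux = [i for i in cols if rec.sensors[i].center_x <= midline]
    return hallux or cols


def _marker_low_mask(marker: MarkerTrajectory, band: float = 0.25) -> np.ndarray:
    """Frames where the filtered marker height sits in the lowest ``band``
    fraction of its excursion (foot on the ground)."""
    z = butterworth_lowpass(marker.z, marker.fs)
    rng = z.max() - z.min()
    if rng <= 0:
        return np.ones(len(z), dtype=bool)
    return z < z.min() + band * rng


def detect_gait_events(
    rec: PressureRecording,
    zp: ZeroingProfile,
    heel_marker: MarkerTrajectory | None = None,
    marker_tolerance_frames: int = 15,
) -> list[TaskSegment]:
    """One segment per step, IC -> TO, from heel/hallux threshold crossings."""
    heel, heel_thr = _region_signal(rec, zp, heel_columns(rec))
    hallux, hallux_thr = _region_signal(rec, zp, hallux_columns(rec))
    n = rec.n_frames
    low = _marker_low_mask(heel_marker) if heel_marker is not None else None

    segments: list[TaskSegment] = []
    t = 0
    step = 0
    while t < n:
        above = _first_sustained(heel[t:] > heel_thr)
        if above is None:
            break
        ic = t + above
        # hallux must first activate after IC, then drop back below threshold
        act = _first_sustained(hallux[ic:] > hallux_thr)
        if act is None:
            break
        act0 = ic + act
        below = _first_sustained(hallux[act0:] < hallux_thr)
        to = act0 + below if below is not None else n
        flags: tuple[str, ...] = ()
        source = "pressure"
        if low is not None:
            source = "combined"
            # the heel marker must reach the ground within the tolerance
            # window around the pressure-detected contact
            w0 = max(ic - marker_tolerance_frames, 0)
            w1 = min(ic + marker_tolerance_frames + 1, len(low))
            if not low[w0:w1].any():
                flags = ("marker_mismatch",)
        segments.append(
            TaskSegment(
                label=f"step_{step}", start_frame=ic, end_frame=to,
                source=source, flags=flags,
            )
        )
        step += 1
        t = to + 1
    if not segments:
        warnings.warn("no gait steps detected", stacklevel=2)
    return segments


def detect_drop_window(
    rec: PressureRecording, zp: ZeroingProfile, fs: float | None = None
) -> TaskSegment:
    """Drop-landing window: hallux release -> landing + 2 s."""
    fs = fs or rec.fs
    hallux, hallux_thr = _region_signal(rec, zp, hallux_columns(rec))
    total = rec.pressures.sum(axis=1)
    total_thr = float(zp.thresholds.sum())

    act = _first_sustained(hallux > hallux_thr)
    if act is None:
        raise ValidationError("no drop detected: hallux never loaded")
    below = _first_sustained(hallux[act:] < hallux_thr)
    if below is None:
        raise ValidationError("no drop detected: hallux never released")
    start = act + below

    air = _first_sustained(total[start:] < total_thr)
    if air is None:
        raise ValidationError("no drop detected: no airborne window after release")
    air0 = start + air
    loaded = _first_sustained(total[air0:] > total_thr)
    if loaded is None:
        raise ValidationError("no drop detected: no landing after airborne window")
    landing = air0 + loaded

    end = landing + int(round(2 * fs))
    flags: tuple[str, ...] = ()
    if end > rec.n_frames:
        end = rec.n_frames
        flags = ("clipped",)
    return TaskSegment(
        label="drop", start_frame=start, end_frame=end, source="pressure", flags=flags
    )


def detect_lifting_phases(
    l5: MarkerTrajectory,
    velocity_fraction: float = 0.05,
    height_fraction: float = 0.8,
) -> list[TaskSegment]:
    """Five squat-lift phases from the filtered vertical L5 trajectory.

    UD: start -> first minimum; LA: first minimum -> plateau onset;
    leave-and-peak: the top plateau (flagged excluded); LD: plateau end ->
    second minimum; UA: second minimum -> end.  Plateau bounds are the
    frames where the vertical velocity stays below ``velocity_fraction`` of
    its peak while the marker is within the top ``1 - height_fraction`` band.
    """
    if l5.label != "L5":
        raise ValidationError("lifting phases require the L5 marker")
    z = butterworth_lowpass(l5.z, l5.fs)
    rng = z.max() - z.min()
    if rng <= 0:
        raise ValidationError("monotone or flat L5 trajectory: no lift detected")
    peaks, props = find_peaks(-z, prominence=0.05 * rng, plateau_size=1)
    minima = props.get("left_edges", peaks)
    if len(minima) < 2:
        raise ValidationError(
            f"expected 2 L5 minima (descend-ascend twice), found {len(minima)}"
        )
    m1, m2 = int(minima[0]), int(minima[1])

    between = slice(m1, m2 + 1)
    v = np.gradient(z)
    vmax = np.max(np.abs(v[between]))
    z_top = z[between].max()
    z_low = min(z[m1], z[m2])
    height_gate = z_low + height_fraction * (z_top - z_low)
    still = (np.abs(v) < velocity_fraction * vmax) & (z > height_gate)
    still_idx = np.nonzero(still[m1: m2 + 1])[0] + m1
    if len(still_idx) == 0:
        raise ValidationError("no top plateau found between the two minima")
    p_start, p_end = int(still_idx[0]), int(still_idx[-1]) + 1

    n = l5.n_frames
    return [
        TaskSegment("UD", 0, m1, "marker"),
        TaskSegment("LA", m1, p_start, "marker"),
        TaskSegment("leave_and_peak", p_start, p_end, "marker", ("excluded",)),
        TaskSegment("LD", p_end, m2, "marker"),
        TaskSegment("UA", m2, n, "marker"),
    ]
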