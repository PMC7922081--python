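"""Synthetic 99-sensor pressure recordings and marker trajectories.

The generator emulates the temporal and spatial structure of three tasks
(self-selected walking, single-leg drop landing from a 32 cm platform, and a
five-phase squat lift) on a 99-cell in-shoe pressure grid sampled at 100 Hz.

Model: the instantaneous pressure field is a convex combination of
anatomically placed 2-D Gaussian blobs (heel, lateral arch, metatarsal
heads, hallux, lateral toes).  Each blob is normalized by its *discrete*
spatial integral over the sensor grid, so that the frame-wise vertical load
Σ_i p_i·A_i equals an analytic load profile L(t) exactly (to rounding), and
the analytic center of pressure is the blob-weighted mean of discrete blob
centroids.  Both are emitted as ground truth next to every trial, which
makes every downstream stage checkable without real data.

With ``noise_sd = 0`` trials are deterministic closed-form fields; otherwise
additive Gaussian sensor noise, truncated at zero, is applied.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry, io
from .core import MarkerTrajectory, PressureRecording, SensorGeometry

#: anatomical pressure sources: (x fraction of width, y fraction of length,
#: Gaussian sigma in mm).  x is medial->lateral, so the hallux and first
#: metatarsal head sit at low x in this side-relative frame.
ANATOMY: dict[str, tuple[float, float, float]] = {
    "heel": (0.50, 0.16, 18.0),
    "arch_lateral": (0.65, 0.43, 14.0),
    "met_medial": (0.34, 0.72, 11.0),
    "met_central": (0.48, 0.72, 12.0),
    "met_lateral": (0.66, 0.71, 11.0),
    "hallux": (0.35, 0.88, 8.0),
    "toes_lateral": (0.60, 0.87, 8.0),
}

_BLOB_ORDER = tuple(ANATOMY)

_N_ROWS = 12
_N_CELLS = 99
_ROW_SPAN = (0.05, 0.93)  # normalized y band covered by the sensor rows


@dataclass(frozen=True)
class TrialParams:
    """Conditions of one synthetic trial; ``seed`` fixes all randomness."""

    task: str
    insole_size: str = "38-39"
    side: str = "left"
    body_weight_N: float = 675.0
    n_steps: int = 10  # gait
    n_reps: int = 1  # lifting
    peak_amplitude: float | None = None  # peak vertical load, %BW
    load_kg: float = 16.0  # lifted mass (lifting task)
    blob_widths: tuple[tuple[str, float], ...] | None = None
    noise_sd: float = 0.001  # %BW/mm^2
    seed: int = 0
    cell_mode: str = "tiled"
    amplitude_scale: float = 1.0
    duration_scale: float = 1.0
    fs: float = 100.0

    def __post_init__(self) -> None:
        if self.task not in ("gait", "drop", "lifting"):
            raise ValueError(f"unknown task {self.task!r}")
        geometry.validate_size(self.insole_size)
        if self.peak_amplitude is not None and self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.amplitude_scale <= 0 or self.duration_scale <= 0:
            raise ValueError("scales must be > 0")

    @property
    def default_peak(self) -> float:
        return {"gait": 115.0, "drop": 250.0, "lifting": 50.0}[self.task]

    @property
    def peak(self) -> float:
        base = self.peak_amplitude if self.peak_amplitude is not None else self.default_peak
        return base * self.amplitude_scale

    @property
    def load_pct_bw(self) -> float:
        """Lifted mass as %BW (whole body, both insoles)."""
        return 100.0 * self.load_kg * 9.81 / self.body_weight_N


@dataclass
class TrialGroundTruth:
    """Analytic labels emitted with every trial (exact when noise_sd = 0)."""

    task: str
    fs: float
    load: np.ndarray  # analytic vertical load per frame, %BW
    cop: np.ndarray  # analytic COP per frame [n, 2] mm, NaN when unloaded
    events: dict[str, int] = field(default_factory=dict)
    step_windows: list[tuple[int, int]] = field(default_factory=list)
    phases: dict[str, tuple[int, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "fs": self.fs,
            "load": [round(float(v), 9) for v in self.load],
            "cop": [
                [None if not np.isfinite(v) else round(float(v), 6) for v in row]
                for row in self.cop
            ],
            "events": {k: int(v) for k, v in self.events.items()},
            "step_windows": [[int(a), int(b)] for a, b in self.step_windows],
            "phases": {k: [int(a), int(b)] for k, (a, b) in self.phases.items()},
        }


def _row_layout(insole_size: str) -> list[tuple[float, float, float, int]]:
    """Per sensor row: (center_y, row_height, usable_halfwidth, n_cells)."""
    length, _ = geometry.size_dims(insole_size)
    u0, u1 = _ROW_SPAN
    du = (u1 - u0) / _N_ROWS
    rows = []
    for r in range(_N_ROWS):
        uc = u0 + (r + 0.5) * du
        yc = uc * length
        dy = du * length
        ys = np.linspace(yc - dy / 2, yc + dy / 2, 9)
        hmin = float(np.min(np.asarray(geometry.halfwidth(ys, insole_size))))
        rows.append((yc, dy, max(hmin - 0.5, 1.0)))
    # cell counts per row by largest-remainder apportionment of the usable
    # half-widths, so wider bands get more cells and the total is exactly 99
    weights = np.array([hw for _, _, hw in rows])
    quota = _N_CELLS * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for idx in np.argsort(-remainder)[: _N_CELLS - counts.sum()]:
        counts[idx] += 1
    return [(yc, dy, hw, int(n)) for (yc, dy, hw), n in zip(rows, counts)]


def generate_template(insole_size: str, cell_mode: str = "tiled") -> list[SensorGeometry]:
    """Deterministic 99-cell experimental sensor grid for one insole size.

    ``cell_mode="tiled"``: rectangular cells sized to tile the footprint
    band-by-band (the physically consistent reading of a 99-cell in-shoe
    grid covering the insole surface).  ``cell_mode="nominal5mm"``: the same
    cell centers with nominal 5 x 5 mm active areas.
    """
    geometry.validate_size(insole_size)
    if cell_mode not in ("tiled", "nominal5mm"):
        raise ValueError(f"unknown cell_mode {cell_mode!r}")
    _, width = geometry.size_dims(insole_size)
    sensors: list[SensorGeometry] = []
    sid = 0
    for yc, dy, hw, n in _row_layout(insole_size):
        span = 2.0 * hw
        cw = span / n
        for i in range(n):
            cx = 0.5 * width - hw + (i + 0.5) * cw
            # 1 um separation keeps abutting cells strictly disjoint under
            # floating-point center/size arithmetic
            w, h = (cw - 1e-6, dy - 1e-6) if cell_mode == "tiled" else (5.0, 5.0)
            sensors.append(
                SensorGeometry(
                    sensor_id=sid,
                    center_x=cx,
                    center_y=yc,
                    width=w,
                    height=h,
                    region=geometry.region_of(cx, yc, insole_size),
                )
            )
            sid += 1
    assert len(sensors) == _N_CELLS
    return sensors


class BlobField:
    """Discrete Gaussian blob basis over a sensor grid.

    ``pressures = load[:, None] * (weights @ Gn)`` yields Σ p·A == load
    exactly, and the analytic COP is ``weights @ centroids``.
    """

    def __init__(
        self,
        sensors: list[SensorGeometry],
        insole_size: str,
        blob_widths: dict[str, float] | None = None,
    ):
        length, width = geometry.size_dims(insole_size)
        centers = np.array([[s.center_x, s.center_y] for s in sensors])
        areas = np.array([s.area_mm2 for s in sensors])
        widths = dict(blob_widths or {})
        Gn = np.zeros((len(_BLOB_ORDER), len(sensors)))
        psum = np.zeros(len(_BLOB_ORDER))
        pcentroids = np.zeros((len(_BLOB_ORDER), 2))
        for b, name in enumerate(_BLOB_ORDER):
            fx, fy, sigma = ANATOMY[name]
            sigma = widths.get(name, sigma)
            if sigma <= 0:
                raise ValueError(f"blob width for {name} must be > 0")
            mu = np.array([fx * width, fy * length])
            g = np.exp(-np.sum((centers - mu) ** 2, axis=1) / (2.0 * sigma**2))
            integral = float(np.sum(g * areas))
            Gn[b] = g / integral
            # per-blob pressure sum and pressure-weighted center, for the
            # exact discrete COP of the composite field
            psum[b] = float(np.sum(Gn[b]))
            pcentroids[b] = (centers * Gn[b][:, None]).sum(axis=0) / psum[b]
        self.Gn = Gn
        self.psum = psum
        self.pcentroids = pcentroids
        self.areas = areas

    def pressures(self, load: np.ndarray, weights: np.ndarray) -> np.ndarray:
        return load[:, None] * (weights @ self.Gn)

    def cop(self, load: np.ndarray, weights: np.ndarray) -> np.ndarray:
        """Exact pressure-weighted centroid of the composite discrete field:
        COP(t) = Σ_b w_tb S_b c_b / Σ_b w_tb S_b with S_b the blob's
        pressure sum and c_b its pressure-weighted center."""
        num = (weights * self.psum[None, :]) @ self.pcentroids
        den = weights @ self.psum
        with np.errstate(invalid="ignore", divide="ignore"):
            cop = num / den[:, None]
        cop[(load <= 0) | (den <= 0)] = np.nan
        return cop


def _hump(tau: np.ndarray, center: float, width: float) -> np.ndarray:
    """cos^2 window of total width ``width`` centered at ``center``."""
    z = (np.asarray(tau, dtype=float) - center) / width
    return np.where(np.abs(z) < 0.5, np.cos(np.pi * z) ** 2, 0.0)


def _normalize_weights(raw: np.ndarray) -> np.ndarray:
    total = raw.sum(axis=1, keepdims=True)
    safe = np.where(total > 0, total, 1.0)
    return raw / safe


def _blob_index(name: str) -> int:
    return _BLOB_ORDER.index(name)


# -- gait ------------------------------------------------------------------

# (blob, relative amplitude, window center, window width) over stance time
_GAIT_WINDOWS = (
    ("heel", 1.00, 0.18, 0.40),
    ("arch_lateral", 0.25, 0.45, 0.40),
    ("met_medial", 0.80, 0.72, 0.45),
    ("met_central", 1.00, 0.70, 0.45),
    ("met_lateral", 0.70, 0.62, 0.45),
    ("hallux", 0.90, 0.88, 0.30),
    ("toes_lateral", 0.25, 0.85, 0.30),
)

_ENV_GRID = np.linspace(0.0, 1.0, 4001)
_ENV_MAX = float(np.max(np.sin(np.pi * _ENV_GRID) + 0.2 * np.sin(3 * np.pi * _ENV_GRID)))


def _gait_envelope(tau: np.ndarray) -> np.ndarray:
    """Normalized double-hump vertical load shape of stance."""
    return (np.sin(np.pi * tau) + 0.2 * np.sin(3 * np.pi * tau)) / _ENV_MAX


def _stance_weights(tau: np.ndarray) -> np.ndarray:
    raw = np.zeros((len(tau), len(_BLOB_ORDER)))
    for name, amp, center, width in _GAIT_WINDOWS:
        raw[:, _blob_index(name)] = amp * _hump(tau, center, width)
    return _normalize_weights(raw)


def _make_recording(
    params: TrialParams,
    sensors: list[SensorGeometry],
    pressures: np.ndarray,
) -> PressureRecording:
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        pressures = pressures + rng.normal(0.0, params.noise_sd, pressures.shape)
        pressures = np.clip(pressures, 0.0, None)
    return PressureRecording(
        sensors=sensors,
        pressures=pressures,
        fs=params.fs,
        insole_size=params.insole_size,
        side=params.side,
        task=params.task,
        total_surface_mm2=geometry.total_surface_mm2(params.insole_size),
        body_weight_N=params.body_weight_N,
    )


def generate_gait_trial(
    params: TrialParams,
) -> tuple[PressureRecording, MarkerTrajectory, TrialGroundTruth]:
    """Walking trial: ``n_steps`` stance phases with a posterior->anterior
    rolling load (heel strike -> loading -> push-off), zero-pressure swings,
    and a heel-marker height trace whose minima sit on the stance windows."""
    if params.task != "gait":
        raise ValueError("generate_gait_trial requires task='gait'")
    fs = params.fs
    n_stance = max(int(round(0.65 * params.duration_scale * fs)), 8)
    n_swing = max(int(round(0.40 * params.duration_scale * fs)), 8)
    n_lead = int(round(0.25 * fs))
    n_total = n_lead + params.n_steps * (n_stance + n_swing)

    sensors = generate_template(params.insole_size, params.cell_mode)
    fld = BlobField(sensors, params.insole_size, dict(params.blob_widths or ()))

    load = np.zeros(n_total)
    weights = np.zeros((n_total, len(_BLOB_ORDER)))
    heel_z = np.full(n_total, 40.0)
    heel_z[:n_lead] = np.linspace(40.0, 2.0, max(n_lead, 1), endpoint=False)

    tau = (np.arange(n_stance) + 0.5) / n_stance
    stance_w = _stance_weights(tau)
    stance_env = params.peak * _gait_envelope(tau)

    step_windows = []
    ic_frames, to_frames = [], []
    for k in range(params.n_steps):
        start = n_lead + k * (n_stance + n_swing)
        end = start + n_stance
        load[start:end] = stance_env
        weights[start:end] = stance_w
        heel_z[start:end] = 2.0
        s = (np.arange(n_swing) + 0.5) / n_swing
        heel_z[end: end + n_swing] = 2.0 + 55.0 * np.sin(np.pi * s)
        step_windows.append((start, end))
        ic_frames.append(start)
        to_frames.append(end)

    pressures = fld.pressures(load, weights)
    rec = _make_recording(params, sensors, pressures)
    marker_label = "heel_left" if params.side == "left" else "heel_right"
    marker = MarkerTrajectory(
        label=marker_label,
        positions=np.column_stack([np.zeros(n_total), np.zeros(n_total), heel_z]),
        fs=fs,
    )
    gt = TrialGroundTruth(
        task="gait",
        fs=fs,
        load=load,
        cop=fld.cop(load, weights),
        events={"first_ic": ic_frames[0], "last_to": to_frames[-1]},
        step_windows=step_windows,
    )
    return rec, marker, gt


# -- drop landing ----------------------------------------------------------

# before release the subject is weight-shifted as far forward as possible,
# so the standing window is forefoot- and hallux-dominant
_DROP_STAND_W = {
    "heel": 0.30, "arch_lateral": 0.05, "met_medial": 0.12, "met_central": 0.22,
    "met_lateral": 0.13, "hallux": 0.15, "toes_lateral": 0.03,
}
_DROP_IMPACT_W = {
    "heel": 0.20, "arch_lateral": 0.05, "met_medial": 0.15, "met_central": 0.30,
    "met_lateral": 0.15, "hallux": 0.10, "toes_lateral": 0.05,
}


def _weights_row(mapping: dict[str, float]) -> np.ndarray:
    row = np.zeros(len(_BLOB_ORDER))
    for name, v in mapping.items():
        row[_blob_index(name)] = v
    return row / row.sum()


def generate_drop_trial(
    params: TrialParams,
) -> tuple[PressureRecording, MarkerTrajectory, TrialGroundTruth]:
    """Single-leg drop landing from a 32 cm platform: a loaded standing
    window, an airborne window of zero pressure, then a short-rise impact
    spike (amplitude above the gait peak) settling over about two seconds."""
    if params.task != "drop":
        raise ValueError("generate_drop_trial requires task='drop'")
    fs = params.fs
    n_stand = int(round(1.0 * fs))
    n_air = max(int(round(0.45 * params.duration_scale * fs)), 4)
    n_settle = int(round(2.5 * params.duration_scale * fs))
    n_total = n_stand + n_air + n_settle

    sensors = generate_template(params.insole_size, params.cell_mode)
    fld = BlobField(sensors, params.insole_size, dict(params.blob_widths or ()))

    load = np.zeros(n_total)
    weights = np.zeros((n_total, len(_BLOB_ORDER)))
    stand_load = 50.0 * params.amplitude_scale
    load[:n_stand] = stand_load
    weights[:n_stand] = _weights_row(_DROP_STAND_W)

    landing = n_stand + n_air
    n_rise = 5
    t_after = np.arange(n_total - landing) / fs
    settle_level = 100.0 * params.amplitude_scale
    impact = settle_level + (params.peak - settle_level) * np.exp(-t_after / 0.15)
    rise = np.sin(0.5 * np.pi * (np.arange(1, n_rise + 1) / n_rise))
    impact[:n_rise] *= rise
    load[landing:] = impact

    blend = np.clip(t_after / 0.5, 0.0, 1.0)[:, None]
    weights[landing:] = (1 - blend) * _weights_row(_DROP_IMPACT_W) + blend * _weights_row(
        _DROP_STAND_W
    )

    heel_z = np.empty(n_total)
    heel_z[:n_stand] = 320.0
    fall = (np.arange(n_air) + 1) / n_air
    heel_z[n_stand:landing] = 320.0 * (1 - fall**2)
    heel_z[landing:] = 5.0

    pressures = fld.pressures(load, weights)
    rec = _make_recording(params, sensors, pressures)
    marker_label = "heel_left" if params.side == "left" else "heel_right"
    marker = MarkerTrajectory(
        label=marker_label,
        positions=np.column_stack([np.zeros(n_total), np.zeros(n_total), heel_z]),
        fs=fs,
    )
    gt = TrialGroundTruth(
        task="drop",
        fs=fs,
        load=load,
        cop=fld.cop(load, weights),
        events={
            "leave": n_stand,
            "landing": landing,
            "end": min(landing + int(round(2 * fs)), n_total),
        },
    )
    return rec, marker, gt


# -- lifting ---------------------------------------------------------------

_LIFT_POSTERIOR_W = {
    "heel": 0.52, "arch_lateral": 0.12, "met_medial": 0.08, "met_central": 0.18,
    "met_lateral": 0.08, "hallux": 0.02, "toes_lateral": 0.0,
}
_LIFT_ANTERIOR_W = {
    "heel": 0.30, "arch_lateral": 0.10, "met_medial": 0.14, "met_central": 0.28,
    "met_lateral": 0.12, "hallux": 0.05, "toes_lateral": 0.01,
}


def _cos_ramp(z0: float, z1: float, n: int) -> np.ndarray:
    s = np.arange(n) / n
    return z0 + (z1 - z0) * (1 - np.cos(np.pi * s)) / 2


def generate_lifting_trial(
    params: TrialParams,
) -> tuple[PressureRecording, MarkerTrajectory, TrialGroundTruth]:
    """Squat lift: quasi-static load with anterior-posterior COP shifts
    synchronized to an L5 height trace going down-up-(plateau)-down-up; the
    leave-and-peak plateau is emitted but labelled excluded from analysis."""
    if params.task != "lifting":
        raise ValueError("generate_lifting_trial requires task='lifting'")
    fs = params.fs
    d = params.duration_scale
    n_lead = int(round(0.5 * fs))
    n_ud = int(round(1.2 * d * fs))
    n_la = int(round(1.5 * d * fs))
    n_plateau = int(round(1.0 * d * fs))
    n_ld = int(round(1.5 * d * fs))
    n_ua = int(round(1.2 * d * fs))
    n_tail = int(round(0.5 * fs))

    z_top, z_bottom = 1000.0, 600.0
    z = np.concatenate(
        [
            np.full(n_lead, z_top),
            _cos_ramp(z_top, z_bottom, n_ud),
            _cos_ramp(z_bottom, z_top, n_la),
            np.full(n_plateau, z_top),
            _cos_ramp(z_top, z_bottom, n_ld),
            _cos_ramp(z_bottom, z_top, n_ua),
            np.full(n_tail, z_top),
        ]
    )
    n_total = len(z)
    m1 = n_lead + n_ud
    p_start = m1 + n_la
    p_end = p_start + n_plateau
    m2 = p_end + n_ld
    ua_end = m2 + n_ua

    # load share carried by one insole: half body weight plus half the
    # lifted mass while the weight is in the hands (LA and LD phases)
    loaded = np.zeros(n_total)
    n_ramp = max(int(round(0.3 * fs)), 2)
    loaded[m1:p_start] = 1.0
    loaded[m1: m1 + n_ramp] = np.linspace(0, 1, n_ramp, endpoint=False)
    loaded[p_start: p_start + n_ramp] = np.linspace(1, 0, n_ramp, endpoint=False)
    loaded[p_start + n_ramp: p_end] = 0.0
    loaded[p_end - n_ramp: p_end] = np.linspace(0, 1, n_ramp, endpoint=False)
    loaded[p_end:m2] = 1.0
    loaded[m2: m2 + n_ramp] = np.linspace(1, 0, n_ramp, endpoint=False)

    base = params.peak  # %BW carried by one insole while standing
    load = base + (params.load_pct_bw / 2.0) * params.amplitude_scale * loaded

    depth = (z_top - z) / (z_top - z_bottom)
    alpha = np.clip(0.6 * depth + 0.4 * loaded, 0.0, 1.0)[:, None]
    w_post = _weights_row(_LIFT_POSTERIOR_W)
    w_ant = _weights_row(_LIFT_ANTERIOR_W)
    weights = (1 - alpha) * w_post + alpha * w_ant

    sensors = generate_template(params.insole_size, params.cell_mode)
    fld = BlobField(sensors, params.insole_size, dict(params.blob_widths or ()))
    pressures = fld.pressures(load, weights)
    rec = _make_recording(params, sensors, pressures)
    marker = MarkerTrajectory(
        label="L5",
        positions=np.column_stack([np.zeros(n_total), np.zeros(n_total), z]),
        fs=fs,
    )
    gt = TrialGroundTruth(
        task="lifting",
        fs=fs,
        load=load,
        cop=fld.cop(load, weights),
        events={"min1": m1, "plateau_start": p_start, "plateau_end": p_end, "min2": m2},
        phases={
            "UD": (n_lead, m1),
            "LA": (m1, p_start),
            "leave_and_peak": (p_start, p_end),
            "LD": (p_end, m2),
            "UA": (m2, ua_end),
        },
    )
    return rec, marker, gt


_GENERATORS = {
    "gait": generate_gait_trial,
    "drop": generate_drop_trial,
    "lifting": generate_lifting_trial,
}


def generate_trial(params: TrialParams):
    return _GENERATORS[params.task](params)


def generate_baseline(params: TrialParams, duration_s: float = 1.0) -> PressureRecording:
    """Unloaded recording (noise only) used for the zeroing process."""
    sensors = generate_template(params.insole_size, params.cell_mode)
    n = int(round(duration_s * params.fs))
    pressures = np.zeros((n, len(sensors)))
    baseline_params = dataclasses.replace(params, seed=params.seed + 101)
    return _make_recording(baseline_params, sensors, pressures)


@dataclass
class CohortTrial:
    subject: int
    trial: int
    side: str
    params: TrialParams
    recording: PressureRecording
    marker: MarkerTrajectory
    ground_truth: TrialGroundTruth
    baseline: PressureRecording


def generate_cohort(
    task: str,
    n_subjects: int,
    seed: int,
    out_dir: str | Path | None = None,
    trials_per_subject: int = 3,
    insole_size: str | None = None,
    noise_sd: float = 0.001,
    cell_mode: str = "tiled",
) -> list[CohortTrial]:
    """Cohort of subjects with +/-10 % uniform jitter on amplitudes, timing
    and body weight; left and right trials per subject.  Fully determined by
    ``seed``; optionally written to ``out_dir`` with a manifest."""
    if n_subjects <= 0:
        raise ValueError("n_subjects must be > 0")
    rng = np.random.default_rng(seed)
    trials: list[CohortTrial] = []
    sizes = geometry.INSOLE_SIZES
    for subj in range(n_subjects):
        size = insole_size or sizes[subj % len(sizes)]
        amp = 1.0 + rng.uniform(-0.10, 0.10)
        dur = 1.0 + rng.uniform(-0.10, 0.10)
        bw = 675.0 * (1.0 + rng.uniform(-0.10, 0.10))
        for t in range(trials_per_subject):
            for side in ("left", "right"):
                trial_seed = int(rng.integers(0, 2**31 - 1))
                params = TrialParams(
                    task=task,
                    insole_size=size,
                    side=side,
                    body_weight_N=bw,
                    amplitude_scale=amp,
                    duration_scale=dur,
                    noise_sd=noise_sd,
                    seed=trial_seed,
                    cell_mode=cell_mode,
                )
                rec, marker, gt = generate_trial(params)
                baseline = generate_baseline(params)
                trials.append(
                    CohortTrial(subj, t, side, params, rec, marker, gt, baseline)
                )
    if out_dir is not None:
        _write_cohort(Path(out_dir), task, n_subjects, seed, trials_per_subject, trials)
    return trials


def _write_cohort(
    out_dir: Path,
    task: str,
    n_subjects: int,
    seed: int,
    trials_per_subject: int,
    trials: list[CohortTrial],
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for ct in trials:
        subj_dir = out_dir / f"subject_{ct.subject:02d}"
        subj_dir.mkdir(exist_ok=True)
        stem = f"{task}_t{ct.trial}_{ct.side}"
        files.append(str(io.write_recording(ct.recording, subj_dir / f"{stem}.tsv").relative_to(out_dir)))
        files.append(str(io.write_marker(ct.marker, subj_dir / f"{stem}_marker.csv").relative_to(out_dir)))
        gt_path = subj_dir / f"{stem}_ground_truth.json"
        gt_path.write_text(json.dumps(ct.ground_truth.to_dict(), sort_keys=True))
        files.append(str(gt_path.relative_to(out_dir)))
    manifest = {
        "task": task,
        "n_subjects": n_subjects,
        "seed": seed,
        "trials_per_subject": trials_per_subject,
        "files": sorted(files),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
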