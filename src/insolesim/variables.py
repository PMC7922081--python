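"""Plantar-pressure variable set computed from any pressure recording.

Seven variables per frame: Peak Pressure, Mean Pressure, vertical GRF,
COP (two formulations), dCOP and Contact Area.  All series except the COP
are low-pass filtered with a zero-phase 3rd-order Butterworth at a cutoff
of 1/8 of the sampling frequency.

Two mean-pressure conventions are available:

* ``"surface"`` (default in :func:`compute_all`): vertical load divided by
  the total insole surface, i.e. the spatial mean over the whole insole.
  This is the convention under which a reduced-coverage layout scales Mean
  Pressure exactly like GRF — the behaviour seen in validation studies of
  reduced-sensor insoles against full-coverage systems.
* ``"contact"`` (the :func:`mean_pressure` function): arithmetic mean over
  the sensors in contact (pressure above threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .core import PressureRecording, ValidationError, ZeroingProfile

FILTER_ORDER = 3
#: digital normalized cutoff: (fs/8) / (fs/2); independent of fs
_WN = 0.25
_B, _A = butter(FILTER_ORDER, _WN)
_PADLEN = 3 * max(len(_B), len(_A))  # scipy filtfilt default


def butterworth_lowpass(series: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase (forward-backward) 3rd-order Butterworth low-pass at
    fc = fs/8, with reflected edge padding."""
    if fs <= 0:
        raise ValueError("fs must be > 0")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if len(x) <= _PADLEN:
        raise ValueError(
            f"series of length {len(x)} is shorter than the filter padding "
            f"requirement ({_PADLEN + 1} samples)"
        )
    return filtfilt(_B, _A, x)


def peak_pressure(rec: PressureRecording) -> np.ndarray:
    """Per-frame maximum pressure over sensors (%BW/mm^2)."""
    if rec.n_frames == 0:
        return np.empty(0)
    return rec.pressures.max(axis=1)


def _threshold_vector(rec: PressureRecording, contact_threshold) -> np.ndarray:
    if contact_threshold is None:
        # fallback: 0.1% of the trial's maximum pressure
        peak = float(rec.pressures.max()) if rec.pressures.size else 0.0
        return np.full(rec.n_sensors, 1e-3 * peak)
    if isinstance(contact_threshold, ZeroingProfile):
        thr = contact_threshold.thresholds
        if len(thr) != rec.n_sensors:
            raise ValidationError(
                "zeroing profile length does not match the recording"
            )
        return thr
    return np.full(rec.n_sensors, float(contact_threshold))


def contact_mask(rec: PressureRecording, contact_threshold=None) -> np.ndarray:
    """Boolean [frames x sensors] mask of sensors in contact."""
    thr = _threshold_vector(rec, contact_threshold)
    return rec.pressures > thr[None, :]


def mean_pressure(rec: PressureRecording, contact_threshold=None) -> np.ndarray:
    """Per-frame arithmetic mean over sensors in contact; 0 when none."""
    mask = contact_mask(rec, contact_threshold)
    n_contact = mask.sum(axis=1)
    total = np.where(mask, rec.pressures, 0.0).sum(axis=1)
    return np.divide(total, n_contact, out=np.zeros(rec.n_frames), where=n_contact > 0)


def grf(rec: PressureRecording) -> np.ndarray:
    """Per-frame vertical ground reaction force Σ p_i·A_i (%BW)."""
    return rec.pressures @ rec.sensor_areas


def cop_eq1(rec: PressureRecording) -> tuple[np.ndarray, np.ndarray]:
    """Pressure-weighted mean of sensor centers per frame (mm).

    X = Σ X_i V_i / Σ V_i and likewise for Y; frames with no load are NaN.
    """
    centers = rec.sensor_centers
    v_sum = rec.pressures.sum(axis=1)
    with np.errstate(invalid="ignore"):
        x = np.where(v_sum > 0, rec.pressures @ centers[:, 0] / v_sum, np.nan)
        y = np.where(v_sum > 0, rec.pressures @ centers[:, 1] / v_sum, np.nan)
    return x, y


def cop_eq2(rec: PressureRecording) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-average COP with per-sensor weights p_i(t) normalized by the
    sensor's own temporal peak; sensors that never load are excluded.  The
    per-sensor COP coordinate is the sensor's center."""
    centers = rec.sensor_centers
    temporal_peak = rec.pressures.max(axis=0) if rec.n_frames else np.zeros(rec.n_sensors)
    active = temporal_peak > 0
    if not np.any(active):
        nan = np.full(rec.n_frames, np.nan)
        return nan, nan.copy()
    w = rec.pressures[:, active] / temporal_peak[active][None, :]
    w_sum = w.sum(axis=1)
    with np.errstate(invalid="ignore"):
        x = np.where(w_sum > 0, w @ centers[active, 0] / w_sum, np.nan)
        y = np.where(w_sum > 0, w @ centers[active, 1] / w_sum, np.nan)
    return x, y


def dcop(cop_x: np.ndarray, cop_y: np.ndarray, rec: PressureRecording) -> np.ndarray:
    """Distance from the COP to the coordinate origin, normalized by the
    square root of the total insole surface (dimensionless)."""
    return np.hypot(cop_x, cop_y) / np.sqrt(rec.total_surface_mm2)


def contact_area(rec: PressureRecording, contact_threshold=None) -> np.ndarray:
    """Per-frame loaded sensor area as % of the total insole surface."""
    mask = contact_mask(rec, contact_threshold)
    return 100.0 * (mask @ rec.sensor_areas) / rec.total_surface_mm2


def _filter_with_gaps(series: np.ndarray, fs: float) -> np.ndarray:
    """Filter a series that may contain NaN stretches: fill by linear
    interpolation (edge hold), filter, then restore the NaNs."""
    x = np.asarray(series, dtype=float)
    nan = ~np.isfinite(x)
    if nan.all():
        return x.copy()
    if nan.any():
        idx = np.arange(len(x))
        filled = np.interp(idx, idx[~nan], x[~nan])
    else:
        filled = x
    out = butterworth_lowpass(filled, fs)
    out[nan] = np.nan
    return out


@dataclass
class VariableSet:
    """Time series of the standard plantar-pressure variables for one trial."""

    peak_pressure: np.ndarray  # %BW/mm^2
    mean_pressure: np.ndarray  # %BW/mm^2
    grf: np.ndarray  # %BW
    cop1_x: np.ndarray  # mm, medial-lateral
    cop1_y: np.ndarray  # mm, anterior-posterior
    cop2_x: np.ndarray
    cop2_y: np.ndarray
    dcop: np.ndarray  # fraction of sqrt(total surface)
    contact_area: np.ndarray  # % of total surface
    fs: float
    filtered: bool

    #: the seven compared variables -> VariableSet attribute
    COMPARED: tuple[tuple[str, str], ...] = (
        ("peak_pressure", "peak_pressure"),
        ("mean_pressure", "mean_pressure"),
        ("grf", "grf"),
        ("dcop", "dcop"),
        ("cop_ml", "cop1_x"),
        ("cop_ap", "cop1_y"),
        ("contact_area", "contact_area"),
    )

    def __post_init__(self) -> None:
        lengths = {
            len(getattr(self, name))
            for name in (
                "peak_pressure", "mean_pressure", "grf", "cop1_x", "cop1_y",
                "cop2_x", "cop2_y", "dcop", "contact_area",
            )
        }
        if len(lengths) != 1:
            raise ValidationError("all variable series must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.grf)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": np.arange(self.n_frames) / self.fs,
                "peak_pressure": self.peak_pressure,
                "mean_pressure": self.mean_pressure,
                "grf": self.grf,
                "cop1_x": self.cop1_x,
                "cop1_y": self.cop1_y,
                "cop2_x": self.cop2_x,
                "cop2_y": self.cop2_y,
                "dcop": self.dcop,
                "contact_area": self.contact_area,
            }
        )

    def crop(self, start: int, end: int) -> "VariableSet":
        kw = {
            name: getattr(self, name)[start:end]
            for name in (
                "peak_pressure", "mean_pressure", "grf", "cop1_x", "cop1_y",
                "cop2_x", "cop2_y", "dcop", "contact_area",
            )
        }
        return VariableSet(fs=self.fs, filtered=self.filtered, **kw)

    def series(self, variable: str) -> np.ndarray:
        attr = dict(self.COMPARED)[variable]
        return getattr(self, attr)


def compute_all(
    rec: PressureRecording,
    contact_threshold=None,
    filtered: bool = True,
    mean_policy: str = "surface",
) -> VariableSet:
    """Compute the full variable set; all series except the COP are low-pass
    filtered when ``filtered`` is true."""
    if mean_policy not in ("surface", "contact"):
        raise ValueError(f"unknown mean_policy {mean_policy!r}")
    pk = peak_pressure(rec)
    load = grf(rec)
    if mean_policy == "surface":
        mp = load / rec.total_surface_mm2
    else:
        mp = mean_pressure(rec, contact_threshold)
    c1x, c1y = cop_eq1(rec)
    c2x, c2y = cop_eq2(rec)
    dc = dcop(c1x, c1y, rec)
    ca = contact_area(rec, contact_threshold)
    if filtered:
        pk = _filter_with_gaps(pk, rec.fs)
        mp = _filter_with_gaps(mp, rec.fs)
        load = _filter_with_gaps(load, rec.fs)
        dc = _filter_with_gaps(dc, rec.fs)
        ca = _filter_with_gaps(ca, rec.fs)
    return VariableSet(
        peak_pressure=pk,
        mean_pressure=mp,
        grf=load,
        cop1_x=c1x,
        cop1_y=c1y,
        cop2_x=c2x,
        cop2_y=c2y,
        dcop=dc,
        contact_area=ca,
        fs=rec.fs,
        filtered=filtered,
    )
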