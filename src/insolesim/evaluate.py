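"""Comparison of experimental vs simulated variable sets.

The agreement metric is the root-mean-square error expressed as a
percentage of the gold-standard (experimental) series' peak magnitude:

    RMSE% = 100 * sqrt(mean_t (a_t - s_t)^2) / max_t |a_t|

Loss-of-data maps give, per experimental sensor location, the percentage of
the experimental peak pressure not captured by the reduced layout:
100 * (exp - sim) / exp at covered locations, 100 at uncovered ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PressureRecording, SensorGeometry, ValidationError
from .simulate import GroupMap
from .variables import VariableSet

VARIABLES = tuple(name for name, _ in VariableSet.COMPARED)


def rmse_percent(observed: np.ndarray, expected: np.ndarray) -> float:
    """RMSE of (observed - expected) as % of the observed series' peak.

    ``observed`` is the gold standard; frames where either series is missing
    (NaN) are excluded.
    """
    a = np.asarray(observed, dtype=float)
    s = np.asarray(expected, dtype=float)
    if a.shape != s.shape:
        raise ValidationError("series must have equal length")
    mask = np.isfinite(a) & np.isfinite(s)
    if not mask.any():
        raise ValidationError("no overlapping finite frames to compare")
    peak = float(np.max(np.abs(a[mask])))
    if peak <= 0:
        raise ValidationError("experimental series peak is zero; RMSE% undefined")
    return 100.0 * float(np.sqrt(np.mean((a[mask] - s[mask]) ** 2))) / peak


@dataclass
class ComparisonReport:
    """Per-variable summary of one experimental/simulated trial pair."""

    task: str
    insole_size: str
    phase: str
    stats: pd.DataFrame  # index: variable; exp_mean, exp_sd, sim_mean, sim_sd, rmse_percent
    n_trials: int = 1

    def rmse(self, variable: str) -> float:
        return float(self.stats.loc[variable, "rmse_percent"])


def compare_variable_sets(
    exp: VariableSet,
    sim: VariableSet,
    task: str = "gait",
    insole_size: str = "38-39",
    phase: str = "all",
) -> ComparisonReport:
    """RMSE% and mean +/- SD of every compared variable on aligned frames."""
    if exp.n_frames != sim.n_frames:
        raise ValidationError("variable sets must cover the same frames")
    rows = {}
    for variable in VARIABLES:
        a = exp.series(variable)
        s = sim.series(variable)
        mask = np.isfinite(a) & np.isfinite(s)
        rows[variable] = {
            "exp_mean": float(np.mean(a[mask])) if mask.any() else np.nan,
            "exp_sd": float(np.std(a[mask], ddof=0)) if mask.any() else np.nan,
            "sim_mean": float(np.mean(s[mask])) if mask.any() else np.nan,
            "sim_sd": float(np.std(s[mask], ddof=0)) if mask.any() else np.nan,
            "rmse_percent": rmse_percent(a, s),
        }
    stats = pd.DataFrame.from_dict(rows, orient="index").loc[list(VARIABLES)]
    return ComparisonReport(
        task=task, insole_size=insole_size, phase=phase, stats=stats
    )


@dataclass
class LossMap:
    """Loss-of-data % at every experimental sensor location."""

    sensors: list[SensorGeometry]
    loss_percent: np.ndarray  # per experimental sensor
    uncovered: np.ndarray  # bool per experimental sensor
    exp_peak: np.ndarray
    sim_peak: np.ndarray  # NaN at uncovered locations

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sensor_id": [s.sensor_id for s in self.sensors],
                "x": [s.center_x for s in self.sensors],
                "y": [s.center_y for s in self.sensors],
                "exp_peak": self.exp_peak,
                "sim_peak": self.sim_peak,
                "loss_percent": self.loss_percent,
                "uncovered": self.uncovered,
            }
        )


def loss_of_data_map(
    exp_peak_map: np.ndarray,
    sim_recording: PressureRecording,
    gmap: GroupMap,
    exp_sensors: list[SensorGeometry],
) -> LossMap:
    """Loss of data per experimental sensor from peak-pressure maps.

    ``exp_peak_map`` holds the per-sensor peak-over-time experimental
    pressures; each covered sensor is compared with the temporal peak of the
    simulated sensor its group feeds; uncovered sensors lose 100 %.
    """
    exp_peak_map = np.asarray(exp_peak_map, dtype=float)
    if len(exp_peak_map) != len(exp_sensors):
        raise ValidationError("peak map length does not match sensor geometry")
    sim_peaks = {
        s.sensor_id: float(sim_recording.pressures[:, j].max())
        if sim_recording.n_frames
        else 0.0
        for j, s in enumerate(sim_recording.sensors)
    }
    member_to_sim: dict[int, int] = {}
    for sim_id, members in gmap.groups.items():
        for m in members:
            member_to_sim[m] = sim_id

    n = len(exp_sensors)
    loss = np.empty(n)
    uncovered = np.zeros(n, dtype=bool)
    sim_peak_at = np.full(n, np.nan)
    for i, sensor in enumerate(exp_sensors):
        exp_val = exp_peak_map[i]
        sim_id = member_to_sim.get(sensor.sensor_id)
        if sim_id is None:
            uncovered[i] = True
            loss[i] = 100.0
            continue
        sim_val = sim_peaks[sim_id]
        sim_peak_at[i] = sim_val
        if exp_val == 0:
            loss[i] = 0.0
        else:
            loss[i] = 100.0 * (exp_val - sim_val) / exp_val
    return LossMap(
        sensors=list(exp_sensors),
        loss_percent=loss,
        uncovered=uncovered,
        exp_peak=exp_peak_map,
        sim_peak=sim_peak_at,
    )


def _resample(series: np.ndarray, n_points: int) -> np.ndarray:
    """Resample onto a 0-100 % segment-normalized base, NaN-aware."""
    x = np.asarray(series, dtype=float)
    if len(x) == 0:
        return np.full(n_points, np.nan)
    src = np.linspace(0.0, 1.0, len(x))
    dst = np.linspace(0.0, 1.0, n_points)
    ok = np.isfinite(x)
    if not ok.any():
        return np.full(n_points, np.nan)
    out = np.interp(dst, src[ok], x[ok])
    # frames interpolated across all-NaN stretches stay NaN
    nearest = np.interp(dst, src, ok.astype(float))
    out[nearest < 0.5] = np.nan
    return out


def average_bilateral(left: VariableSet, right: VariableSet, n_points: int = 101) -> VariableSet:
    """Average left and right variable sets after resampling both onto a
    common 101-point (0-100 % of segment) base."""
    fields = (
        "peak_pressure", "mean_pressure", "grf", "cop1_x", "cop1_y",
        "cop2_x", "cop2_y", "dcop", "contact_area",
    )
    kw = {}
    for name in fields:
        a = _resample(getattr(left, name), n_points)
        b = _resample(getattr(right, name), n_points)
        kw[name] = 0.5 * (a + b)
    return VariableSet(
        fs=0.5 * (left.fs + right.fs), filtered=left.filtered and right.filtered, **kw
    )


def average_reports(left: ComparisonReport, right: ComparisonReport) -> ComparisonReport:
    """Element-wise mean of two trial reports (bilateral averaging)."""
    if (left.task, left.insole_size, left.phase) != (
        right.task, right.insole_size, right.phase,
    ):
        raise ValidationError("cannot average reports from different groups")
    return ComparisonReport(
        task=left.task,
        insole_size=left.insole_size,
        phase=left.phase,
        stats=(left.stats + right.stats) / 2.0,
        n_trials=left.n_trials + right.n_trials,
    )


def summarize(reports: list[ComparisonReport]) -> pd.DataFrame:
    """Aggregate trial reports into a task x size x phase table: variable-wise
    mean +/- SD of both systems and the <min-max> RMSE% range."""
    if not reports:
        raise ValidationError("no reports to summarize")
    rows = []
    for rep in reports:
        for variable in rep.stats.index:
            r = rep.stats.loc[variable]
            rows.append(
                {
                    "task": rep.task,
                    "insole_size": rep.insole_size,
                    "phase": rep.phase,
                    "variable": variable,
                    "exp_mean": r["exp_mean"],
                    "exp_sd": r["exp_sd"],
                    "sim_mean": r["sim_mean"],
                    "sim_sd": r["sim_sd"],
                    "rmse_percent": r["rmse_percent"],
                }
            )
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(["task", "insole_size", "phase", "variable"], sort=True)
        .agg(
            exp_mean=("exp_mean", "mean"),
            exp_sd=("exp_mean", "std"),
            sim_mean=("sim_mean", "mean"),
            sim_sd=("sim_mean", "std"),
            rmse_min=("rmse_percent", "min"),
            rmse_max=("rmse_percent", "max"),
            n_trials=("rmse_percent", "size"),
        )
        .reset_index()
    )
    return grouped


def summary_to_markdown(summary: pd.DataFrame) -> str:
    """Tables-style rendering: one block per task x size x phase with
    variable rows 'exp mean +/- SD | sim mean +/- SD | <min-max> RMSE%'."""
    lines = []
    for (task, size, phase), block in summary.groupby(["task", "insole_size", "phase"]):
        lines.append(f"### {task} — size {size} — phase {phase}")
        lines.append("| Variable | Gold standard | Simulated layout | RMSE % |")
        lines.append("| --- | --- | --- | --- |")
        for _, r in block.iterrows():
            exp_sd = 0.0 if np.isnan(r["exp_sd"]) else r["exp_sd"]
            sim_sd = 0.0 if np.isnan(r["sim_sd"]) else r["sim_sd"]
            lines.append(
                f"| {r['variable']} | {r['exp_mean']:.4g} ± {exp_sd:.2g} "
                f"| {r['sim_mean']:.4g} ± {sim_sd:.2g} "
                f"| <{r['rmse_min']:.3g}–{r['rmse_max']:.3g}> |"
            )
        lines.append("")
    return "\n".join(lines)


def plot_loss_map(loss_map: LossMap, path) -> None:
    """Render the loss-of-data footprint (grey-level, white = 100 % loss)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.2, 6.4))
    vals = np.clip(loss_map.loss_percent, 0, 100)
    for s, v in zip(loss_map.sensors, vals):
        grey = v / 100.0  # 0 loss -> black, 100 -> white
        ax.add_patch(
            plt.Rectangle(
                (s.center_x - s.width / 2, s.center_y - s.height / 2),
                s.width, s.height, facecolor=(grey, grey, grey), edgecolor="0.7",
                linewidth=0.2,
            )
        )
    xs = [s.center_x for s in loss_map.sensors]
    ys = [s.center_y for s in loss_map.sensors]
    ax.set_xlim(min(xs) - 15, max(xs) + 15)
    ax.set_ylim(min(ys) - 15, max(ys) + 15)
    ax.set_aspect("equal")
    ax.set_xlabel("medial–lateral (mm)")
    ax.set_ylabel("posterior–anterior (mm)")
    ax.set_title("loss of data (%)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
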