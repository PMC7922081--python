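"""End-to-end run configuration and orchestration.

``run_pipeline`` chains synthesis -> layout -> simulation -> variables ->
events -> evaluation into a run directory with a manifest; rerunning the
same configuration reproduces every numeric output bit-exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__, evaluate, events, io, layout as layout_mod, simulate, synthetic, variables
from .core import ZeroingProfile

logger = logging.getLogger("insolesim")


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    task: Literal["gait", "drop", "lifting"]
    out_dir: str
    n_subjects: int = Field(default=3, ge=1)
    trials_per_subject: int = Field(default=2, ge=1)
    seed: int = 1
    insole_size: Optional[Literal["38-39", "40-41", "42-43", "44-45"]] = None
    layout_source: Literal["default", "file", "design"] = "default"
    layout_path: Optional[str] = None
    grouping_method: Literal["k_nearest", "geometric_overlap"] = "k_nearest"
    k: int = Field(default=3, ge=1)
    filtered: bool = True
    mean_policy: Literal["surface", "contact"] = "surface"
    noise_sd: float = Field(default=0.001, ge=0.0)
    zeroing_margin: float = Field(default=events.DEFAULT_ZEROING_MARGIN, ge=0.0)
    cell_mode: Literal["tiled", "nominal5mm"] = "tiled"


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    return RunConfig(**data)


def _layout_for(config: RunConfig, size: str, cohort_recs) -> "layout_mod.InsoleLayout":
    if config.layout_source == "default":
        return layout_mod.default_layout(size)
    if config.layout_source == "file":
        if not config.layout_path:
            raise ValueError("layout_source='file' requires layout_path")
        lay = io.read_layout(config.layout_path)
        if lay.insole_size != size:
            lay = layout_mod.scale_layout(lay, size)
        return lay
    recs = [r for r in cohort_recs if r.insole_size == size]
    hist = layout_mod.peak_location_histogram(recs, mode="per_trial")
    return layout_mod.design_layout(
        hist, recs[0].sensors, layout_mod.LayoutConstraints(), insole_size=size
    )


def _analysis_segments(task, rec, marker, zp) -> list[events.TaskSegment]:
    if task == "gait":
        steps = events.detect_gait_events(rec, zp, heel_marker=marker)
        if not steps:
            return []
        return [
            events.TaskSegment(
                label="all",
                start_frame=steps[0].start_frame,
                end_frame=steps[-1].end_frame,
                source="combined",
            )
        ]
    if task == "drop":
        return [events.detect_drop_window(rec, zp)]
    return [s for s in events.detect_lifting_phases(marker) if not s.excluded]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full chain and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run started: task=%s seed=%d", config.task, config.seed)

    cohort = synthetic.generate_cohort(
        config.task,
        config.n_subjects,
        config.seed,
        out_dir=out / "recordings",
        trials_per_subject=config.trials_per_subject,
        insole_size=config.insole_size,
        noise_sd=config.noise_sd,
        cell_mode=config.cell_mode,
    )

    sizes = sorted({ct.recording.insole_size for ct in cohort})
    layouts = {
        size: _layout_for(config, size, [ct.recording for ct in cohort])
        for size in sizes
    }
    layout_dir = out / "layouts"
    layout_dir.mkdir(exist_ok=True)
    for size, lay in layouts.items():
        io.write_layout(lay, layout_dir / f"layout_{size}.json")

    reports: dict[tuple[int, int, str], list[evaluate.ComparisonReport]] = {}
    var_dir = out / "variables"
    var_dir.mkdir(exist_ok=True)
    seg_dir = out / "segments"
    seg_dir.mkdir(exist_ok=True)
    loss_dir = out / "loss_maps"
    loss_dir.mkdir(exist_ok=True)

    for ct in cohort:
        rec = ct.recording
        stem = f"s{ct.subject:02d}_t{ct.trial}_{ct.side}"
        lay = layouts[rec.insole_size]
        gmap = simulate.assign_groups(
            lay, rec.sensors, method=config.grouping_method, k=config.k
        )
        sim = simulate.simulate_recording(rec, gmap, lay)
        io.write_recording(sim, var_dir / f"{stem}_sim.tsv")

        zp = events.zeroing_thresholds(ct.baseline, margin=config.zeroing_margin)
        segments = _analysis_segments(config.task, rec, ct.marker, zp)
        (seg_dir / f"{stem}.json").write_text(
            json.dumps(
                [
                    {
                        "label": s.label,
                        "start_frame": s.start_frame,
                        "end_frame": s.end_frame,
                        "source": s.source,
                        "flags": list(s.flags),
                    }
                    for s in segments
                ],
                indent=2,
            )
            + "\n"
        )

        exp_vars = variables.compute_all(
            rec, contact_threshold=zp, filtered=config.filtered,
            mean_policy=config.mean_policy,
        )
        sim_zp = ZeroingProfile(
            thresholds=np.full(lay.n_sensors, float(np.median(zp.thresholds)))
        )
        sim_vars = variables.compute_all(
            sim, contact_threshold=sim_zp, filtered=config.filtered,
            mean_policy=config.mean_policy,
        )
        exp_vars.to_dataframe().to_csv(var_dir / f"{stem}_exp.csv", index=False)
        sim_vars.to_dataframe().to_csv(var_dir / f"{stem}_sim.csv", index=False)

        for seg in segments:
            rep = evaluate.compare_variable_sets(
                exp_vars.crop(seg.start_frame, seg.end_frame),
                sim_vars.crop(seg.start_frame, seg.end_frame),
                task=config.task,
                insole_size=rec.insole_size,
                phase=seg.label,
            )
            reports.setdefault((ct.subject, ct.trial, seg.label), []).append(rep)

        if segments:
            seg0 = segments[0]
            exp_peak = rec.pressures[seg0.start_frame: seg0.end_frame].max(axis=0)
            lm = evaluate.loss_of_data_map(
                exp_peak,
                sim.with_pressures(sim.pressures[seg0.start_frame: seg0.end_frame]),
                gmap,
                rec.sensors,
            )
            lm.to_dataframe().to_csv(loss_dir / f"{stem}.csv", index=False)

    bilateral = []
    for (subject, trial, phase), side_reports in sorted(reports.items()):
        if len(side_reports) == 2:
            bilateral.append(evaluate.average_reports(side_reports[0], side_reports[1]))
        else:
            bilateral.extend(side_reports)
    summary = evaluate.summarize(bilateral)
    summary.to_csv(out / "summary.csv", index=False)
    (out / "summary.md").write_text(evaluate.summary_to_markdown(summary) + "\n")

    manifest = {
        "tool": "insolesim",
        "version": __version__,
        # out_dir is implied by the manifest's own location; leaving it out
        # keeps manifests of identical runs bit-identical across directories
        "config": config.model_dump(exclude={"out_dir"}),
        "n_trial_recordings": len(cohort),
        "files": sorted(
            str(p.relative_to(out))
            for p in out.rglob("*")
            if p.is_file() and p.name != "manifest.json"
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("run finished: %s", out)
    return out
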