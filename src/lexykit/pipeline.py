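"""End-to-end orchestration: simulate → render → segment → quantify → fit.

High-level entry points used by the examples, the CLI and the acceptance
script:

* :func:`run_live_experiment` — full live-imaging pipeline on a named
  photocycle preset, returning per-cell quantification traces, per-cell
  exponential fits and the median half-time.
* :func:`run_fixed_experiment` — fixed-mode z-stack pipeline on a named
  dark/lit ratio-pair preset, returning per-cell ratios per condition and
  the fold-depletion with a bootstrap CI.
* :class:`RunConfig` + :func:`run_simulation` / :func:`run_quantification`
  — file-based runs (TIFF stacks, CSV tables, JSON ground truth and a
  provenance sidecar) driven by a YAML config.

Seeds are mandatory throughout; identical config + seed gives byte-identical
outputs.  Time is minutes everywhere internally.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinetics import FoldChange, fit_cells, fold_change, median_half_time, summarize_cells
from .photocycle import LightProtocol, StateTrace, dark_initial_state, lit_initial_state, simulate
from .presets import FIXED_PRESETS, LIVE_PRESETS, fixed_preset, live_preset
from .quantify import measure_stack, quantify_fixed, relative_fluorescence, write_measurements
from .scene import AcquisitionPlan, ScenePlan, render_fixed, render_timelapse, write_stack
from .segmentation import (RoiConfig, SegmentationConfig, derive_rois, flag_mitotic,
                           marker_features, segment_nuclei, track_labels)

logger = logging.getLogger("lexykit")

__all__ = [
    "RunConfig",
    "LiveRunResult",
    "FixedRunResult",
    "segment_stack",
    "run_live_experiment",
    "run_fixed_experiment",
    "run_simulation",
    "run_quantification",
    "make_fixtures",
]


@dataclass
class LiveRunResult:
    traces: pd.DataFrame          # quantification-trace schema
    fits: pd.DataFrame            # per-cell fit table
    median_t_half_min: float
    summary: pd.DataFrame         # per-timepoint mean ± SD
    truth: object                 # GroundTruth
    trace_model: StateTrace
    n_cells_quantified: int


@dataclass
class FixedRunResult:
    dark_ratios: pd.Series
    lit_ratios: pd.Series
    fold: FoldChange
    preset: str


def segment_stack(marker_stack: np.ndarray,
                  seg_config: SegmentationConfig = SegmentationConfig(),
                  roi_config: RoiConfig = RoiConfig(),
                  max_displacement: float = 5.0,
                  mitotic_alpha: float = 0.7, mitotic_beta: float = 1.5):
    """Segment every frame, track labels to frame 0, derive ROIs, flag mitosis.

    Returns ``(roisets, mitotic_ids)`` where ``roisets`` has one RoiSet per
    frame with frame-0-consistent cell ids, and ``mitotic_ids`` is the set of
    cell ids flagged mitotic in any frame (excluded from quantification, per
    the rule that dividing cells leave the analysis for the whole course).
    """
    marker_stack = np.asarray(marker_stack)
    reference = segment_nuclei(marker_stack[0], seg_config)
    roisets = []
    mitotic_ids: set[int] = set()
    for m in range(marker_stack.shape[0]):
        labels = segment_nuclei(marker_stack[m], seg_config)
        if m > 0:
            labels = track_labels(reference, labels, max_displacement)
        feats = marker_features(labels, marker_stack[m])
        if not feats.empty:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                flags = flag_mitotic(feats["area_px"].to_numpy(),
                                     feats["mean_intensity"].to_numpy(),
                                     mitotic_alpha, mitotic_beta)
            mitotic_ids.update(feats.loc[flags, "cell_id"].astype(int).tolist())
        roisets.append(derive_rois(labels, roi_config))
    for rs in roisets:
        for c in rs.cells:
            if c.cell_id in mitotic_ids:
                c.valid = False
    return roisets, mitotic_ids


def _live_protocol_and_initial(params, phase: str, duration_min: float):
    if phase == "induction":
        return LightProtocol.constant(1.0, duration_min), dark_initial_state(params)
    if phase == "recovery":
        return LightProtocol.constant(0.0, duration_min), lit_initial_state(params)
    raise ValueError(f"phase must be 'induction' or 'recovery', got {phase!r}")


def run_live_experiment(preset: str, phase: str = "induction",
                        n_cells: int = 10, frame_interval_min: float = 0.5,
                        duration_min: float = 10.0, seed: int = 0,
                        noise: bool = True, mode: str = "corrected",
                        scene_kwargs: dict | None = None,
                        acq_kwargs: dict | None = None) -> LiveRunResult:
    """Full live pipeline: simulate a preset, render, segment, quantify, fit.

    ``phase="induction"`` applies continuous full-intensity blue light from
    the dark steady state; ``phase="recovery"`` images the dark return from
    the lit steady state.  The median fitted half-time is taken across
    accepted per-cell fits of the relative N/C ratio.
    """
    params = live_preset(preset)
    protocol, initial = _live_protocol_and_initial(params, phase, duration_min)
    grid = np.linspace(0.0, duration_min, max(2001, int(duration_min * 40) + 1))
    trace = simulate(params, protocol, grid, initial=initial)

    ss = np.random.SeedSequence([seed, 17])
    scene_seed = int(ss.generate_state(1)[0] % (2 ** 31))
    scene = ScenePlan.grid(n_cells=n_cells, seed=scene_seed, **(scene_kwargs or {}))
    acq = AcquisitionPlan.regular(frame_interval_min, duration_min, noise=noise,
                                  **(acq_kwargs or {}))
    reporter, marker, truth = render_timelapse(scene, trace, acq)

    roisets, mitotic_ids = segment_stack(marker)
    if mitotic_ids:
        logger.info("excluding %d mitotic-flagged cells", len(mitotic_ids))
    measurements = measure_stack(reporter, roisets, scene.pixel_size_um,
                                 times_min=np.asarray(acq.frame_times_min))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        traces = relative_fluorescence(measurements, mode=mode)
        fits = fit_cells(traces, phase=phase, column="nc_ratio_rel")
        summary = summarize_cells(traces)
    return LiveRunResult(
        traces=traces, fits=fits, median_t_half_min=median_half_time(fits),
        summary=summary, truth=truth, trace_model=trace,
        n_cells_quantified=int(traces["cell_id"].nunique()))


def _quantify_fixed_stack(reporter, marker, scene, n_z: int) -> pd.Series:
    roisets = []
    mitotic_by_cell: dict[int, bool] = {}
    reference = segment_nuclei(marker[0])
    for z in range(n_z):
        labels = segment_nuclei(marker[z])
        if z > 0:
            labels = track_labels(reference, labels)
        feats = marker_features(labels, marker[z])
        if not feats.empty:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                flags = flag_mitotic(feats["area_px"].to_numpy(),
                                     feats["mean_intensity"].to_numpy())
            for cid, fl in zip(feats["cell_id"].astype(int), flags):
                mitotic_by_cell[cid] = mitotic_by_cell.get(cid, False) or bool(fl)
        roisets.append(derive_rois(labels))
    measurements = measure_stack(reporter, roisets, scene.pixel_size_um)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return quantify_fixed(measurements, z_center=n_z // 2, mitotic=mitotic_by_cell)


def run_fixed_experiment(preset: str, n_cells: int = 30, n_z: int = 3,
                         seed: int = 0, noise: bool = True,
                         n_boot: int = 2000) -> FixedRunResult:
    """Fixed-mode pipeline: render dark and lit z-stacks at the preset ratio
    pair, quantify per cell over three consecutive z-planes, and report the
    fold reduction in mean N/C ratio with a bootstrap CI."""
    dark_ratio, lit_ratio = fixed_preset(preset)
    ss = np.random.SeedSequence([seed, 29])
    seeds = [int(s % (2 ** 31)) for s in ss.generate_state(3)]
    shape = (384, 384) if n_cells > 25 else (256, 256)

    ratios = {}
    for label, nc, sc_seed in (("dark", dark_ratio, seeds[0]),
                               ("lit", lit_ratio, seeds[1])):
        scene = ScenePlan.grid(n_cells=n_cells, shape=shape, seed=sc_seed)
        acq = AcquisitionPlan.fixed_stack(n_z, noise=noise)
        reporter, marker, _truth = render_fixed(scene, nc, n_z, acq)
        ratios[label] = _quantify_fixed_stack(reporter, marker, scene, n_z)
    fold = fold_change(ratios["dark"].to_numpy(), ratios["lit"].to_numpy(),
                       n_boot=n_boot, seed=seeds[2])
    return FixedRunResult(dark_ratios=ratios["dark"], lit_ratios=ratios["lit"],
                          fold=fold, preset=preset)


# ---------------------------------------------------------------------------
# file-based runs


_CONFIG_FIELDS = {
    "preset": str, "mode": str, "phase": str, "n_cells": int,
    "frame_interval_min": float, "duration_min": float, "n_z": int,
    "quant_mode": str, "noise": bool, "seed": int, "outdir": str,
}


@dataclass
class RunConfig:
    """Serializable description of one pipeline run.

    ``mode`` is "live" or "fixed"; ``phase`` applies to live runs.  Unknown
    keys in a YAML config are rejected.
    """

    preset: str = "live-iLEXYs"
    mode: str = "live"
    phase: str = "induction"
    n_cells: int = 10
    frame_interval_min: float = 0.5
    duration_min: float = 10.0
    n_z: int = 3
    quant_mode: str = "corrected"
    noise: bool = True
    seed: int = 0
    outdir: str = "lexykit_run"

    def __post_init__(self) -> None:
        if self.mode not in ("live", "fixed"):
            raise ValueError(f"mode must be 'live' or 'fixed', got {self.mode!r}")
        known = LIVE_PRESETS if self.mode == "live" else FIXED_PRESETS
        if self.preset not in known:
            raise ValueError(f"unknown {self.mode} preset {self.preset!r}; "
                             f"choose from {sorted(known)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(_CONFIG_FIELDS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: _CONFIG_FIELDS[k](v) for k, v in data.items()})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _write_provenance(outdir: Path, config: RunConfig, stage: str) -> None:
    record = {"stage": stage, "config_hash": config.config_hash,
              "seed": config.seed, "version": __version__,
              "config": config.to_dict()}
    (outdir / f"provenance_{stage}.json").write_text(json.dumps(record, indent=2))


def run_simulation(config: RunConfig) -> dict[str, Path]:
    """Simulate + render a config to disk: TIFF stacks, ground truth, provenance."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence([config.seed, 17])
    scene_seed = int(ss.generate_state(1)[0] % (2 ** 31))

    if config.mode == "live":
        params = live_preset(config.preset)
        protocol, initial = _live_protocol_and_initial(params, config.phase,
                                                       config.duration_min)
        grid = np.linspace(0.0, config.duration_min,
                           max(2001, int(config.duration_min * 40) + 1))
        trace = simulate(params, protocol, grid, initial=initial)
        scene = ScenePlan.grid(n_cells=config.n_cells, seed=scene_seed)
        acq = AcquisitionPlan.regular(config.frame_interval_min,
                                      config.duration_min, noise=config.noise)
        reporter, marker, truth = render_timelapse(scene, trace, acq)
        trace.to_csv(outdir / "model_trace.csv")
    else:
        dark_ratio, lit_ratio = fixed_preset(config.preset)
        scene = ScenePlan.grid(n_cells=config.n_cells, seed=scene_seed,
                               shape=(384, 384) if config.n_cells > 25 else (256, 256))
        acq = AcquisitionPlan.fixed_stack(config.n_z, noise=config.noise)
        reporter, marker, truth = render_fixed(scene, dark_ratio, config.n_z, acq)

    paths = {"reporter": outdir / "reporter.tif", "marker": outdir / "marker.tif",
             "ground_truth": outdir / "ground_truth.json",
             "truth_csv": outdir / "ground_truth.csv"}
    write_stack(paths["reporter"], reporter)
    write_stack(paths["marker"], marker)
    truth.to_json(paths["ground_truth"])
    n_cells, n_frames = truth.nuc_mean.shape
    pd.DataFrame({
        "cell_id": np.repeat(np.arange(1, n_cells + 1), n_frames),
        "t_index": np.tile(np.arange(n_frames), n_cells),
        "true_nuc_mean": truth.nuc_mean.ravel(),
        "true_cyt_mean": truth.cyt_mean.ravel(),
        "true_ratio": truth.ratio.ravel(),
    }).to_csv(paths["truth_csv"], index=False, float_format="%.9g")
    _write_provenance(outdir, config, "simulate")
    return paths


def run_quantification(config: RunConfig, reporter: np.ndarray,
                       marker: np.ndarray) -> dict[str, Path]:
    """Segment + quantify + fit rendered stacks; write CSV outputs.

    Partial failures (a cell's fit rejected, zero detected cells) are logged
    and the run completes; outputs may be empty tables.
    """
    if reporter.shape != marker.shape:
        raise ValueError("reporter and marker stacks must have identical shapes")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scene_px = ScenePlan.grid(n_cells=1).pixel_size_um  # default pixel size

    if config.mode == "live":
        times = np.arange(reporter.shape[0]) * config.frame_interval_min
        roisets, mitotic = segment_stack(marker)
        measurements = measure_stack(reporter, roisets, scene_px, times_min=times)
        paths = {"measurements": outdir / "measurements.csv",
                 "traces": outdir / "quant_traces.csv",
                 "fits": outdir / "fits.csv", "summary": outdir / "summary.csv"}
        write_measurements(measurements, paths["measurements"])
        if measurements.empty or not (measurements["roi_type"] == "nucleus").any():
            logger.warning("no cells detected; writing empty outputs")
            from .quantify import TRACE_COLUMNS

            pd.DataFrame(columns=TRACE_COLUMNS).to_csv(paths["traces"], index=False)
            pd.DataFrame(columns=["cell_id", "phase", "k_per_min", "t_half_min",
                                  "y0", "y_inf", "rms", "n", "accepted"]
                         ).to_csv(paths["fits"], index=False)
            pd.DataFrame(columns=["time_min", "mean", "sd", "n"]
                         ).to_csv(paths["summary"], index=False)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                traces = relative_fluorescence(measurements, mode=config.quant_mode)
                fits = fit_cells(traces, phase=config.phase)
                summary = summarize_cells(traces)
            traces.to_csv(paths["traces"], index=False)
            fits.to_csv(paths["fits"], index=False)
            summary.to_csv(paths["summary"], index=False)
    else:
        scene = ScenePlan.grid(n_cells=config.n_cells,
                               shape=(384, 384) if config.n_cells > 25 else (256, 256))
        ratios = _quantify_fixed_stack(reporter, marker, scene, config.n_z)
        paths = {"ratios": outdir / "fixed_ratios.csv"}
        ratios.rename_axis("cell_id").to_csv(paths["ratios"])
    _write_provenance(outdir, config, "quantify")
    return paths


def make_fixtures(outdir) -> dict[str, Path]:
    """Write small deterministic demonstration fixtures.

    A 6-cell live induction scene (iLEXYs preset), a 12-cell fixed dark/lit
    pair, and the synthetic stage-shift hatch table; everything regenerable
    bit-for-bit from the fixed seeds.
    """
    from .viability import example_hatch_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    live_cfg = RunConfig(preset="live-iLEXYs", mode="live", phase="induction",
                         n_cells=6, frame_interval_min=0.5, duration_min=5.0,
                         seed=7, outdir=str(outdir / "live_demo"))
    paths.update({f"live_{k}": v for k, v in run_simulation(live_cfg).items()})
    fixed_cfg = RunConfig(preset="fixed-iLEXYs", mode="fixed", n_cells=12,
                          seed=7, outdir=str(outdir / "fixed_demo"))
    paths.update({f"fixed_{k}": v for k, v in run_simulation(fixed_cfg).items()})
    hatch_path = outdir / "hatch_table_example.csv"
    example_hatch_table(seed=7).to_csv(hatch_path, index=False)
    paths["hatch_table"] = hatch_path
    return paths
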