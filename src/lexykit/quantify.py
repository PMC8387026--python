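"""Bleach-corrected, background-subtracted relative fluorescence and N/C ratios.

Implements the standard two-compartment ROI quantification for live
time-lapse data:

* **Bleaching factor** at time ``tx`` — the background-subtracted whole-field
  density relative to the first time point::

      B(tx) = [(RawIntDen/Area)_AllCells - (RawIntDen/Area)_BG]_tx
            / [(RawIntDen/Area)_AllCells - (RawIntDen/Area)_BG]_t0

* **Fluorescence** per compartment — the mean over that compartment's ROIs of
  RawIntDen/Area, background subtracted, combined with the bleaching factor.
  Two modes are provided: ``"as-printed"`` *multiplies* by the bleaching
  factor, ``"corrected"`` (default) *divides* by it.  A survival factor is
  < 1 under bleaching, so multiplying aggravates rather than corrects the
  decay; both modes are kept because the multiplicative form circulates in
  protocol write-ups.  The N/C ratio is identical either way — the factor
  multiplies both compartments and cancels.

* **Relative fluorescence** — nuclear and cytoplasmic fluorescence divided by
  the *nuclear* fluorescence at the first time point, so relative nuclear
  fluorescence at t0 is exactly 1.

Fixed-mode stacks are quantified per cell by averaging the density over
three consecutive z-planes per compartment, subtracting the background
density, and taking the nuclear/cytoplasmic quotient; mitotic-flagged cells
are excluded.

The measurement table schema (importable from any image tool) is::

    cell_id, t_index, time_min, roi_type in {nucleus, cytoplasm, BG, AllCells},
    area_um2, raw_int_den

Multiple rows per (cell, time, roi_type) are allowed and are averaged as
per-ROI densities (RawIntDen_i / Area_i), which is robust to unequal ROI
sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import RoiSet, sample_sub_rois

__all__ = [
    "QuantError",
    "RoiMeasurement",
    "measure_roi",
    "measure_stack",
    "bleaching_factor",
    "relative_fluorescence",
    "quantify_fixed",
    "read_measurements",
    "write_measurements",
]

MEASUREMENT_COLUMNS = ["cell_id", "t_index", "time_min", "roi_type",
                       "area_um2", "raw_int_den"]
TRACE_COLUMNS = ["cell_id", "time_min", "bleach_factor", "rel_nuc", "rel_cyt",
                 "nc_ratio", "nc_ratio_rel", "valid"]
ROI_TYPES = ("nucleus", "cytoplasm", "BG", "AllCells")


class QuantError(ValueError):
    """Quantification impossible (no signal, empty mask, missing t0...)."""


@dataclass(frozen=True)
class RoiMeasurement:
    """Area (µm²) and raw integrated density of one ROI at one time point."""

    cell_id: int
    t_index: int
    roi_type: str
    area_um2: float
    raw_int_den: float
    time_min: float = 0.0

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise QuantError("ROI area must be positive")
        if self.raw_int_den < 0:
            raise QuantError("raw integrated density must be non-negative")

    @property
    def density(self) -> float:
        return self.raw_int_den / self.area_um2


def measure_roi(image: np.ndarray, mask: np.ndarray, pixel_size_um: float,
                cell_id: int = 0, t_index: int = 0, roi_type: str = "nucleus",
                time_min: float = 0.0) -> RoiMeasurement:
    """Area = pixel count x pixel size², RawIntDen = sum of pixel values."""
    mask = np.asarray(mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px == 0:
        raise QuantError(f"empty mask for cell {cell_id} at t_index {t_index}")
    return RoiMeasurement(
        cell_id=cell_id, t_index=t_index, roi_type=roi_type, time_min=time_min,
        area_um2=n_px * pixel_size_um ** 2,
        raw_int_den=float(np.asarray(image, dtype=float)[mask].sum()))


def measure_stack(stack: np.ndarray, roisets: list[RoiSet] | RoiSet,
                  pixel_size_um: float, times_min: np.ndarray | None = None,
                  n_sub_rois: int = 0, sub_roi_radius: int = 3,
                  sub_roi_seed: int = 0) -> pd.DataFrame:
    """Measure every ROI of every frame of a stack into the standard table.

    ``roisets`` may be a single RoiSet (static cells) or one per frame.
    With ``n_sub_rois > 0``, each compartment contributes that many random
    disk sub-ROIs per frame (emulating manual ROI drawing) instead of its
    full mask.
    """
    stack = np.asarray(stack)
    n_frames = stack.shape[0]
    if isinstance(roisets, RoiSet):
        roisets = [roisets] * n_frames
    if len(roisets) != n_frames:
        raise ValueError("need one RoiSet per frame (or a single shared one)")
    if times_min is None:
        times_min = np.arange(n_frames, dtype=float)
    rng = np.random.default_rng(sub_roi_seed)

    rows = []

    def add(meas: RoiMeasurement) -> None:
        rows.append({"cell_id": meas.cell_id, "t_index": meas.t_index,
                     "time_min": meas.time_min, "roi_type": meas.roi_type,
                     "area_um2": meas.area_um2, "raw_int_den": meas.raw_int_den})

    for m in range(n_frames):
        frame, rois = stack[m], roisets[m]
        for c in rois.cells:
            if not c.valid:
                continue
            for roi_type, mask in (("nucleus", c.nucleus), ("cytoplasm", c.cytoplasm)):
                if n_sub_rois > 0:
                    parts = sample_sub_rois(mask, n_sub_rois, sub_roi_radius, rng)
                else:
                    parts = [mask]
                for part in parts:
                    if part.any():
                        add(measure_roi(frame, part, pixel_size_um, c.cell_id,
                                        m, roi_type, float(times_min[m])))
        for roi_type, mask in (("BG", rois.background), ("AllCells", rois.allcells)):
            if mask.any():
                add(measure_roi(frame, mask, pixel_size_um, 0, m, roi_type,
                                float(times_min[m])))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def _density(area_um2, raw_int_den) -> float:
    return float(raw_int_den) / float(area_um2)


def bleaching_factor(allcells_tx: RoiMeasurement | tuple[float, float],
                     bg_tx: RoiMeasurement | tuple[float, float],
                     allcells_t0: RoiMeasurement | tuple[float, float],
                     bg_t0: RoiMeasurement | tuple[float, float]) -> float:
    """Whole-field bleaching factor at ``tx`` relative to ``t0``.

    Arguments are RoiMeasurements or ``(area_um2, raw_int_den)`` pairs for
    the AllCells and BG regions at the two time points.
    """
    def dens(x) -> float:
        if isinstance(x, RoiMeasurement):
            return x.density
        return _density(*x)

    denom = dens(allcells_t0) - dens(bg_t0)
    if denom <= 0:
        raise QuantError("no signal above background at t0; bleaching factor undefined")
    return (dens(allcells_tx) - dens(bg_tx)) / denom


def _density_table(measurements: pd.DataFrame) -> pd.DataFrame:
    df = measurements.copy()
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise QuantError(f"measurement table missing columns: {sorted(missing)}")
    bad = set(df["roi_type"].unique()) - set(ROI_TYPES)
    if bad:
        raise QuantError(f"unknown roi_type values: {sorted(bad)}")
    df["density"] = df["raw_int_den"] / df["area_um2"]
    return df


def relative_fluorescence(measurements: pd.DataFrame,
                          mode: str = "corrected") -> pd.DataFrame:
    """Compute per-cell quantification traces from a measurement table.

    Returns a table with one row per (cell, time point): bleaching factor,
    relative nuclear and cytoplasmic fluorescence (normalized by nuclear
    fluorescence at t0), absolute N/C density ratio and the ratio relative
    to t0, plus a validity flag.  Time points whose background-subtracted
    density is non-positive are marked invalid (never interpolated); cells
    without a valid first time point are dropped with a warning.
    """
    if mode not in ("corrected", "as-printed"):
        raise ValueError(f"mode must be 'corrected' or 'as-printed', got {mode!r}")
    df = _density_table(measurements)

    # per-frame scene-wide densities
    frame_idx = sorted(df["t_index"].unique())
    scene = (df[df["roi_type"].isin(["BG", "AllCells"])]
             .groupby(["t_index", "roi_type"])["density"].mean().unstack())
    for col in ("BG", "AllCells"):
        if col not in getattr(scene, "columns", []):
            raise QuantError(f"measurement table has no {col} rows")
    t0 = frame_idx[0]
    denom0 = scene.loc[t0, "AllCells"] - scene.loc[t0, "BG"]
    if denom0 <= 0:
        raise QuantError("no signal above background at t0; bleaching factor undefined")
    bleach = (scene["AllCells"] - scene["BG"]) / denom0

    times = df.groupby("t_index")["time_min"].first()
    cell_dens = (df[df["roi_type"].isin(["nucleus", "cytoplasm"])]
                 .groupby(["cell_id", "t_index", "roi_type"])["density"].mean()
                 .unstack())

    records = []
    for cell_id, sub in cell_dens.groupby(level="cell_id"):
        sub = sub.droplevel("cell_id").reindex(frame_idx)
        nuc = sub.get("nucleus")
        cyt = sub.get("cytoplasm")
        if nuc is None or cyt is None:
            continue
        nuc_bs = nuc - scene["BG"]
        cyt_bs = cyt - scene["BG"]
        valid = (nuc_bs > 0) & (cyt_bs > 0) & nuc.notna() & cyt.notna()
        if not valid.get(t0, False):
            warnings.warn(f"cell {cell_id}: first time point invalid; cell dropped",
                          stacklevel=2)
            continue
        if mode == "as-printed":
            fluor_nuc = nuc_bs * bleach
            fluor_cyt = cyt_bs * bleach
        else:
            fluor_nuc = nuc_bs / bleach
            fluor_cyt = cyt_bs / bleach
        f0 = fluor_nuc.loc[t0]
        nc = nuc_bs / cyt_bs
        nc0 = nc.loc[t0]
        for ti in frame_idx:
            ok = bool(valid.get(ti, False))
            records.append({
                "cell_id": cell_id, "time_min": float(times.loc[ti]),
                "bleach_factor": float(bleach.loc[ti]),
                "rel_nuc": float(fluor_nuc.loc[ti] / f0) if ok else np.nan,
                "rel_cyt": float(fluor_cyt.loc[ti] / f0) if ok else np.nan,
                "nc_ratio": float(nc.loc[ti]) if ok else np.nan,
                "nc_ratio_rel": float(nc.loc[ti] / nc0) if ok else np.nan,
                "valid": ok,
            })
    out = pd.DataFrame(records, columns=TRACE_COLUMNS)
    if out.empty:
        raise QuantError("no cell had a valid first time point")
    return out


def quantify_fixed(measurements: pd.DataFrame, z_center: int,
                   mitotic: dict[int, bool] | None = None) -> pd.Series:
    """Per-cell N/C ratio from three consecutive z-planes of a fixed stack.

    For each cell, the nuclear and cytoplasmic densities are averaged over
    planes ``z_center - 1 .. z_center + 1``, the background density (averaged
    over the same planes) is subtracted, and the ratio of the two
    background-subtracted densities is returned.  Mitotic-flagged cells are
    excluded; cells whose cytoplasmic density does not exceed background are
    excluded with a warning.
    """
    df = _density_table(measurements)
    planes = [z_center - 1, z_center, z_center + 1]
    if not set(planes) <= set(df["t_index"].unique()):
        raise QuantError(f"need z-planes {planes} in the measurement table")
    df = df[df["t_index"].isin(planes)]
    bg = df[df["roi_type"] == "BG"].groupby("t_index")["density"].mean().mean()
    mitotic = mitotic or {}

    ratios = {}
    comp = (df[df["roi_type"].isin(["nucleus", "cytoplasm"])]
            .groupby(["cell_id", "roi_type"])["density"].mean().unstack())
    for cell_id, row in comp.iterrows():
        if mitotic.get(cell_id, False):
            continue
        nuc = row.get("nucleus", np.nan) - bg
        cyt = row.get("cytoplasm", np.nan) - bg
        if not np.isfinite(cyt) or cyt <= 0:
            warnings.warn(f"cell {cell_id}: cytoplasmic density not above background; "
                          "excluded", stacklevel=2)
            continue
        ratios[cell_id] = nuc / cyt
    return pd.Series(ratios, name="nc_ratio").sort_index()


def write_measurements(df: pd.DataFrame, path) -> None:
    df[MEASUREMENT_COLUMNS].to_csv(path, index=False)


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise QuantError(f"measurement CSV missing columns: {sorted(missing)}")
    return df[MEASUREMENT_COLUMNS]
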