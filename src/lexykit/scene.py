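"""Synthetic two-channel microscopy renderer with ground truth.

Renders photocycle :class:`~lexykit.photocycle.StateTrace` dynamics into
time-lapse stacks (reporter channel, e.g. an mCherry fusion, plus a nuclear
histone marker channel) and fixed z-stacks of cells at a steady-state
nucleocytoplasmic partition.  Cells are disks (nucleus) surrounded by annular
cytoplasm; mitotic cells are rendered condensed (half area) and twice as
bright in the marker channel so the downstream exclusion heuristic has a
detectable signature.

Intensity model per pixel: ``background + brightness * concentration *
b**frame`` where ``b`` is the per-acquisition bleach survival factor,
followed by Poisson shot noise and Gaussian read noise (optional), quantized
to 16-bit.  Compartment amounts map to mean pixel intensity with equal
volume proxies — nuclear mean is proportional to N, cytoplasmic mean to C —
so the rendered intensity-density ratio equals the model's N/C amount ratio.

Everything is deterministic under a fixed scene seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

from .photocycle import DomainError, StateTrace

__all__ = [
    "CellGeometry",
    "ScenePlan",
    "AcquisitionPlan",
    "GroundTruth",
    "render_timelapse",
    "render_fixed",
    "write_stack",
    "read_stack",
]

_U16_MAX = 65535


@dataclass(frozen=True)
class CellGeometry:
    """One cell: nucleus disk of radius ``r_nuc`` inside a cytoplasmic
    annulus reaching ``r_cyto``, centred at (cy, cx) in pixel coordinates."""

    cy: float
    cx: float
    r_nuc: float = 7.0
    r_cyto: float = 13.0
    mitotic: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.r_nuc < self.r_cyto:
            raise DomainError("need 0 < r_nuc < r_cyto")


@dataclass(frozen=True)
class ScenePlan:
    """Field layout and photometry of a synthetic scene.

    ``reporter_scale`` is the reporter brightness per unit total amount:
    a cell holding its full amount in the nucleus would have nuclear mean
    ``background + reporter_scale`` (a.u., pre-noise, pre-bleach).
    """

    cells: tuple[CellGeometry, ...]
    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    reporter_scale: float = 800.0
    marker_level: float = 400.0
    background: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        for c in self.cells:
            if not (c.r_cyto <= c.cy <= h - 1 - c.r_cyto
                    and c.r_cyto <= c.cx <= w - 1 - c.r_cyto):
                raise DomainError(f"cell at ({c.cy}, {c.cx}) does not fit the field")
        for a in self.cells:
            for b in self.cells:
                if a is not b:
                    d = np.hypot(a.cy - b.cy, a.cx - b.cx)
                    if d < a.r_cyto + b.r_cyto:
                        raise DomainError("cells overlap; increase spacing")

    @classmethod
    def grid(cls, n_cells: int = 10, shape: tuple[int, int] = (256, 256),
             r_nuc: float = 7.0, r_cyto: float = 13.0, jitter: float = 2.0,
             mitotic: tuple[int, ...] = (), seed: int = 0,
             **kwargs) -> "ScenePlan":
        """Place ``n_cells`` on a jittered grid, non-overlapping by construction."""
        rng = np.random.default_rng(seed)
        n_cols = int(np.ceil(np.sqrt(n_cells)))
        n_rows = int(np.ceil(n_cells / n_cols))
        h, w = shape
        margin = r_cyto + jitter + 3
        ys = np.linspace(margin, h - 1 - margin, n_rows)
        xs = np.linspace(margin, w - 1 - margin, n_cols)
        min_gap = min(np.diff(ys).min() if n_rows > 1 else np.inf,
                      np.diff(xs).min() if n_cols > 1 else np.inf)
        if min_gap < 2 * (r_cyto + jitter) + 1:
            raise DomainError(
                f"{n_cells} cells of outer radius {r_cyto} do not fit {shape}")
        cells = []
        for i in range(n_cells):
            cy = ys[i // n_cols] + rng.uniform(-jitter, jitter)
            cx = xs[i % n_cols] + rng.uniform(-jitter, jitter)
            cells.append(CellGeometry(cy, cx, r_nuc, r_cyto, mitotic=i in mitotic))
        return cls(cells=tuple(cells), shape=shape, seed=seed, **kwargs)

    def replace(self, **kwargs) -> "ScenePlan":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class AcquisitionPlan:
    """Frame schedule and noise/bleach model of an acquisition.

    ``bleach_reporter`` / ``bleach_marker`` are per-acquisition-event survival
    factors in (0, 1]: the signal at frame m is scaled by ``b**m``, matching a
    per-timepoint bleaching-factor correction downstream.  ``gain`` converts
    intensity to detected photon counts for the Poisson shot-noise draw.
    """

    frame_times_min: tuple[float, ...]
    bleach_reporter: float = 0.985
    bleach_marker: float = 0.995
    gain: float = 1.0
    read_noise_sd: float = 3.0
    noise: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.frame_times_min, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise DomainError("frame times must be non-empty and strictly increasing")
        for b in (self.bleach_reporter, self.bleach_marker):
            if not 0.0 < b <= 1.0:
                raise DomainError("bleach survival factors must be in (0, 1]")
        if self.gain <= 0:
            raise DomainError("gain must be positive")

    @classmethod
    def regular(cls, interval_min: float, duration_min: float,
                **kwargs) -> "AcquisitionPlan":
        n = int(np.floor(duration_min / interval_min + 1e-9)) + 1
        return cls(tuple(np.arange(n) * interval_min), **kwargs)

    @classmethod
    def fixed_stack(cls, n_z: int = 3, **kwargs) -> "AcquisitionPlan":
        """Plan for a fixed z-stack: one 'frame' per plane, no bleach by default."""
        kwargs.setdefault("bleach_reporter", 1.0)
        kwargs.setdefault("bleach_marker", 1.0)
        return cls(tuple(float(i) for i in range(n_z)), **kwargs)

    @property
    def n_frames(self) -> int:
        return len(self.frame_times_min)

    def replace(self, **kwargs) -> "AcquisitionPlan":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Machine-readable truth for a rendered scene.

    ``nuc_mean`` / ``cyt_mean`` are the true per-cell per-frame mean signal
    intensities above background (pre-noise, bleach included); ``ratio`` is
    the true N/C density ratio (bleach- and background-free).
    """

    nuc_mean: np.ndarray          # (n_cells, n_frames)
    cyt_mean: np.ndarray          # (n_cells, n_frames)
    ratio: np.ndarray             # (n_cells, n_frames)
    label_mask: np.ndarray        # (H, W) nucleus labels, 1-based
    cyto_mask: np.ndarray         # (H, W) cytoplasm labels, 1-based
    mitotic: np.ndarray           # (n_cells,) bool
    frame_times_min: np.ndarray   # (n_frames,)
    background: float

    def to_json(self, path) -> None:
        data = {
            "nuc_mean": self.nuc_mean.tolist(),
            "cyt_mean": self.cyt_mean.tolist(),
            "ratio": self.ratio.tolist(),
            "mitotic": self.mitotic.astype(bool).tolist(),
            "frame_times_min": self.frame_times_min.tolist(),
            "background": self.background,
        }
        with open(path, "w") as fh:
            json.dump(data, fh)


def _masks(scene: ScenePlan) -> tuple[np.ndarray, np.ndarray]:
    """Nucleus and cytoplasm label images (0 = none, i+1 = cell i)."""
    h, w = scene.shape
    yy, xx = np.mgrid[0:h, 0:w]
    nuc = np.zeros((h, w), dtype=np.uint16)
    cyt = np.zeros((h, w), dtype=np.uint16)
    for i, c in enumerate(scene.cells, start=1):
        r2 = (yy - c.cy) ** 2 + (xx - c.cx) ** 2
        r_nuc = c.r_nuc * (np.sqrt(0.5) if c.mitotic else 1.0)
        nuc[r2 <= r_nuc ** 2] = i
        cyt[(r2 > c.r_nuc ** 2) & (r2 <= c.r_cyto ** 2)] = i
    return nuc, cyt


def _apply_noise(image: np.ndarray, acq: AcquisitionPlan,
                 rng: np.random.Generator) -> np.ndarray:
    counts = rng.poisson(np.maximum(image, 0.0) / acq.gain) * acq.gain
    noisy = counts + rng.normal(0.0, acq.read_noise_sd, size=image.shape)
    return np.clip(np.rint(noisy), 0, _U16_MAX).astype(np.uint16)


def render_timelapse(scene: ScenePlan, trace: StateTrace,
                     acq: AcquisitionPlan) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a two-channel time-lapse from a model trajectory.

    Returns ``(reporter, marker, truth)``; stacks have shape
    ``(n_frames, H, W)``, dtype uint16 with noise on, float64 otherwise.
    The trace must cover all frame times (values are interpolated).
    """
    t = np.asarray(acq.frame_times_min, dtype=float)
    if t[0] < trace.times[0] - 1e-9 or t[-1] > trace.times[-1] + 1e-9:
        raise DomainError("frame times outside the simulated trace")
    n_interp = np.interp(t, trace.times, trace.N)
    c_interp = np.interp(t, trace.times, trace.C)

    nuc_labels, cyt_labels = _masks(scene)
    n_cells = len(scene.cells)
    n_frames = acq.n_frames
    nuc_true = np.empty((n_cells, n_frames))
    cyt_true = np.empty((n_cells, n_frames))
    for i in range(n_cells):
        nuc_true[i] = scene.reporter_scale * n_interp
        cyt_true[i] = scene.reporter_scale * c_interp
    bleach_r = acq.bleach_reporter ** np.arange(n_frames)
    bleach_m = acq.bleach_marker ** np.arange(n_frames)
    nuc_true *= bleach_r
    cyt_true *= bleach_r

    marker_base = np.zeros(scene.shape)
    for i, cell in enumerate(scene.cells, start=1):
        level = scene.marker_level * (2.0 if cell.mitotic else 1.0)
        marker_base[nuc_labels == i] = level

    dtype = np.uint16 if acq.noise else np.float64
    reporter = np.empty((n_frames, *scene.shape), dtype=dtype)
    marker = np.empty_like(reporter)
    rng_rep = np.random.default_rng(np.random.SeedSequence([scene.seed, 1]))
    rng_mark = np.random.default_rng(np.random.SeedSequence([scene.seed, 2]))
    for m in range(n_frames):
        frame = np.full(scene.shape, scene.background, dtype=float)
        for i in range(1, n_cells + 1):
            frame[nuc_labels == i] += nuc_true[i - 1, m]
            frame[cyt_labels == i] += cyt_true[i - 1, m]
        mframe = scene.background + marker_base * bleach_m[m]
        if acq.noise:
            reporter[m] = _apply_noise(frame, acq, rng_rep)
            marker[m] = _apply_noise(mframe, acq, rng_mark)
        else:
            reporter[m] = frame
            marker[m] = mframe

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(c_interp > 0, n_interp / c_interp, np.inf)
    truth = GroundTruth(
        nuc_mean=nuc_true, cyt_mean=cyt_true,
        ratio=np.broadcast_to(ratio, (n_cells, n_frames)).copy(),
        label_mask=nuc_labels, cyto_mask=cyt_labels,
        mitotic=np.array([c.mitotic for c in scene.cells]),
        frame_times_min=t, background=scene.background)
    return reporter, marker, truth


def render_fixed(scene: ScenePlan, nc_ratio: float, n_z: int = 3,
                 acq: AcquisitionPlan | None = None,
                 z_jitter: float = 0.03) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a fixed-mode z-stack of cells at a steady-state N/C partition.

    Each cell holds unit total amount split so the nuclear/cytoplasmic mean
    density ratio equals ``nc_ratio``; each z-plane gets a small per-cell
    intensity jitter (default ±3%, applied jointly to both compartments so
    the true ratio is exact per plane).  No bleaching across z by default.
    """
    if nc_ratio <= 0:
        raise DomainError("nc_ratio must be positive")
    if n_z < 3:
        raise DomainError("fixed-mode stacks need at least 3 z-planes")
    if acq is None:
        acq = AcquisitionPlan.fixed_stack(n_z)
    elif acq.n_frames != n_z:
        raise DomainError("acquisition plan length must equal n_z")

    nuc_labels, cyt_labels = _masks(scene)
    n_cells = len(scene.cells)
    # split unit amount: nuc density r/(1+r)*2, cyt density 1/(1+r)*2
    nuc_level = scene.reporter_scale * 2.0 * nc_ratio / (1.0 + nc_ratio)
    cyt_level = scene.reporter_scale * 2.0 / (1.0 + nc_ratio)

    rng_jit = np.random.default_rng(np.random.SeedSequence([scene.seed, 3]))
    jitter = 1.0 + rng_jit.uniform(-z_jitter, z_jitter, size=(n_cells, n_z))
    bleach_r = acq.bleach_reporter ** np.arange(n_z)
    nuc_true = nuc_level * jitter * bleach_r
    cyt_true = cyt_level * jitter * bleach_r

    marker_base = np.zeros(scene.shape)
    for i, cell in enumerate(scene.cells, start=1):
        level = scene.marker_level * (2.0 if cell.mitotic else 1.0)
        marker_base[nuc_labels == i] = level

    dtype = np.uint16 if acq.noise else np.float64
    reporter = np.empty((n_z, *scene.shape), dtype=dtype)
    marker = np.empty_like(reporter)
    rng_rep = np.random.default_rng(np.random.SeedSequence([scene.seed, 1]))
    rng_mark = np.random.default_rng(np.random.SeedSequence([scene.seed, 2]))
    for z in range(n_z):
        frame = np.full(scene.shape, scene.background, dtype=float)
        for i in range(1, n_cells + 1):
            frame[nuc_labels == i] += nuc_true[i - 1, z]
            frame[cyt_labels == i] += cyt_true[i - 1, z]
        mframe = scene.background + marker_base * acq.bleach_marker ** z
        if acq.noise:
            reporter[z] = _apply_noise(frame, acq, rng_rep)
            marker[z] = _apply_noise(mframe, acq, rng_mark)
        else:
            reporter[z] = frame
            marker[z] = mframe

    truth = GroundTruth(
        nuc_mean=nuc_true, cyt_mean=cyt_true,
        ratio=np.full((n_cells, n_z), float(nc_ratio)),
        label_mask=nuc_labels, cyto_mask=cyt_labels,
        mitotic=np.array([c.mitotic for c in scene.cells]),
        frame_times_min=np.asarray(acq.frame_times_min), background=scene.background)
    return reporter, marker, truth


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (frames, H, W) stack as a multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack")


def read_stack(path) -> np.ndarray:
    return tifffile.imread(path)
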