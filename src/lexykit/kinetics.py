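"""Exponential kinetics estimation: half-times, fold-changes, recovery readouts.

Each phase (induction: light on, N/C ratio falls; recovery: light off, ratio
rises) is summarized by a single exponential with plateau::

    y(t) = y_inf + (y0 - y_inf) * exp(-k * t)

fitted by nonlinear least squares on the phase window, with the half-time
t_1/2 = ln2 / k.  The underlying model has two timescales (photoswitch state
and transport); the faster one is absorbed into the plateau, a documented
simplification that matches how half-times are conventionally reported for
these constructs.

Fold-depletion between conditions is the quotient of mean N/C ratios with a
seeded nonparametric bootstrap confidence interval.  Population summaries
are per-timepoint mean ± sample SD across valid cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FitError",
    "KineticsFit",
    "FoldChange",
    "fit_exponential",
    "fit_cells",
    "median_half_time",
    "fold_change",
    "time_to_fraction",
    "summarize_cells",
]

_K_BOUNDS = (1e-5, 1e4)  # 1/min search bounds; a fit pinned here is rejected


class FitError(RuntimeError):
    """Exponential fit rejected (degenerate data, non-convergence, pinned rate)."""


@dataclass(frozen=True)
class KineticsFit:
    """Accepted single-exponential fit of one phase of one trace."""

    phase: str
    k: float            # 1/min
    y0: float
    y_inf: float
    rms: float
    n: int

    @property
    def t_half(self) -> float:
        """Half-time ln2/k in minutes."""
        return math.log(2.0) / self.k

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.y_inf + (self.y0 - self.y_inf) * np.exp(-self.k * np.asarray(t))


@dataclass(frozen=True)
class FoldChange:
    fold: float
    ci_low: float
    ci_high: float
    n_dark: int
    n_lit: int


def _model(t, y0, y_inf, k):
    return y_inf + (y0 - y_inf) * np.exp(-k * t)


def fit_exponential(times: np.ndarray, values: np.ndarray,
                    phase: str = "induction") -> KineticsFit:
    """Least-squares single-exponential fit on a phase window.

    ``times`` are minutes relative to the phase boundary (light-on or
    light-off); the first point need not be at 0.  Requires >= 5 valid
    points; raises :class:`FitError` for degenerate traces, non-convergence,
    or a rate pinned at the search bounds.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 5:
        raise FitError(f"need >= 5 valid points, got {t.size}")
    t = t - t[0]

    y0g, y_infg = y[0], y[-1]
    span = y_infg - y0g
    scale = max(abs(y0g), abs(y_infg), 1e-12)
    if abs(span) < 1e-6 * scale:
        raise FitError("degenerate trace: initial and final values coincide")

    # log-linearized slope for the rate guess
    resid = (y - y_infg) / (y0g - y_infg)
    pos = resid > 1e-3
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(resid[pos]), 1)[0]
        kg = float(np.clip(-slope, 1e-3, 1e3))
    else:
        kg = 3.0 / max(t[-1], 1e-6)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _model, t, y, p0=(y0g, y_infg, kg),
                bounds=([-np.inf, -np.inf, _K_BOUNDS[0]],
                        [np.inf, np.inf, _K_BOUNDS[1]]),
                maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"fit did not converge: {exc}") from exc
    y0f, y_inff, kf = (float(v) for v in popt)
    if kf <= _K_BOUNDS[0] * 1.01 or kf >= _K_BOUNDS[1] * 0.99:
        raise FitError(f"rate pinned at search bound: k = {kf:.3g}/min")
    if abs(y0f - y_inff) < 1e-9 * max(abs(y0f), abs(y_inff), 1e-12):
        raise FitError("fit degenerate: y0 equals plateau")
    rms = float(np.sqrt(np.mean((y - _model(t, *popt)) ** 2)))
    return KineticsFit(phase=phase, k=kf, y0=y0f, y_inf=y_inff, rms=rms, n=int(t.size))


def fit_cells(traces: pd.DataFrame, phase: str = "induction",
              column: str = "nc_ratio_rel") -> pd.DataFrame:
    """Fit every cell's trace; rejected fits are recorded, not fatal.

    ``traces`` follows the quantification-trace schema (cell_id, time_min,
    ``column``, valid).  Returns one row per cell with the fit parameters
    and an ``accepted`` flag.
    """
    rows = []
    for cell_id, sub in traces.groupby("cell_id"):
        sub = sub[sub["valid"]]
        try:
            fit = fit_exponential(sub["time_min"].to_numpy(),
                                  sub[column].to_numpy(), phase=phase)
            rows.append({"cell_id": cell_id, "phase": phase, "k_per_min": fit.k,
                         "t_half_min": fit.t_half, "y0": fit.y0, "y_inf": fit.y_inf,
                         "rms": fit.rms, "n": fit.n, "accepted": True})
        except FitError as exc:
            rows.append({"cell_id": cell_id, "phase": phase, "k_per_min": np.nan,
                         "t_half_min": np.nan, "y0": np.nan, "y_inf": np.nan,
                         "rms": np.nan, "n": int(sub.shape[0]), "accepted": False})
            warnings.warn(f"cell {cell_id}: {exc}", stacklevel=2)
    return pd.DataFrame(rows, columns=["cell_id", "phase", "k_per_min", "t_half_min",
                                       "y0", "y_inf", "rms", "n", "accepted"])


def median_half_time(fits: pd.DataFrame) -> float:
    """Median t_1/2 (min) across accepted per-cell fits."""
    accepted = fits[fits["accepted"]]
    if accepted.empty:
        raise FitError("no accepted fits")
    return float(accepted["t_half_min"].median())


def fold_change(dark_ratios: np.ndarray, lit_ratios: np.ndarray,
                n_boot: int = 2000, seed: int = 0,
                ci: float = 0.95) -> FoldChange:
    """Fold reduction mean(dark)/mean(lit) with a bootstrap CI.

    Non-positive lit ratios are excluded with a warning (they cannot enter a
    quotient of means meaningfully); at least 3 cells per condition required.
    """
    dark = np.asarray(dark_ratios, dtype=float)
    lit = np.asarray(lit_ratios, dtype=float)
    n_bad = int((lit <= 0).sum())
    if n_bad:
        warnings.warn(f"excluding {n_bad} non-positive lit ratios", stacklevel=2)
        lit = lit[lit > 0]
    if dark.size < 3 or lit.size < 3:
        raise ValueError("need >= 3 cells per condition")
    fold = float(dark.mean() / lit.mean())
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        d = rng.choice(dark, size=dark.size, replace=True)
        l = rng.choice(lit, size=lit.size, replace=True)
        boots[b] = d.mean() / l.mean()
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return FoldChange(fold=fold, ci_low=float(lo), ci_high=float(hi),
                      n_dark=int(dark.size), n_lit=int(lit.size))


def time_to_fraction(fit: KineticsFit, fraction: float) -> float:
    """Time (min) at which the fitted curve has traversed ``fraction`` of
    its excursion (y0 -> y_inf); closed form -ln(1 - fraction)/k."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    return -math.log(1.0 - fraction) / fit.k


def summarize_cells(traces: pd.DataFrame,
                    column: str = "nc_ratio_rel") -> pd.DataFrame:
    """Per-timepoint mean ± sample SD of ``column`` across valid cells.

    Cells invalid at a timepoint are omitted there; timepoints with fewer
    than 2 valid cells are dropped.  Raises if no timepoint has >= 2 cells.
    """
    valid = traces[traces["valid"]]
    g = valid.groupby("time_min")[column]
    out = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.count()})
    out = out[out["n"] >= 2].reset_index()
    if out.empty:
        raise ValueError("no timepoint with >= 2 valid cells")
    return out
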