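"""Hatching-assay statistics: viability rates, dose–response, sensitivity score.

Embryonic viability is scored as the fraction of fertilized eggs that hatch
into first-instar larvae; unfertilized eggs are excluded from the
denominator.  Light-exposed viability is reported relative to dark-incubated
siblings of the same genotype and stage.  A stage-wise *sensitivity score*
summarizes graded light exposures: the weighted mean of dark-relative
viabilities across exposure conditions, scaled to [0, 1] with 0 the most
sensitive stage.  The weighting is a methodological choice (the original
description does not state it): the default weights each condition by its
total embryo count — the natural precision weight for binomial rates — and
an equal-weights mode is provided for comparison.  "Scaled from 0 to 1" is
interpreted as clipping of the weighted mean (dark-relative viabilities are
naturally in [0, 1] up to sampling noise); min–max rescaling across stages
is available as an alternative mode.

Table schema (``HatchTable``): one row per replicate count with columns
``genotype, stage, condition, replicate, hatched, unhatched, unfertilized``.
Stage and condition labels are free-form strings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "HATCH_COLUMNS",
    "validate_hatch_table",
    "viability_rate",
    "relative_viability",
    "sensitivity_score",
    "dose_response",
    "example_hatch_table",
    "synth_hatch_table",
]

HATCH_COLUMNS = ["genotype", "stage", "condition", "replicate",
                 "hatched", "unhatched", "unfertilized"]


def validate_hatch_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(HATCH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hatch table missing columns: {sorted(missing)}")
    counts = df[["hatched", "unhatched", "unfertilized"]]
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    if ((df["hatched"] + df["unhatched"]) < 1).any():
        raise ValueError("each row needs at least one scored (fertilized) egg")
    return df


def viability_rate(hatched, unhatched, unfertilized=0):
    """hatched / (hatched + unhatched); unfertilized eggs are excluded.

    Accepts scalars or aligned arrays/Series.
    """
    hatched = np.asarray(hatched, dtype=float)
    unhatched = np.asarray(unhatched, dtype=float)
    denom = hatched + unhatched
    if np.any(denom < 1):
        raise ValueError("viability rate undefined without scored eggs")
    out = hatched / denom
    return float(out) if out.ndim == 0 else out


def _replicate_rates(df: pd.DataFrame) -> np.ndarray:
    return viability_rate(df["hatched"].to_numpy(), df["unhatched"].to_numpy())


def relative_viability(light: pd.DataFrame, dark: pd.DataFrame) -> tuple[float, float]:
    """Mean light viability over mean dark viability, with a propagated SD.

    Inputs are matched-genotype/stage HatchTable slices with >= 1 replicate
    each.  The SD is propagated from per-replicate rate SDs by first-order
    error propagation on the quotient of means; values above 1 are reported
    as-is (no clamping).  A zero dark rate is an uninterpretable baseline.
    """
    r_light = _replicate_rates(validate_hatch_table(light))
    r_dark = _replicate_rates(validate_hatch_table(dark))
    mean_dark = r_dark.mean()
    if mean_dark <= 0:
        raise ValueError("dark viability is zero; relative viability undefined")
    mean_light = r_light.mean()
    ratio = mean_light / mean_dark
    var_l = r_light.var(ddof=1) / r_light.size if r_light.size > 1 else 0.0
    var_d = r_dark.var(ddof=1) / r_dark.size if r_dark.size > 1 else 0.0
    if mean_light > 0:
        sd = ratio * np.sqrt(var_l / mean_light ** 2 + var_d / mean_dark ** 2)
    else:
        sd = np.sqrt(var_l) / mean_dark
    return float(ratio), float(sd)


def sensitivity_score(rel_viability: pd.DataFrame,
                      weights: pd.Series | dict | None = None,
                      mode: str = "clip") -> pd.Series:
    """Stage-wise weighted mean of dark-relative viabilities, scaled to [0, 1].

    Parameters
    ----------
    rel_viability : DataFrame indexed by stage with one column per condition
        (values v_{s,j}: viability of stage s under condition j relative to
        dark).  NaN entries (condition missing for a stage) are dropped for
        that stage with a warning-free renormalization of the weights.
    weights : per-condition weights w_j >= 0, not all zero (e.g. total
        embryos counted per condition).  Default: equal weights.
    mode : ``"clip"`` (default) clips the weighted mean into [0, 1];
        ``"minmax"`` rescales the scores across stages to span [0, 1].

    Returns the per-stage score, 0 = most sensitive.
    """
    v = rel_viability.astype(float)
    if weights is None:
        w = pd.Series(1.0, index=v.columns)
    else:
        w = pd.Series(weights, dtype=float).reindex(v.columns)
        if w.isna().any():
            raise ValueError("weights must cover every condition column")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative and not all zero")

    scores = {}
    for stage, row in v.iterrows():
        present = row.notna()
        if not present.any():
            raise ValueError(f"stage {stage!r} has no conditions")
        ws = w[present]
        if ws.sum() <= 0:
            raise ValueError(f"stage {stage!r}: all applicable weights are zero")
        scores[stage] = float((row[present] * ws).sum() / ws.sum())
    out = pd.Series(scores, name="sensitivity_score")
    if mode == "clip":
        return out.clip(0.0, 1.0)
    if mode == "minmax":
        span = out.max() - out.min()
        if span == 0:
            return pd.Series(0.0, index=out.index, name=out.name)
        return (out - out.min()) / span
    raise ValueError(f"mode must be 'clip' or 'minmax', got {mode!r}")


def dose_response(df: pd.DataFrame) -> pd.DataFrame:
    """Per genotype × LED intensity: mean ± SD viability and a monotonicity
    diagnostic.

    ``condition`` is interpreted as the LED intensity (numeric, percent).
    SD is reported as NaN (missing, not zero) for single-replicate groups.
    The Spearman correlation of mean rate vs intensity is attached per
    genotype as a diagnostic, not enforced.
    """
    from scipy.stats import spearmanr

    df = validate_hatch_table(df).copy()
    df["intensity"] = pd.to_numeric(df["condition"])
    df["rate"] = viability_rate(df["hatched"].to_numpy(), df["unhatched"].to_numpy())
    g = df.groupby(["genotype", "intensity"])["rate"]
    out = pd.DataFrame({"mean": g.mean(),
                        "sd": g.std(ddof=1),
                        "n_replicates": g.count()}).reset_index()
    out.loc[out["n_replicates"] < 2, "sd"] = np.nan
    rhos = {}
    for genotype, sub in out.groupby("genotype"):
        if sub.shape[0] >= 3:
            rhos[genotype] = float(spearmanr(sub["intensity"], sub["mean"]).statistic)
        else:
            rhos[genotype] = np.nan
    out["spearman_rho"] = out["genotype"].map(rhos)
    return out


def example_hatch_table(seed: int = 0) -> pd.DataFrame:
    """Synthetic documentation example of a stage-shift hatching experiment.

    Emulates a depletion time-window mapping: embryos shifted from blue
    light to dark at successive stages (early shifts rescue viability) and
    the reverse.  Counts are binomial draws around plausible stage profiles;
    this is illustrative synthetic data, not a measured dataset.
    """
    rng = np.random.default_rng(seed)
    stages = ["stage 5", "stage 6", "stage 7", "stage 8", "stage 10", "stage 11"]
    profiles = {
        "on_to_off": [0.50, 0.15, 0.05, 0.05, 0.20, 0.60],
        "off_to_on": [0.00, 0.00, 0.00, 0.05, 0.35, 0.90],
        "pulse_5min": [0.80, 0.60, 0.55, 0.60, 0.75, 0.95],
        "pulse_60min": [0.45, 0.10, 0.05, 0.15, 0.50, 0.90],
    }
    rows = []
    for condition, probs in profiles.items():
        for stage, p in zip(stages, probs):
            for rep in (1, 2):
                n = int(rng.integers(15, 41))
                hatched = int(rng.binomial(n, min(max(p, 0.001), 0.999)))
                rows.append({"genotype": "iLEXYi", "stage": stage,
                             "condition": condition, "replicate": rep,
                             "hatched": hatched, "unhatched": n - hatched,
                             "unfertilized": int(rng.integers(0, 4))})
    return validate_hatch_table(pd.DataFrame(rows, columns=HATCH_COLUMNS))


def synth_hatch_table(rates: dict[str, float], n_embryos: int = 50,
                      n_replicates: int = 2, genotype: str = "synthetic",
                      stage: str = "stage 5", seed: int = 0) -> pd.DataFrame:
    """Binomial HatchTable generator for simulation studies.

    ``rates`` maps condition label -> true hatching probability.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for condition, p in rates.items():
        for rep in range(1, n_replicates + 1):
            hatched = int(rng.binomial(n_embryos, p))
            rows.append({"genotype": genotype, "stage": stage,
                         "condition": condition, "replicate": rep,
                         "hatched": hatched, "unhatched": n_embryos - hatched,
                         "unfertilized": 0})
    return validate_hatch_table(pd.DataFrame(rows, columns=HATCH_COLUMNS))
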