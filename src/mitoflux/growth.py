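"""Serial-passage growth curves and ladder-calibrated mtDNA copy number.

Growth: cells are counted and re-seeded to the original density at each
passage, so the per-passage fold harvest/seed accumulates into a cumulative
log2 growth curve independent of absolute seeding density.  The growth rate
(doublings/day) is the least-squares slope of that curve over a stated day
window (default days 2-6, omitting days 0-2 where drug effects are not yet
fully developed); traces are fitted individually and averaged across
replicates.

Copy number: multiplexed two-channel qPCR (a mitochondrial target such as
MT-ND2 and a nuclear repeat such as AluYb8) is calibrated with dilution
ladders, Ct = intercept + slope * log10(copies).  Per-sample mtDNA/nuclear
copy ratios are expressed relative to a reference sample, which cancels the
arbitrary scale of the nuclear ladder (calibrated against bulk DNA rather
than an absolute standard).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def cumulative_curve(passages: pd.DataFrame) -> pd.DataFrame:
    """Cumulative log2 fold-growth series for one serially passaged trace.

    ``passages`` holds one condition/replicate, ordered by passage, with
    columns (seed_count, harvest_count, interval_days).  Returns a DataFrame
    (day, cum_log2) starting at (0, 0).
    """
    required = {"seed_count", "harvest_count", "interval_days"}
    missing = required - set(passages.columns)
    if missing:
        raise ValueError(f"passage table lacks columns {sorted(missing)}")
    seeds = passages["seed_count"].to_numpy(dtype=float)
    harvests = passages["harvest_count"].to_numpy(dtype=float)
    intervals = passages["interval_days"].to_numpy(dtype=float)
    if (seeds <= 0).any() or (harvests <= 0).any():
        raise ValueError("cell counts must be positive")
    if (intervals <= 0).any():
        raise ValueError("passage intervals must be positive")
    days = np.concatenate([[0.0], np.cumsum(intervals)])
    cum = np.concatenate([[0.0], np.cumsum(np.log2(harvests / seeds))])
    return pd.DataFrame({"day": days, "cum_log2": cum})


def fit_growth_rate(
    curve: pd.DataFrame, window: tuple[float, float] = (2.0, 6.0)
) -> tuple[float, float]:
    """Least-squares (slope, intercept) of cumulative log2 fold vs day.

    Restricted to curve points with day inside the window (inclusive); the
    slope is the growth rate in doublings/day.
    """
    sel = (curve["day"] >= window[0]) & (curve["day"] <= window[1])
    if sel.sum() < 2:
        raise ValueError(
            f"need >= 2 curve points within days {window}, have {int(sel.sum())}"
        )
    x = curve.loc[sel, "day"].to_numpy(dtype=float)
    y = curve.loc[sel, "cum_log2"].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept)


def fit_growth_rates(
    passages: pd.DataFrame, window: tuple[float, float] = (2.0, 6.0)
) -> pd.DataFrame:
    """Per-condition growth rates: fit each replicate trace, then average.

    ``passages`` is long-form with columns (condition, replicate,
    passage_index, seed_count, harvest_count, interval_days).  Returns one row
    per condition with rate_mean (doublings/day), rate_sem and n_replicates.
    """
    rows = []
    for cond, grp in passages.groupby("condition", sort=True):
        slopes = []
        for _, trace in grp.groupby("replicate", sort=True):
            curve = cumulative_curve(trace.sort_values("passage_index"))
            slope, _ = fit_growth_rate(curve, window=window)
            slopes.append(slope)
        arr = np.asarray(slopes, dtype=float)
        rows.append({
            "condition": cond,
            "rate_mean": arr.mean(),
            "rate_sem": arr.std(ddof=1) / math.sqrt(arr.size) if arr.size > 1 else np.nan,
            "n_replicates": arr.size,
        })
    return pd.DataFrame(rows)


@dataclass
class LadderFit:
    """Dilution-ladder calibration: Ct = intercept + slope * log10(copies)."""

    slope: float
    intercept: float
    efficiency: float   # per-cycle amplification factor minus 1; 1.0 = doubling

    def copies_of(self, ct) -> float | np.ndarray:
        out = 10.0 ** ((np.asarray(ct, dtype=float) - self.intercept) / self.slope)
        return float(out) if np.isscalar(ct) else out


def ladder_fit(copies, ct) -> LadderFit:
    """Fit a qPCR dilution ladder by least squares of Ct vs log10(copies).

    Requires >= 3 points spanning >= 2 decades; a non-negative slope means the
    ladder did not amplify and is an error.  Efficiency is
    E = 10^(-1/slope) - 1 (E = 1 for perfect doubling, slope ~ -3.3219).
    """
    x = np.log10(np.asarray(copies, dtype=float))
    y = np.asarray(ct, dtype=float)
    if x.size != y.size:
        raise ValueError("copies and Ct differ in length")
    if np.unique(x).size < 3:
        raise ValueError("ladder needs >= 3 distinct points")
    if x.max() - x.min() < 2.0:
        raise ValueError("ladder must span >= 2 log10 units")
    if not np.isfinite(y).all() or (y <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError("non-amplifying ladder (slope >= 0)")
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return LadderFit(slope=float(fit.slope), intercept=float(fit.intercept),
                     efficiency=float(efficiency))


def relative_mtdna(
    samples: pd.DataFrame,
    target_ladder: LadderFit,
    nuclear_ladder: LadderFit,
    reference_sample: str,
) -> pd.DataFrame:
    """Per-sample mtDNA copy number relative to a reference sample.

    ``samples`` has columns (sample_id, ct_target, ct_nuclear); replicate
    wells of the same sample are combined by mean Ct.  Each sample's
    target/nuclear copy ratio is divided by the reference sample's ratio, so
    the reference maps to exactly 1.0 and any common affine shift of both
    ladders cancels.
    """
    required = {"sample_id", "ct_target", "ct_nuclear"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table lacks columns {sorted(missing)}")
    if samples[["ct_target", "ct_nuclear"]].isna().to_numpy().any():
        raise ValueError("missing Ct channel for at least one well")
    mean_ct = samples.groupby("sample_id", sort=True)[["ct_target", "ct_nuclear"]].mean()
    if reference_sample not in mean_ct.index:
        raise ValueError(f"reference sample {reference_sample!r} not present")
    ratio = (
        target_ladder.copies_of(mean_ct["ct_target"].to_numpy())
        / nuclear_ladder.copies_of(mean_ct["ct_nuclear"].to_numpy())
    )
    ratio = pd.Series(ratio, index=mean_ct.index)
    rel = ratio / ratio.loc[reference_sample]
    return pd.DataFrame({
        "sample_id": mean_ct.index,
        "relative_copy_number": rel.to_numpy(dtype=float),
    }).reset_index(drop=True)
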