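"""Time-course expression filtering, ranking, and pooled comparison.

Probesets from a treatment time course (linear-scale summarized intensities,
one array per time point, with >= 2 pre-treatment samples) are filtered by
three criteria before any downstream analysis:

(a) variation  — standard deviation across samples at least a fraction of the
                 probeset mean (default 7.5%), removing unchanging probesets;
(b) signal     — maximum intensity at least a floor (default 50), removing
                 probesets without usable signal;
(c) band power — total power in low-frequency Fourier coefficients (default
                 k in {2..6}) at least that in a high-frequency band (default
                 k in {7..12}), removing probesets dominated by high-frequency
                 noise that cannot reflect a smooth treatment response.

Genes are then ordered by the ratio of their mean treated intensity (days 1-10
by default) to their mean untreated intensity; normalized ranks
(i - 0.5)/N feed the motif-enrichment stage.  A pooled late-vs-pre comparison
(days 5-7 against days -1/0) gives per-probeset fold changes and Welch t
statistics on log2 intensities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: sentinel magnitude used when a pooled comparison has zero variance
T_CAP = 1e6


@dataclass
class ExpressionTimeCourse:
    """Probesets x samples intensity matrix with per-sample day labels and
    treated flags."""

    values: pd.DataFrame          # index: probeset ids; one column per sample
    days: np.ndarray              # float day label per column (<= 0 = pre)
    treated: np.ndarray           # bool per column

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.treated = np.asarray(self.treated, dtype=bool)
        if len(self.days) != self.values.shape[1] or len(self.treated) != self.values.shape[1]:
            raise ValueError("days/treated must have one entry per sample column")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression intensities must be non-negative")
        if int((~self.treated).sum()) < 2:
            raise ValueError("at least two untreated columns are required")

    @property
    def probesets(self) -> pd.Index:
        return self.values.index

    def columns_where(self, treated: bool | None = None,
                      day_min: float = -math.inf,
                      day_max: float = math.inf) -> np.ndarray:
        """Boolean column selector by treated flag and day range."""
        sel = (self.days >= day_min) & (self.days <= day_max)
        if treated is not None:
            sel &= self.treated == treated
        return sel

    def to_tsv(self, path) -> None:
        """Write as TSV with a two-row header (day label, treated flag)."""
        out = self.values.copy()
        out.columns = pd.MultiIndex.from_arrays(
            [self.days, self.treated.astype(int)], names=["day", "treated"]
        )
        out.index.name = "probeset"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTimeCourse":
        raw = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0,
                          float_precision="round_trip")
        days = np.array([float(d) for d, _ in raw.columns])
        treated = np.array([bool(int(float(t))) for _, t in raw.columns])
        raw.columns = [f"s{i}" for i in range(raw.shape[1])]
        return cls(values=raw, days=days, treated=treated)


@dataclass
class FilterCriteria:
    sd_frac_min: float = 0.075
    signal_floor: float = 50.0
    low_band: frozenset = field(default_factory=lambda: frozenset(range(2, 7)))
    high_band: frozenset = field(default_factory=lambda: frozenset(range(7, 13)))

    def __post_init__(self) -> None:
        self.low_band = frozenset(self.low_band)
        self.high_band = frozenset(self.high_band)
        if self.sd_frac_min <= 0:
            raise ValueError("sd_frac_min must be positive")
        if self.low_band & self.high_band:
            raise ValueError("frequency bands must be disjoint")


def band_power(series, band) -> float:
    """Total DFT power in a set of coefficient indices.

    X_k = sum_n x_n exp(-2 pi i k n / N); returns sum over k in band of
    |X_k|^2.  Indices are 0-based bins of the full complex DFT.
    """
    x = np.asarray(series, dtype=float)
    band = sorted(int(k) for k in band)
    if band and band[-1] >= len(x):
        raise ValueError(
            f"band index {band[-1]} out of range for series of length {len(x)}"
        )
    spectrum = np.fft.fft(x)
    return float(np.sum(np.abs(spectrum[band]) ** 2))


def filter_probesets(
    tc: ExpressionTimeCourse, criteria: FilterCriteria | None = None
) -> pd.DataFrame:
    """Apply the three filter criteria; returns per-probeset pass flags.

    Columns: variation, signal, band, kept (all boolean).  A zero-mean
    probeset fails the variation criterion by definition.  Samples are taken
    in day order for the Fourier criterion.
    """
    criteria = criteria or FilterCriteria()
    order = np.argsort(tc.days, kind="stable")
    mat = tc.values.to_numpy(dtype=float)[:, order]
    n = mat.shape[1]
    if max(criteria.low_band | criteria.high_band) >= n:
        raise ValueError("band indices exceed number of time points")

    means = mat.mean(axis=1)
    sds = mat.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        variation = np.where(means > 0, sds >= criteria.sd_frac_min * means, False)
    signal = mat.max(axis=1) >= criteria.signal_floor

    spectrum = np.fft.fft(mat, axis=1)
    power = np.abs(spectrum) ** 2
    low = power[:, sorted(criteria.low_band)].sum(axis=1)
    high = power[:, sorted(criteria.high_band)].sum(axis=1)
    band = low >= high

    flags = pd.DataFrame(
        {"variation": variation, "signal": signal, "band": band},
        index=tc.probesets,
    )
    flags["kept"] = flags.all(axis=1)
    return flags


def rank_genes(
    tc: ExpressionTimeCourse,
    treated_day_range: tuple[float, float] = (1.0, 10.0),
    keep: pd.Index | None = None,
) -> pd.DataFrame:
    """Order genes by mean treated / mean untreated intensity ratio.

    Returns a DataFrame (gene_id, score, rank, norm_rank) in descending score
    order; rank 1 is the most upregulated gene.  Normalized rank is
    (i - 0.5)/N.  Ties are broken by gene id (lexicographic) for determinism.
    Probesets with zero untreated mean are excluded with a warning.
    """
    treated_sel = tc.columns_where(treated=True, day_min=treated_day_range[0],
                                   day_max=treated_day_range[1])
    untreated_sel = tc.columns_where(treated=False)
    if not treated_sel.any():
        raise ValueError("no treated columns in the requested day range")
    if not untreated_sel.any():
        raise ValueError("no untreated columns")
    values = tc.values if keep is None else tc.values.loc[keep]
    t_mean = values.to_numpy(dtype=float)[:, treated_sel].mean(axis=1)
    u_mean = values.to_numpy(dtype=float)[:, untreated_sel].mean(axis=1)
    ok = u_mean > 0
    if not ok.all():
        logger.warning(
            "%d probesets excluded from ranking (zero untreated mean)",
            int((~ok).sum()),
        )
    frame = pd.DataFrame(
        {"gene_id": values.index[ok], "score": t_mean[ok] / u_mean[ok]}
    )
    frame = frame.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    n = len(frame)
    frame["rank"] = np.arange(1, n + 1)
    frame["norm_rank"] = (frame["rank"] - 0.5) / n
    return frame


def pooled_comparison(
    tc: ExpressionTimeCourse,
    late_days: tuple[float, float] = (5.0, 7.0),
    pre_days: tuple[float, float] = (-1.0, 0.0),
) -> pd.DataFrame:
    """Fold change and Welch t statistic, pooled late vs pre-treatment days.

    The t statistic is computed on log2 intensities with unequal variances.
    A comparison with zero pooled variance is capped at +/- T_CAP rather than
    reported as infinite.
    """
    late_sel = tc.columns_where(treated=True, day_min=late_days[0],
                                day_max=late_days[1])
    pre_sel = tc.columns_where(treated=False, day_min=pre_days[0],
                               day_max=pre_days[1])
    if late_sel.sum() < 2 or pre_sel.sum() < 2:
        raise ValueError("each pool needs at least two sample columns")
    mat = tc.values.to_numpy(dtype=float)
    late = mat[:, late_sel]
    pre = mat[:, pre_sel]
    with np.errstate(divide="ignore"):
        log_late = np.log2(np.maximum(late, 1e-12))
        log_pre = np.log2(np.maximum(pre, 1e-12))
    pre_mean = pre.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = np.where(pre_mean > 0, late.mean(axis=1) / pre_mean, np.nan)
    res = stats.ttest_ind(log_late, log_pre, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    diff = log_late.mean(axis=1) - log_pre.mean(axis=1)
    bad = ~np.isfinite(t)
    t[bad & (diff > 0)] = T_CAP
    t[bad & (diff < 0)] = -T_CAP
    t[bad & (diff == 0)] = 0.0
    return pd.DataFrame(
        {"fold": fold, "t_stat": t}, index=tc.probesets
    )
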