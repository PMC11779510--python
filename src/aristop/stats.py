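"""Pointwise inhibition statistics.

The headline computation: a paired t test at every epoch time point across
participants' condition-mean traces, Benjamini-Hochberg FDR at q = 0.05
within each comparison, and the longest contiguous interval in which
strictly more than 90% of time points are significant. Also the paired-t
power function (noncentral t) used for the post hoc power statement.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .errors import DegenerateInputError, UsageError
from .types import EpochMatrix, PointwiseTestResult, SuppressionInterval

logger = logging.getLogger(__name__)

__all__ = [
    "pointwise_paired_t", "bh_fdr", "longest_qualified_interval",
    "paired_t_power", "cohens_d_paired",
]


def pointwise_paired_t(a: EpochMatrix, b: EpochMatrix,
                       config: AnalysisConfig | None = None,
                       ) -> PointwiseTestResult:
    """Paired t test (a - b) per time point across participants.

    Rows must be matched participants. Time points with zero variance of the
    paired differences get NaN p-values (logged) and are excluded from the
    FDR ranking.
    """
    config = config or AnalysisConfig()
    if a.values.shape != b.values.shape:
        raise UsageError("epoch matrices must share participants and samples")
    n = a.values.shape[0]
    if n < 2:
        raise UsageError("paired test needs >= 2 participants")
    if a.participants and b.participants and a.participants != b.participants:
        raise UsageError("participant order differs between conditions")

    diffs = a.values - b.values
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    # exactly equal conditions are a true null (t = 0, p = 1); a constant
    # nonzero difference leaves the test undefined (p absent)
    t = np.where(sd == 0.0, np.where(mean == 0.0, 0.0, np.nan), t)
    if np.isnan(t).any():
        logger.warning("%d time points with zero-variance differences",
                       int(np.isnan(t).sum()))
    if config.sided == "two-sided":
        p = 2.0 * sp_stats.t.sf(np.abs(t), df)
    elif config.sided == "less":
        p = sp_stats.t.cdf(t, df)
    else:
        p = sp_stats.t.sf(t, df)
    return PointwiseTestResult(times=a.times, t_values=t, p_values=p,
                               fdr_mask=bh_fdr(p, config.q), df=df,
                               q=config.q)


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at level ``q``.

    Rejects all p <= p(k*) where k* is the largest rank k with
    p(k) <= q k / m. NaN entries are excluded from the ranking and never
    rejected.
    """
    p = np.asarray(p_values, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    valid = ~np.isnan(p)
    if valid.any():
        if (p[valid] < 0).any() or (p[valid] > 1).any():
            raise UsageError("p-values must lie in [0, 1]")
        mask[valid] = multipletests(p[valid], alpha=q, method="fdr_bh")[0]
    return mask


def longest_qualified_interval(mask, min_prop: float = 0.9,
                               times: np.ndarray | None = None,
                               ) -> SuppressionInterval | None:
    """Longest contiguous interval with strictly more than ``min_prop`` of
    its points significant; ties broken toward the earliest onset.

    Endpoints are reported on ``times`` (ms relative to the stop signal) when
    given, else as sample indices. The qualification test is exact integer
    arithmetic (no float thresholds). Returns ``None`` when no interval — not
    even a single significant point — qualifies.
    """
    m = np.asarray(mask, dtype=bool).astype(np.int64)
    n = m.size
    if n == 0:
        return None
    # fraction > min_prop  <=>  denom * count > num * length, integer-exact
    # (min_prop snapped to a small rational so products stay within int64)
    frac = Fraction(min_prop).limit_denominator(1_000_000)
    num, denom = frac.numerator, frac.denominator
    c = np.concatenate([[0], np.cumsum(m)])
    for length in range(n, 0, -1):
        counts = c[length:] - c[:-length]
        ok = np.flatnonzero(denom * counts > num * length)
        if ok.size:
            start = int(ok[0])
            stop = start + length - 1  # inclusive
            prop = counts[start] / length
            if times is not None:
                onset, offset = float(times[start]), float(times[stop])
            else:
                onset, offset = float(start), float(stop)
            return SuppressionInterval(onset=onset, offset=offset,
                                       n_points=length,
                                       prop_significant=float(prop))
    return None


def paired_t_power(n: int, d: float, alpha: float = 0.05,
                   sided: str = "two-sided") -> float:
    """Power of a paired (one-sample-on-differences) t test.

    ``d`` is the paired Cohen's d (mean difference / SD of differences); the
    test statistic is noncentral t with df = n - 1 and noncentrality
    d * sqrt(n).
    """
    if n < 2:
        raise UsageError("power requires n >= 2")
    if d < 0 or not 0.0 < alpha < 1.0:
        raise UsageError("d must be >= 0 and alpha in (0, 1)")
    df = n - 1
    nc = d * np.sqrt(n)
    if sided == "two-sided":
        tc = sp_stats.t.ppf(1.0 - alpha / 2.0, df)
        power = (1.0 - sp_stats.nct.cdf(tc, df, nc)
                 + sp_stats.nct.cdf(-tc, df, nc))
    elif sided == "greater":
        tc = sp_stats.t.ppf(1.0 - alpha, df)
        power = 1.0 - sp_stats.nct.cdf(tc, df, nc)
    else:
        raise UsageError(f"unsupported sidedness {sided!r}")
    return float(power)


def cohens_d_paired(differences) -> float:
    """Paired Cohen's d: mean of the differences over their sample SD."""
    x = np.asarray(differences, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("cohens_d_paired needs >= 2 differences")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("zero SD of differences")
    return float(x.mean() / sd)
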