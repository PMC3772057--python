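"""Two-group expression screening: quantile normalization, t-test, SNR rank.

The screening recipe applied to each public expression dataset is small and
fixed: quantile-normalize the intensity matrix so every sample shares one
intensity distribution, test each gene for a group difference with an
unpaired (Welch) t-test, keep genes with nominal p < 0.05, and rank the
survivors by the absolute signal-to-noise ratio

    SNR = (mean_group1 - mean_group2) / (sd_group1 + sd_group2),

the classical two-group gene-ranking statistic.  Genes of special interest
can be looked up in the output whether or not they pass the screen, since
every gene's t, p and SNR are reported alongside the rank column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["quantile_normalize", "screen_and_rank"]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean empirical distribution.

    Each column's k-th order statistic is replaced by the across-column
    mean of k-th order statistics.  Ties within a column receive the mean
    of the reference values their positions span (the dense dialect would
    instead repeat a single value; dialects differ, so the choice is
    documented here).  Idempotent: a second pass is a no-op.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    x = matrix.to_numpy(dtype=float)
    n, m = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    mu = sorted_x.mean(axis=1)  # reference distribution: mean order statistics
    # Prefix sums let a tied block [i..j] take mean(mu[i..j]) in O(1).
    mu_cum = np.concatenate([[0.0], np.cumsum(mu)])
    out = np.empty_like(x)
    for col in range(m):
        xs = sorted_x[:, col]
        vals = np.empty(n)
        i = 0
        while i < n:
            j = i
            while j + 1 < n and xs[j + 1] == xs[i]:
                j += 1
            vals[i : j + 1] = (mu_cum[j + 1] - mu_cum[i]) / (j - i + 1)
            i = j + 1
        out[order[:, col], col] = vals
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def screen_and_rank(
    matrix: pd.DataFrame,
    groups: pd.Series,
    alpha_screen: float = 0.05,
    sd_mode: str = "sum",
    signed: bool = False,
) -> pd.DataFrame:
    """Welch-test every gene, then rank the significant ones by |SNR|.

    Parameters
    ----------
    matrix
        Genes x samples intensities.
    groups
        Sample -> group label; exactly two groups, each with >= 2 samples.
    alpha_screen
        Nominal screening level (genes with p < alpha_screen get a rank).
    sd_mode
        "sum" (default): SNR denominator sd1 + sd2; "pooled": the pooled
        two-sample SD.
    signed
        If True rank by signed SNR descending instead of |SNR|.

    Returns a frame indexed by gene with columns ``t_statistic, p_value,
    snr, passed, rank`` (rank is NaN for genes that fail the screen or have
    an undefined SNR; ranks are 1..n_ranked, 1 = strongest).
    """
    if not 0.0 < alpha_screen < 1.0:
        raise ValueError("alpha_screen must be in (0,1)")
    labels = np.sort(pd.unique(groups.to_numpy()))  # lexicographic: group 1 = smaller label
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    g1 = matrix.loc[:, groups[groups == labels[0]].index].to_numpy(dtype=float)
    g2 = matrix.loc[:, groups[groups == labels[1]].index].to_numpy(dtype=float)
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValueError("both groups need >= 2 samples")
    t, p = stats.ttest_ind(g1, g2, axis=1, equal_var=False)
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    s1 = g1.std(axis=1, ddof=1)
    s2 = g2.std(axis=1, ddof=1)
    if sd_mode == "sum":
        denom = s1 + s2
    elif sd_mode == "pooled":
        n1, n2 = g1.shape[1], g2.shape[1]
        denom = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(denom > 0, (m1 - m2) / np.where(denom > 0, denom, 1.0), np.nan)
    out = pd.DataFrame(
        {
            "t_statistic": t,
            "p_value": p,
            "snr": snr,
            "passed": p < alpha_screen,
        },
        index=matrix.index,
    )
    rankable = out["passed"] & np.isfinite(out["snr"])
    key = out.loc[rankable, "snr"] if signed else out.loc[rankable, "snr"].abs()
    # rank 1 = strongest; ties broken by gene order for determinism
    ranks = key.rank(method="first", ascending=False)
    out["rank"] = np.nan
    out.loc[rankable, "rank"] = ranks
    return out
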