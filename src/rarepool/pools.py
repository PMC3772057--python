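"""Pooled-sequencing allele-frequency estimation and variant triage.

A DNA pool of N diploid individuals carries a latent alternate-allele count
k in {0, ..., 2N}.  Each sequencing read drawn from the pool reports the
alternate allele with probability

    q(k) = k/2N * (1 - e) + (1 - k/2N) * e,

where e is the per-read miscall rate.  :func:`estimate_pool_maf` maximizes
the binomial read likelihood over the 2N + 1 candidate counts; because the
binomial log-likelihood is strictly concave in q and q(k) is affine
increasing in k (for e < 1/2), the likelihood is unimodal in k and the
maximizer is one of the two lattice points bracketing the continuous
optimum — which is how the estimator avoids scanning all candidates.

The module also provides the discovery-stage bookkeeping: variant class
summaries (non-synonymous/synonymous and transition/transversion ratios,
per-sample coverage) and the ordered follow-up filter chain
(validation -> singleton -> MHC -> functional class -> common frequency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Variant",
    "ClassSummary",
    "PoolMafEstimate",
    "MHC_REGION_B36",
    "estimate_pool_maf",
    "estimate_pileup_mafs",
    "maf_concordance",
    "summarize_variant_classes",
    "filter_for_followup",
    "amplicon_success_rate",
]

FUNC_CLASSES = frozenset({"missense", "nonsense", "synonymous", "splice", "other"})

# Extended MHC on chromosome 6, build-36 coordinates.
MHC_REGION_B36 = ("6", 25_000_000, 34_000_000)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass(frozen=True)
class Variant:
    """A biallelic SNV with its functional class and discovery flags."""

    chrom: str
    pos: int
    ref: str
    alt: str
    func_class: str = "other"
    validated: bool = True
    singleton: bool = False
    in_mhc: bool = False
    discovery_maf: float = 0.0
    variant_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("position is 1-based, must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(f"unknown functional class {self.func_class!r}")
        if not 0.0 <= self.discovery_maf <= 1.0:
            raise ValueError("discovery_maf must be in [0,1]")
        if self.variant_id is None:
            object.__setattr__(
                self, "variant_id", f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"
            )

    @property
    def is_transition(self) -> bool:
        pair = {self.ref, self.alt}
        return pair <= _PURINES or pair <= _PYRIMIDINES


@dataclass(frozen=True)
class ClassSummary:
    """Coding-variant class counts and the standard quality ratios.

    ``ns_s_ratio`` is (missense + nonsense) / synonymous and ``titv_ratio``
    is transitions / transversions over all SNVs; either is None when its
    denominator is zero.  Ratios are reported at one decimal via
    :meth:`rounded`; full precision is kept here.
    """

    n_total_coding: int
    n_missense: int
    n_synonymous: int
    n_nonsense: int
    n_splice: int
    ns_s_ratio: float | None
    titv_ratio: float | None
    per_sample_coverage: float | None

    def rounded(self) -> dict:
        """Summary with ratios at one decimal, as printed in reports."""
        rnd = lambda x: None if x is None else round(x, 1)
        return {
            "n_total_coding": self.n_total_coding,
            "n_missense": self.n_missense,
            "n_synonymous": self.n_synonymous,
            "n_nonsense": self.n_nonsense,
            "n_splice": self.n_splice,
            "ns_s_ratio": rnd(self.ns_s_ratio),
            "titv_ratio": rnd(self.titv_ratio),
            "per_sample_coverage": rnd(self.per_sample_coverage),
        }


@dataclass(frozen=True)
class PoolMafEstimate:
    """MLE of a pool's alternate-allele count and the implied frequency.

    ``no_data`` marks a zero-depth site: the estimate is undefined there,
    not zero.
    """

    k: int | None
    maf: float | None
    no_data: bool = False


def _read_loglik(k: int, n_chrom: int, n_ref: int, n_alt: int, e: float) -> float:
    """Binomial log-likelihood of (n_ref, n_alt) reads at allele count k."""
    q = (k / n_chrom) * (1 - e) + (1 - k / n_chrom) * e
    if q == 0.0:
        return 0.0 if n_alt == 0 else -math.inf
    if q == 1.0:
        return 0.0 if n_ref == 0 else -math.inf
    return n_alt * math.log(q) + n_ref * math.log(1 - q)


def estimate_pool_maf(
    n_ref: int, n_alt: int, pool_chromosomes: int, error_rate: float = 0.0
) -> PoolMafEstimate:
    """Maximum-likelihood pool allele count from ref/alt read counts.

    Parameters
    ----------
    n_ref, n_alt
        Reads supporting the reference and alternate allele.
    pool_chromosomes
        2N, the number of chromosomes in the pool.
    error_rate
        Per-read miscall probability e in [0, 0.5).

    Returns the count k in {0..2N} maximizing the Binomial(depth, q(k))
    likelihood, with ties broken toward smaller k, and maf = k / 2N.
    """
    if n_ref < 0 or n_alt < 0:
        raise ValueError("read counts must be non-negative")
    if pool_chromosomes < 1:
        raise ValueError("pool must contain at least one chromosome")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    depth = n_ref + n_alt
    if depth == 0:
        return PoolMafEstimate(k=None, maf=None, no_data=True)
    m = pool_chromosomes
    e = error_rate
    # Continuous MLE of the read-level alt fraction, inverted through q(k).
    q_hat = n_alt / depth
    f_hat = (q_hat - e) / (1 - 2 * e)
    f_hat = min(max(f_hat, 0.0), 1.0)
    center = f_hat * m
    # Unimodal in k: only the lattice points bracketing the optimum compete.
    candidates = sorted({int(math.floor(center)), int(math.ceil(center))})
    candidates = [k for k in candidates if 0 <= k <= m]
    best_k, best_ll = None, -math.inf
    for k in candidates:  # ascending: strict '>' keeps the smaller k on ties
        ll = _read_loglik(k, m, n_ref, n_alt, e)
        if ll > best_ll:
            best_k, best_ll = k, ll
    return PoolMafEstimate(k=best_k, maf=best_k / m)


def estimate_pileup_mafs(pileup: pd.DataFrame, error_rate: float = 0.0) -> pd.DataFrame:
    """Per-variant pooled MAF estimates from a tidy pool pileup.

    Expects columns ``variant_id, pool_id, n_ref_reads, n_alt_reads,
    pool_size``.  Each pool contributes its MLE allele count; the variant's
    estimate is total estimated alt alleles over total chromosomes across
    pools with data.  Returns a frame indexed by variant with columns
    ``k_total, n_chromosomes, maf`` (NaN when no pool had reads).
    """
    required = {"variant_id", "pool_id", "n_ref_reads", "n_alt_reads", "pool_size"}
    missing = required - set(pileup.columns)
    if missing:
        raise ValueError(f"pileup is missing columns: {sorted(missing)}")
    rows = []
    for vid, grp in pileup.groupby("variant_id", sort=False):
        k_total, chrom_total = 0, 0
        for row in grp.itertuples(index=False):
            est = estimate_pool_maf(
                row.n_ref_reads, row.n_alt_reads, 2 * row.pool_size, error_rate
            )
            if not est.no_data:
                k_total += est.k
                chrom_total += 2 * row.pool_size
        maf = k_total / chrom_total if chrom_total else float("nan")
        rows.append((vid, k_total, chrom_total, maf))
    return pd.DataFrame(
        rows, columns=["variant_id", "k_total", "n_chromosomes", "maf"]
    ).set_index("variant_id")


def maf_concordance(
    estimates, truths, thresholds=(0.0,)
) -> dict[float, float | None]:
    """Squared Pearson correlation between estimated and reference MAFs.

    For each threshold t, R^2 is computed over pairs whose reference MAF is
    >= t; bins with fewer than 2 pairs or zero variance yield None.  Mirrors
    the standard sequence-vs-genotype frequency concordance check.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape or est.ndim != 1:
        raise ValueError("estimates and truths must be 1-D of equal length")
    if est.size < 2:
        raise ValueError("need at least 2 pairs")
    out: dict[float, float | None] = {}
    for t in thresholds:
        sel = tru >= t
        keep = sel & np.isfinite(est) & np.isfinite(tru)
        x, y = est[keep], tru[keep]
        if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
            out[float(t)] = None
            continue
        r = stats.pearsonr(x, y).statistic
        out[float(t)] = float(r * r)
    return out


def summarize_variant_classes(
    variants,
    pool_coverage: float | None = None,
    pool_size: int | None = None,
) -> ClassSummary:
    """Count coding variants by class and compute NS/S, Ti/Tv and coverage.

    ``n_total_coding`` counts missense + synonymous + nonsense + splice;
    Ti/Tv is over all single-base variants regardless of class.
    Per-sample coverage is pool coverage divided by pool size when both are
    given.
    """
    counts = {"missense": 0, "synonymous": 0, "nonsense": 0, "splice": 0}
    n_ti = n_tv = 0
    for v in variants:
        if v.func_class in counts:
            counts[v.func_class] += 1
        if len(v.ref) == 1 and len(v.alt) == 1:
            if v.is_transition:
                n_ti += 1
            else:
                n_tv += 1
    ns = counts["missense"] + counts["nonsense"]
    ns_s = ns / counts["synonymous"] if counts["synonymous"] else None
    titv = n_ti / n_tv if n_tv else None
    cov = (
        pool_coverage / pool_size
        if pool_coverage is not None and pool_size
        else None
    )
    return ClassSummary(
        n_total_coding=sum(counts.values()),
        n_missense=counts["missense"],
        n_synonymous=counts["synonymous"],
        n_nonsense=counts["nonsense"],
        n_splice=counts["splice"],
        ns_s_ratio=ns_s,
        titv_ratio=titv,
        per_sample_coverage=cov,
    )


# Follow-up triage, applied in order; a variant is rejected for the FIRST
# matching reason.
_FILTER_CHAIN = (
    ("not_validated", lambda v, thr: not v.validated),
    ("singleton", lambda v, thr: v.singleton),
    ("in_mhc", lambda v, thr: v.in_mhc),
    ("not_nonsynonymous", lambda v, thr: v.func_class not in ("missense", "nonsense", "splice")),
    ("common", lambda v, thr: v.discovery_maf > thr),
)


def filter_for_followup(
    variants, common_threshold: float = 0.05
) -> tuple[list[Variant], list[tuple[Variant, str]]]:
    """Select rare non-synonymous validated variants for follow-up genotyping.

    Exclusions, in order (first match recorded as the reason): variants that
    did not validate; singletons; MHC-region variants; variants that are not
    missense/nonsense/splice; variants with discovery frequency strictly
    above ``common_threshold`` (a variant at exactly the threshold is kept).

    Returns (selected, rejected) where rejected pairs each variant with its
    rejection reason.  selected + rejected partition the input.
    """
    selected: list[Variant] = []
    rejected: list[tuple[Variant, str]] = []
    for v in variants:
        for reason, hit in _FILTER_CHAIN:
            if hit(v, common_threshold):
                rejected.append((v, reason))
                break
        else:
            selected.append(v)
    return selected, rejected


def amplicon_success_rate(n_successful: int, n_designed: int) -> float:
    """Fraction of designed amplicons that amplified, in [0, 1]."""
    if n_designed < 1 or n_successful < 0 or n_successful > n_designed:
        raise ValueError("need 0 <= n_successful <= n_designed, n_designed >= 1")
    return n_successful / n_designed
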