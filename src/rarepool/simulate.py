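"""Synthetic data generators for stratified rare-variant association studies.

Everything downstream of this module — pooled-sequencing frequency
estimation, the stratified permutation association test, power analysis and
two-group expression ranking — is exercised on data produced here, so the
generators are first-class, validated code rather than test scaffolding.

The genotype model is the allelic (multiplicative-on-odds) disease model:
controls in stratum ``s`` carry the minor allele at frequency ``p0[s]`` and
cases at

    p1 = OR * p0 / (1 + p0 * (OR - 1)),

which is the case allele frequency implied by an allelic odds ratio ``OR``
at control frequency ``p0``.  Genotypes are Binomial(2, p) per individual,
i.e. Hardy-Weinberg within each phenotype-by-stratum cell, with no linkage
disequilibrium or relatedness.

Pooled sequencing is modelled as: a pool of N diploid individuals carries
``k`` alternate alleles out of 2N chromosomes (the sum of its members'
genotypes); read depth is Poisson around the target coverage; each read
reports the alternate allele with probability ``k/2N * (1-e) + (1-k/2N) * e``
where ``e`` is the per-read miscall rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StratumSpec",
    "CohortSpec",
    "PoolSpec",
    "ExpressionSpec",
    "CohortData",
    "ExpressionData",
    "case_allele_frequency",
    "simulate_cohorts",
    "simulate_confounded_null",
    "simulate_pools",
    "pooled_true_allele_counts",
    "simulate_expression",
]

MISSING = -1  # sentinel for a missing genotype in int8 matrices


def case_allele_frequency(p0: float, odds_ratio: float) -> float:
    """Case minor-allele frequency implied by an allelic odds ratio.

    Solves odds(case)/odds(control) = OR for the case frequency:
    ``p1 = OR*p0 / (1 + p0*(OR-1))``.  Always in [0, 1] for p0 in [0, 1]
    and OR > 0.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"control allele frequency must be in [0,1], got {p0}")
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    return odds_ratio * p0 / (1.0 + p0 * (odds_ratio - 1.0))


@dataclass(frozen=True)
class StratumSpec:
    """One case-control sub-cohort: label, sample sizes and control MAF.

    ``p0`` may be a scalar (every simulated variant shares it) or a sequence
    of per-variant control frequencies of length ``n_variants``.
    """

    label: str
    n_cases: int
    n_controls: int
    p0: float | Sequence[float]

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("sample counts must be non-negative")
        p = np.atleast_1d(np.asarray(self.p0, dtype=float))
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("control allele frequency must be in [0,1]")


@dataclass(frozen=True)
class CohortSpec:
    """Stratified case-control genotype simulation parameters.

    Parameters
    ----------
    strata
        Sub-cohorts, each with its own sizes and baseline frequency.
    odds_ratio
        Shared allelic odds ratio (cases vs controls), > 0.  1.0 is the null.
    missing_rate
        Per-genotype probability of being missing, completely at random.
    n_variants
        Number of independent variants to draw.
    seed
        Seed for a dedicated generator; identical spec + seed gives
        byte-identical output.
    """

    strata: tuple[StratumSpec, ...]
    odds_ratio: float = 1.0
    missing_rate: float = 0.0
    n_variants: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "strata", tuple(self.strata))
        if not self.strata:
            raise ValueError("at least one stratum is required")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0,1)")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")


@dataclass(frozen=True)
class PoolSpec:
    """Pooled-sequencing experiment parameters.

    Defaults follow the discovery design this package targets: pools of 50
    diploid individuals sequenced to roughly 1575x mean coverage per pool
    (31.5x per sample).
    """

    n_individuals_per_pool: int = 50
    n_pools_case: int | None = None  # None: as many disjoint pools as fit
    n_pools_control: int | None = None
    coverage_mean: float = 1575.0
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals_per_pool < 1:
            raise ValueError("pool size must be >= 1")
        for n in (self.n_pools_case, self.n_pools_control):
            if n is not None and n < 0:
                raise ValueError("pool counts must be non-negative")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


@dataclass(frozen=True)
class ExpressionSpec:
    """Two-group expression matrix with a known truth set.

    ``n_differential`` genes are mean-shifted by ``effect_size`` standard
    deviations in group 2; the rest are exchangeable noise.
    """

    n_genes: int = 1000
    n_samples_per_group: int = 10
    n_differential: int = 50
    effect_size: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_differential > self.n_genes:
            raise ValueError("n_differential cannot exceed n_genes")
        if self.n_samples_per_group < 1:
            raise ValueError("need at least one sample per group")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")


@dataclass
class CohortData:
    """Genotypes with phenotype and stratum labels.

    ``genotypes`` is (n_variants, n_samples) int8 with entries 0/1/2 counting
    minor (alternate) alleles and -1 for missing.  ``is_case`` and
    ``stratum`` are per-sample.
    """

    genotypes: np.ndarray
    is_case: np.ndarray
    stratum: np.ndarray
    sample_ids: np.ndarray
    variant_ids: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        self.stratum = np.asarray(self.stratum)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (variants x samples)")
        n = self.genotypes.shape[1]
        if not (len(self.is_case) == len(self.stratum) == len(self.sample_ids) == n):
            raise ValueError("per-sample arrays must match genotype columns")
        if len(self.variant_ids) != self.genotypes.shape[0]:
            raise ValueError("variant_ids must match genotype rows")

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    @property
    def strata_labels(self) -> np.ndarray:
        """Stratum labels in order of first appearance."""
        _, idx = np.unique(self.stratum, return_index=True)
        return self.stratum[np.sort(idx)]

    def variant_index(self, variant_id: str) -> int:
        hits = np.flatnonzero(self.variant_ids == variant_id)
        if hits.size == 0:
            raise KeyError(f"variant {variant_id!r} not present in cohort data")
        return int(hits[0])

    def allele_frequency(self, variant: int, mask: np.ndarray | None = None) -> float:
        """Minor-allele frequency among non-missing genotypes (optionally masked)."""
        g = self.genotypes[variant]
        if mask is not None:
            g = g[mask]
        g = g[g != MISSING]
        if g.size == 0:
            return float("nan")
        return float(g.sum() / (2 * g.size))


@dataclass
class ExpressionData:
    """Gene-by-sample intensities, group labels and the differential truth set."""

    matrix: pd.DataFrame  # genes x samples
    groups: pd.Series  # sample -> group label ("g1"/"g2")
    truth: np.ndarray  # gene ids that are truly differential


def _stratum_frequencies(stratum: StratumSpec, odds_ratio: float, n_variants: int):
    p0 = np.broadcast_to(np.atleast_1d(np.asarray(stratum.p0, dtype=float)), (n_variants,))
    p1 = odds_ratio * p0 / (1.0 + p0 * (odds_ratio - 1.0))
    return p0, p1


def simulate_cohorts(spec: CohortSpec) -> CohortData:
    """Draw stratified case-control genotypes under the allelic odds model.

    Controls in each stratum are Binomial(2, p0); cases are Binomial(2, p1)
    with p1 from :func:`case_allele_frequency`.  Missing genotypes are
    inserted independently at ``spec.missing_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    blocks, case_flags, strata_lab, sample_ids = [], [], [], []
    for st in spec.strata:
        p0, p1 = _stratum_frequencies(st, spec.odds_ratio, spec.n_variants)
        g_case = rng.binomial(2, p1[:, None], size=(spec.n_variants, st.n_cases))
        g_ctrl = rng.binomial(2, p0[:, None], size=(spec.n_variants, st.n_controls))
        blocks.append(np.concatenate([g_case, g_ctrl], axis=1).astype(np.int8))
        case_flags.append(np.r_[np.ones(st.n_cases, bool), np.zeros(st.n_controls, bool)])
        strata_lab.extend([st.label] * (st.n_cases + st.n_controls))
        sample_ids.extend(
            f"{st.label}_{'case' if i < st.n_cases else 'ctrl'}_{i}"
            for i in range(st.n_cases + st.n_controls)
        )
    geno = np.concatenate(blocks, axis=1)
    if spec.missing_rate > 0:
        miss = rng.random(geno.shape) < spec.missing_rate
        geno[miss] = MISSING
    return CohortData(
        genotypes=geno,
        is_case=np.concatenate(case_flags),
        stratum=np.asarray(strata_lab),
        sample_ids=np.asarray(sample_ids),
        variant_ids=np.asarray([f"var{i}" for i in range(spec.n_variants)]),
    )


def simulate_confounded_null(spec: CohortSpec) -> CohortData:
    """Null data (OR forced to 1) where stratum confounds the marginal contrast.

    Within every stratum cases and controls share the stratum's allele
    frequency, so there is no true association; but when strata differ both
    in baseline frequency and in case:control ratio, the frequency pooled
    across strata differs between cases and controls.  An unstratified test
    mistakes that for association; a within-stratum permutation test must not.
    """
    if len(spec.strata) < 2:
        raise ValueError("confounded null needs at least 2 strata")
    p0s = [np.atleast_1d(np.asarray(s.p0, float)) for s in spec.strata]
    if all(np.array_equal(p0s[0], p) for p in p0s[1:]):
        raise ValueError("confounding requires strata with different allele frequencies")
    null_spec = CohortSpec(
        strata=spec.strata,
        odds_ratio=1.0,
        missing_rate=spec.missing_rate,
        n_variants=spec.n_variants,
        seed=spec.seed,
    )
    return simulate_cohorts(null_spec)


def simulate_pools(cohort: CohortData, spec: PoolSpec) -> pd.DataFrame:
    """Sequence the cohort in phenotype-homogeneous pools of N individuals.

    Individuals are partitioned, in cohort order, into case-only and
    control-only pools of exactly ``spec.n_individuals_per_pool``; a trailing
    remainder that cannot fill a pool is left unsequenced.  Returns the pool
    pileup as a tidy frame with one row per (variant, pool):
    ``variant_id, pool_id, pool_role, n_ref_reads, n_alt_reads, pool_size``.
    """
    n_pool = spec.n_individuals_per_pool
    case_idx = np.flatnonzero(cohort.is_case)
    ctrl_idx = np.flatnonzero(~cohort.is_case)
    if len(case_idx) < n_pool and len(ctrl_idx) < n_pool:
        raise ValueError(
            f"pool size {n_pool} exceeds both available cases ({len(case_idx)}) "
            f"and controls ({len(ctrl_idx)})"
        )
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple] = []
    for role, idx, requested in (
        ("case", case_idx, spec.n_pools_case),
        ("control", ctrl_idx, spec.n_pools_control),
    ):
        n_pools = len(idx) // n_pool
        if requested is not None:
            if requested > n_pools:
                raise ValueError(
                    f"{requested} {role} pools of {n_pool} need "
                    f"{requested * n_pool} individuals, only {len(idx)} available"
                )
            n_pools = requested
        for p in range(n_pools):
            members = idx[p * n_pool : (p + 1) * n_pool]
            g = cohort.genotypes[:, members]
            if np.any(g == MISSING):
                raise ValueError("pooled individuals must have complete genotypes")
            k = g.sum(axis=1)  # true alt-allele count per variant, 0..2N
            depth = rng.poisson(spec.coverage_mean, size=cohort.n_variants)
            f = k / (2 * n_pool)
            p_alt = f * (1 - spec.error_rate) + (1 - f) * spec.error_rate
            alt = rng.binomial(depth, p_alt)
            pool_id = f"{role}_pool_{p}"
            for v in range(cohort.n_variants):
                rows.append(
                    (cohort.variant_ids[v], pool_id, role,
                     int(depth[v] - alt[v]), int(alt[v]), n_pool)
                )
    return pd.DataFrame(
        rows,
        columns=["variant_id", "pool_id", "pool_role",
                 "n_ref_reads", "n_alt_reads", "pool_size"],
    )


def pooled_true_allele_counts(cohort: CohortData, spec: PoolSpec) -> pd.Series:
    """True alt-allele count per variant among the individuals that were pooled.

    Uses the same deterministic pool assignment as :func:`simulate_pools`,
    so the pileup's latent truth can be checked: summing each pool's ``k``
    equals these counts.
    """
    n_pool = spec.n_individuals_per_pool
    total = np.zeros(cohort.n_variants, dtype=np.int64)
    for idx, requested in (
        (np.flatnonzero(cohort.is_case), spec.n_pools_case),
        (np.flatnonzero(~cohort.is_case), spec.n_pools_control),
    ):
        n_pools = len(idx) // n_pool if requested is None else requested
        used = idx[: n_pools * n_pool]
        if used.size:
            total += cohort.genotypes[:, used].sum(axis=1)
    return pd.Series(total, index=cohort.variant_ids, name="alt_allele_count")


def simulate_expression(spec: ExpressionSpec) -> ExpressionData:
    """Gaussian two-group expression matrix with a planted differential set.

    Background genes are N(0, 1) in both groups; the first
    ``n_differential`` genes get a ``+effect_size`` mean shift (in SD units)
    in group 2.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_genes, spec.n_samples_per_group
    x = rng.standard_normal((n, 2 * m))
    x[: spec.n_differential, m:] += spec.effect_size
    genes = np.asarray([f"gene{i}" for i in range(n)])
    samples = [f"g1_s{i}" for i in range(m)] + [f"g2_s{i}" for i in range(m)]
    groups = pd.Series(["g1"] * m + ["g2"] * m, index=samples, name="group")
    return ExpressionData(
        matrix=pd.DataFrame(x, index=genes, columns=samples),
        groups=groups,
        truth=genes[: spec.n_differential].copy(),
    )
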