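"""Stratified rare-variant association by within-stratum permutation (MARV).

Rare variants yield too few minor alleles per sub-cohort for asymptotic
chi-square tests, and low-frequency alleles make population stratification
especially dangerous.  The mega-analysis of rare variants (MARV) therefore
(i) stratifies by sub-cohort, (ii) scores each variant with the
observed-minus-expected case minor-allele count summed over strata,

    T = sum_s [ a_s - (a_s + c_s)(a_s + b_s) / n_s ],

where (a, b) are case minor/major allele counts, (c, d) the control counts
and n_s = a_s + b_s + c_s + d_s, and (iii) obtains significance by permuting
phenotype labels *within* each stratum, which preserves every stratum's
case:control ratio and allele pool under the null.  Because alleles never
cross stratum boundaries, between-cohort frequency differences cannot
produce a signal, and because individuals (not alleles) are permuted the
test is robust to Hardy-Weinberg departures; each individual's genotype,
including missingness, stays attached to that individual.

The two-sided empirical p-value uses the add-one rule
p = (1 + #{|T*| >= |T|}) / (1 + n_perm), so p is never zero and is bounded
below by 1/(n_perm + 1).

Effect sizes are summarized with the allele-based Mantel-Haenszel odds
ratio and a Robins-Breslow-Greenland 95% CI; strata containing a zero cell
receive the Haldane-Anscombe 0.5 continuity correction (flagged).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .simulate import MISSING, CohortData

__all__ = [
    "StratumTable",
    "AssociationResult",
    "stratified_counts",
    "marv_statistic",
    "marv_test",
    "mh_odds_ratio",
    "combine_subanalyses",
    "unstratified_chi2_p",
]


@dataclass(frozen=True)
class StratumTable:
    """Allele-count 2x2 table for one sub-cohort.

    a/b: case minor/major allele counts; c/d: control minor/major.  Each
    non-missing diploid contributes two alleles, so a + b is twice the
    number of non-missing cases.
    """

    label: str
    a: int
    b: int
    c: int
    d: int
    all_missing: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped_arms(self) -> "StratumTable":
        """Case/control arms exchanged (maps OR to 1/OR)."""
        return StratumTable(self.label, self.c, self.d, self.a, self.b, self.all_missing)


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of a MARV run for one variant."""

    variant_id: str
    statistic: float
    p_perm: float
    n_perm: int
    or_mh: float | None
    ci95: tuple[float, float] | None
    per_stratum: tuple[StratumTable, ...]
    zero_cell_corrected: bool = False
    degenerate: bool = False

    @property
    def n_alleles_case(self) -> int:
        return sum(t.a + t.b for t in self.per_stratum)

    @property
    def n_alleles_control(self) -> int:
        return sum(t.c + t.d for t in self.per_stratum)


def stratified_counts(cohort: CohortData, variant: int | str) -> list[StratumTable]:
    """Per-stratum case/control minor/major allele counts for one variant.

    Missing genotypes contribute no alleles.  A stratum with every genotype
    missing is kept as an all-zero table flagged ``all_missing`` so the
    stratum list always matches the cohort's strata.
    """
    v = cohort.variant_index(variant) if isinstance(variant, str) else int(variant)
    if not 0 <= v < cohort.n_variants:
        raise KeyError(f"variant index {v} out of range")
    g = cohort.genotypes[v]
    tables = []
    for lab in cohort.strata_labels:
        in_s = cohort.stratum == lab
        gc = g[in_s & cohort.is_case]
        gn = g[in_s & ~cohort.is_case]
        gc, gn = gc[gc != MISSING], gn[gn != MISSING]
        a = int(gc.sum())
        c = int(gn.sum())
        tables.append(
            StratumTable(
                label=str(lab),
                a=a,
                b=2 * gc.size - a,
                c=c,
                d=2 * gn.size - c,
                all_missing=(gc.size + gn.size == 0),
            )
        )
    return tables


def marv_statistic(tables: Sequence[StratumTable]) -> float:
    """Observed minus expected case minor-allele count, summed over strata."""
    t = 0.0
    for s in tables:
        if s.n == 0:
            continue
        t += s.a - (s.a + s.c) * (s.a + s.b) / s.n
    return t


def _stratum_class_counts(cohort: CohortData, v: int):
    """Per-stratum genotype-class counts (n0, n1, n2, n_missing, n_cases).

    The permutation null needs only how many individuals of each genotype
    class land in the case arm, so strata are reduced to class counts.
    """
    g = cohort.genotypes[v]
    out = []
    for lab in cohort.strata_labels:
        in_s = cohort.stratum == lab
        gs = g[in_s]
        out.append(
            (
                int(np.sum(gs == 0)),
                int(np.sum(gs == 1)),
                int(np.sum(gs == 2)),
                int(np.sum(gs == MISSING)),
                int(cohort.is_case[in_s].sum()),
            )
        )
    return out


def _permuted_statistics(
    strata_counts, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null statistics under within-stratum phenotype permutation.

    Permuting labels within a stratum and recounting is equivalent to
    drawing the case arm's genotype-class composition from a multivariate
    hypergeometric distribution, sampled here as sequential univariate
    hypergeometrics (missing, then homozygous-alt, then heterozygous).
    This is exact — not an approximation — because the statistic depends on
    the assignment only through those class counts.
    """
    t_star = np.zeros(n_perm)
    for n0, n1, n2, nm, n_cases in strata_counts:
        n_tot = n0 + n1 + n2 + nm
        n_nonmiss = n_tot - nm
        if n_nonmiss == 0 or n_cases == 0 or n_cases == n_tot:
            continue
        minor_total = n1 + 2 * n2  # a + c, fixed under permutation
        n_alleles = 2 * n_nonmiss  # stratum allele total, fixed
        m_miss = rng.hypergeometric(nm, n_tot - nm, n_cases, size=n_perm) if nm else np.zeros(n_perm, dtype=np.int64)
        rem = n_cases - m_miss
        m2 = rng.hypergeometric(n2, n_nonmiss - n2, rem) if n2 else np.zeros(n_perm, dtype=np.int64)
        rem = rem - m2
        m1 = rng.hypergeometric(n1, n_nonmiss - n2 - n1, rem) if n1 else np.zeros(n_perm, dtype=np.int64)
        a = m1 + 2 * m2
        nonmiss_cases = n_cases - m_miss
        t_star += a - minor_total * (2 * nonmiss_cases) / n_alleles
    return t_star


def marv_test(
    cohort: CohortData,
    variant: int | str = 0,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
    adaptive_min_exceedances: int | None = None,
) -> AssociationResult:
    """MARV within-stratum permutation test for one variant.

    Parameters
    ----------
    cohort
        Genotypes with phenotype and stratum labels.
    variant
        Row index or variant id.
    n_perm
        Number of label permutations; p >= 1/(n_perm + 1).
    seed
        Integer seed or a Generator (shared across calls for batch runs).
    adaptive_min_exceedances
        If set, stop permuting once this many exceedances of |T| have been
        seen; the p-value then uses the permutations actually run.  Off by
        default so results are exactly reproducible from (spec, seed).

    Returns an :class:`AssociationResult` with the permutation p-value and
    the Mantel-Haenszel odds ratio.  A variant with no minor alleles in any
    informative stratum is degenerate: T = 0, p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    v = cohort.variant_index(variant) if isinstance(variant, str) else int(variant)
    tables = stratified_counts(cohort, v)
    if not any(t.a + t.b > 0 and t.c + t.d > 0 for t in tables):
        raise ValueError("need at least one stratum with cases and controls")
    vid = str(cohort.variant_ids[v])
    or_mh, ci = _safe_or(tables)
    corrected = _needs_correction(tables)
    if all(t.a + t.c == 0 for t in tables):
        return AssociationResult(
            variant_id=vid, statistic=0.0, p_perm=1.0, n_perm=0,
            or_mh=or_mh, ci95=ci, per_stratum=tuple(tables),
            zero_cell_corrected=corrected, degenerate=True,
        )
    t_obs = marv_statistic(tables)
    strata_counts = _stratum_class_counts(cohort, v)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    abs_t = abs(t_obs) - 1e-9  # guard against float round-off in ties
    n_done = 0
    n_exceed = 0
    chunk = n_perm if adaptive_min_exceedances is None else min(n_perm, 200)
    while n_done < n_perm:
        size = min(chunk, n_perm - n_done)
        t_star = _permuted_statistics(strata_counts, size, rng)
        n_exceed += int(np.sum(np.abs(t_star) >= abs_t))
        n_done += size
        if (
            adaptive_min_exceedances is not None
            and n_exceed >= adaptive_min_exceedances
        ):
            break
    p = (1 + n_exceed) / (1 + n_done)
    return AssociationResult(
        variant_id=vid, statistic=t_obs, p_perm=p, n_perm=n_done,
        or_mh=or_mh, ci95=ci, per_stratum=tuple(tables),
        zero_cell_corrected=corrected,
    )


def _needs_correction(tables: Sequence[StratumTable]) -> bool:
    return any(
        t.n > 0 and min(t.a, t.b, t.c, t.d) == 0 for t in tables
    )


def _safe_or(tables):
    try:
        return mh_odds_ratio(tables)
    except ValueError:
        return None, None


def mh_odds_ratio(
    tables: Sequence[StratumTable], z: float = 1.959963984540054
) -> tuple[float, tuple[float, float]]:
    """Allele-based Mantel-Haenszel odds ratio with an RBG 95% CI.

    OR_MH = sum_s(a_s d_s / n_s) / sum_s(b_s c_s / n_s).  The variance of
    log OR_MH follows Robins, Breslow and Greenland, which stays valid for
    many sparse strata.  Any stratum containing a zero cell gets 0.5 added
    to all four of its cells (Haldane-Anscombe) before the sums, so the OR
    and CI are finite even when one arm carries no minor alleles.
    """
    kept = [t for t in tables if t.n > 0]
    if not kept:
        raise ValueError("all stratum tables are empty")
    R = S = 0.0  # MH numerator / denominator sums
    sum_pr = sum_ps_qr = sum_qs = 0.0  # RBG variance pieces
    for t in kept:
        a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
        if min(a, b, c, d) == 0.0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        n = a + b + c + d
        r_s = a * d / n
        s_s = b * c / n
        p_s = (a + d) / n
        q_s = (b + c) / n
        R += r_s
        S += s_s
        sum_pr += p_s * r_s
        sum_ps_qr += p_s * s_s + q_s * r_s
        sum_qs += q_s * s_s
    or_mh = R / S
    var_log = sum_pr / (2 * R * R) + sum_ps_qr / (2 * R * S) + sum_qs / (2 * S * S)
    se = np.sqrt(var_log)
    log_or = np.log(or_mh)
    return float(or_mh), (float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se)))


def combine_subanalyses(
    results,
    mode: str = "stouffer",
) -> float:
    """Combine evidence for one variant across independent sub-analyses.

    Two modes:

    ``"joint"``
        ``results`` is a list of :class:`~rarepool.simulate.CohortData`
        (each contributing its own strata) plus keyword-free tuple
        ``(cohorts, variant, n_perm, seed)`` is not supported here — use
        :func:`joint_marv` instead.  Provided for discoverability.
    ``"stouffer"``
        ``results`` is a list of ``(p, direction, n_effective)`` with
        two-sided p in (0, 1], direction +1/-1 for the effect sign and
        weights sqrt(n_effective).  Each p is mapped to a signed z-score,
        combined as sum(w z)/sqrt(sum w^2), and returned as a two-sided p.
    """
    if mode == "joint":
        raise ValueError("use joint_marv(cohorts, ...) for the joint permutation mode")
    if mode != "stouffer":
        raise ValueError(f"unknown mode {mode!r}")
    results = list(results)
    if not results:
        raise ValueError("need at least one sub-analysis")
    zs, ws = [], []
    for p, direction, n_eff in results:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value must be in (0,1], got {p}")
        if direction not in (-1, 1, -1.0, 1.0):
            raise ValueError("direction must be +1 or -1")
        if n_eff <= 0:
            raise ValueError("n_effective must be positive")
        zs.append(direction * stats.norm.isf(p / 2.0))
        ws.append(np.sqrt(n_eff))
    zs, ws = np.asarray(zs), np.asarray(ws)
    z_comb = float(np.dot(ws, zs) / np.sqrt(np.dot(ws, ws)))
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z_comb))))


def joint_marv(
    cohorts: Sequence[CohortData],
    variant: int | str = 0,
    n_perm: int = 9999,
    seed: int = 0,
) -> AssociationResult:
    """Joint permutation combination: one MARV run over the union of strata.

    The preferred combination when individual-level data exist for every
    sub-analysis.  Stratum labels are prefixed per sub-cohort so strata stay
    distinct; the variant must be present (same id) in all cohorts.
    """
    cohorts = list(cohorts)
    if not cohorts:
        raise ValueError("need at least one cohort")
    if isinstance(variant, str):
        vids = {variant}
        idxs = [c.variant_index(variant) for c in cohorts]
    else:
        idxs = [int(variant)] * len(cohorts)
        vids = {str(c.variant_ids[i]) for c, i in zip(cohorts, idxs)}
    if len(vids) != 1:
        raise ValueError(f"variant identity differs across sub-analyses: {sorted(vids)}")
    geno = np.concatenate([c.genotypes[i][None, :] for c, i in zip(cohorts, idxs)], axis=1)
    merged = CohortData(
        genotypes=geno,
        is_case=np.concatenate([c.is_case for c in cohorts]),
        stratum=np.concatenate(
            [np.char.add(f"sub{j}:", c.stratum.astype(str)) for j, c in enumerate(cohorts)]
        ),
        sample_ids=np.concatenate(
            [np.char.add(f"sub{j}:", c.sample_ids.astype(str)) for j, c in enumerate(cohorts)]
        ),
        variant_ids=np.asarray([vids.pop()]),
    )
    return marv_test(merged, 0, n_perm=n_perm, seed=seed)


def unstratified_chi2_p(cohort: CohortData, variant: int | str = 0) -> float:
    """Naive allele-count chi-square p-value ignoring strata.

    The comparator that demonstrates confounding by population
    stratification: pools all strata into a single 2x2 allele table and
    applies the (uncorrected) chi-square test.
    """
    tables = stratified_counts(cohort, variant)
    a = sum(t.a for t in tables)
    b = sum(t.b for t in tables)
    c = sum(t.c for t in tables)
    d = sum(t.d for t in tables)
    obs = np.array([[a, b], [c, d]], dtype=float)
    if obs.sum() == 0 or (a + c) == 0 or (b + d) == 0:
        return 1.0
    _, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(p)
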