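"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive — exhaustive scans and enumerations
that are obviously correct at small sizes — and shares no code with the
implementation it checks.
"""

from itertools import combinations

import numpy as np
from scipy.stats import binom


def brute_force_pool_mle(n_ref: int, n_alt: int, n_chrom: int, e: float) -> int:
    """Scan every candidate allele count k in 0..2N for the likelihood max.

    Ties broken toward smaller k, matching the estimator's contract.
    """
    depth = n_ref + n_alt
    best_k, best_ll = 0, -np.inf
    for k in range(n_chrom + 1):
        q = (k / n_chrom) * (1 - e) + (1 - k / n_chrom) * e
        ll = binom.logpmf(n_alt, depth, q)
        if ll > best_ll + 1e-12:
            best_k, best_ll = k, ll
    return best_k


def marv_T(tables):
    """Observed-minus-expected case minor-allele count, from raw tables."""
    t = 0.0
    for a, b, c, d in tables:
        n = a + b + c + d
        if n:
            t += a - (a + c) * (a + b) / n
    return t


def enumerate_single_stratum_p(genotypes, n_cases: int) -> float:
    """Exact two-sided permutation p for one stratum by full enumeration.

    Walks every C(n, n_cases) assignment of case labels; the observed
    assignment is cases = the first n_cases individuals.  Missing genotypes
    are encoded as -1 and contribute no alleles.  Uses the same add-nothing
    exact convention: p = #{|T*| >= |T|} / #assignments (the observed
    assignment is one of them, so p > 0).
    """
    g = np.asarray(genotypes)
    n = g.size

    def table(case_idx):
        mask = np.zeros(n, dtype=bool)
        mask[list(case_idx)] = True
        gc, gn = g[mask], g[~mask]
        gc, gn = gc[gc >= 0], gn[gn >= 0]
        a, c = int(gc.sum()), int(gn.sum())
        return a, 2 * len(gc) - a, c, 2 * len(gn) - c

    t_obs = abs(marv_T([table(range(n_cases))]))
    n_tot = 0
    n_exceed = 0
    for idx in combinations(range(n), n_cases):
        n_tot += 1
        if abs(marv_T([table(idx)])) >= t_obs - 1e-12:
            n_exceed += 1
    return n_exceed / n_tot


def binom_tail_by_summation(k: int, m: int, alpha: float) -> float:
    """P(X >= k) for X ~ Binomial(m, alpha) by direct pmf summation."""
    from math import comb

    return sum(comb(m, j) * alpha**j * (1 - alpha) ** (m - j) for j in range(k, m + 1))
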