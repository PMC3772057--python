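"""Study-design arithmetic: multiple testing, excess of significance, power.

Three small pieces of the statistical plumbing around a targeted follow-up
study of m candidate variants:

* the Bonferroni per-test threshold alpha_FWER / m;
* the "excess of nominal significance" argument — under the global null the
  number of tests below a nominal alpha is Binomial(m, alpha), so both the
  expected count and the exact tail probability of observing at least the
  realized number of hits are available in closed form;
* statistical power for a single low-frequency variant, both by the
  standard two-proportion normal approximation on allele counts and by
  Monte-Carlo simulation.

The power model works on alleles: a study with n_cases and n_controls
diploids compares 2*n_cases vs 2*n_controls binomial allele draws at
frequencies p1 (cases) and p0 (controls), where p1 is implied by the
allelic odds ratio (see :func:`rarepool.simulate.case_allele_frequency`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import case_allele_frequency

__all__ = [
    "DesignSpec",
    "PowerSpec",
    "bonferroni_alpha",
    "excess_significance",
    "analytic_power",
    "simulation_power",
]


@dataclass(frozen=True)
class DesignSpec:
    """Multiple-testing design: number of tests and family-wise alpha."""

    m_tests: int = 42
    fwer: float = 0.05

    def __post_init__(self) -> None:
        if self.m_tests < 1:
            raise ValueError("m_tests must be >= 1")
        if not 0.0 < self.fwer < 1.0:
            raise ValueError("fwer must be in (0,1)")


@dataclass(frozen=True)
class PowerSpec:
    """Single-variant power scenario.

    p0 is the control minor-allele frequency, odds_ratio the allelic OR;
    alpha is the two-sided significance level of the allele-count test.
    """

    p0: float
    odds_ratio: float
    n_cases: int
    n_controls: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must be in (0,1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")


def bonferroni_alpha(m_tests: int, fwer: float = 0.05) -> tuple[float, float]:
    """Bonferroni per-test threshold.

    Returns (exact, two_significant_figures); e.g. 42 tests at family-wise
    0.05 give 0.0011905 exactly, reported as 0.0012.
    """
    spec = DesignSpec(m_tests=m_tests, fwer=fwer)  # validates
    alpha = spec.fwer / spec.m_tests
    two_sf = float(f"{alpha:.2g}")
    return alpha, two_sf


def excess_significance(
    m_tests: int, alpha_nominal: float, observed_count: int | None = None
) -> tuple[float, float | None]:
    """Expected null hits at a nominal level, and the exact binomial tail.

    Under the global null the hit count is X ~ Binomial(m, alpha); returns
    (E[X], P(X >= observed_count)).  The tail probability is None when no
    observed count is supplied.
    """
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    if not 0.0 < alpha_nominal < 1.0:
        raise ValueError("alpha_nominal must be in (0,1)")
    expected = m_tests * alpha_nominal
    if observed_count is None:
        return expected, None
    if not 0 <= observed_count <= m_tests:
        raise ValueError("observed_count must be in 0..m_tests")
    # P(X >= k) via the exact survival function; sf(k-1) includes k itself.
    tail = float(stats.binom.sf(observed_count - 1, m_tests, alpha_nominal))
    return expected, tail


def analytic_power(spec: PowerSpec) -> float:
    """Normal-approximation power of the two-sided two-proportion allele test.

    With m1 = 2*n_cases and m0 = 2*n_controls allele draws, the test
    statistic (p1_hat - p0_hat) / SE is approximately normal; under the
    alternative the unpooled SE is sqrt(p1(1-p1)/m1 + p0(1-p0)/m0) and,
    writing delta = |p1 - p0|/SE, power is

        Phi(delta - z_{1-alpha/2}) + Phi(-delta - z_{1-alpha/2}),

    i.e. both rejection tails are kept, so the null (OR = 1) returns
    exactly alpha; the second term is negligible whenever power matters.
    """
    p0 = spec.p0
    p1 = case_allele_frequency(p0, spec.odds_ratio)
    m1, m0 = 2 * spec.n_cases, 2 * spec.n_controls
    if p1 in (0.0, 1.0):
        raise ValueError("degenerate case allele frequency")
    se_alt = np.sqrt(p1 * (1 - p1) / m1 + p0 * (1 - p0) / m0)
    z_crit = stats.norm.isf(spec.alpha / 2.0)
    delta = abs(p1 - p0) / se_alt
    return float(stats.norm.cdf(delta - z_crit) + stats.norm.cdf(-delta - z_crit))


def simulation_power(
    spec: PowerSpec,
    n_reps: int = 5000,
    seed: int = 0,
    test: str = "ztest",
    n_perm: int = 999,
) -> tuple[float, tuple[float, float]]:
    """Monte-Carlo power with a Wilson 95% CI on the rejection fraction.

    ``test="ztest"`` (default) simulates case/control allele counts and
    applies the same unpooled two-proportion z-test that
    :func:`analytic_power` approximates — a direct cross-check of the
    normal approximation, vectorized over replicates.

    ``test="marv"`` simulates a full single-stratum cohort per replicate
    and runs the MARV permutation test with ``n_perm`` permutations; use
    modest ``n_reps`` as each replicate permutes.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a usable estimate")
    p0 = spec.p0
    p1 = case_allele_frequency(p0, spec.odds_ratio)
    rng = np.random.default_rng(seed)
    if test == "ztest":
        m1, m0 = 2 * spec.n_cases, 2 * spec.n_controls
        x1 = rng.binomial(m1, p1, size=n_reps)
        x0 = rng.binomial(m0, p0, size=n_reps)
        f1, f0 = x1 / m1, x0 / m0
        se = np.sqrt(f1 * (1 - f1) / m1 + f0 * (1 - f0) / m0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, np.abs(f1 - f0) / np.where(se > 0, se, 1.0), 0.0)
        reject = z > stats.norm.isf(spec.alpha / 2.0)
    elif test == "marv":
        from .marv import marv_test
        from .simulate import CohortSpec, StratumSpec, simulate_cohorts

        reject = np.zeros(n_reps, dtype=bool)
        for r in range(n_reps):
            cohort = simulate_cohorts(
                CohortSpec(
                    strata=(StratumSpec("s1", spec.n_cases, spec.n_controls, p0),),
                    odds_ratio=spec.odds_ratio,
                    seed=int(rng.integers(2**31 - 1)),
                )
            )
            res = marv_test(cohort, 0, n_perm=n_perm, seed=rng)
            reject[r] = res.p_perm <= spec.alpha
    else:
        raise ValueError(f"unknown test {test!r}")
    k = int(reject.sum())
    power = k / n_reps
    lo, hi = _wilson_ci(k, n_reps)
    return power, (lo, hi)


def _wilson_ci(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return float(max(0.0, center - half)), float(min(1.0, center + half))
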