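"""The stratified permutation test, MH odds ratios and evidence combination."""

import numpy as np
import pytest
from scipy import stats

from _oracles import enumerate_single_stratum_p, marv_T
from rarepool import (
    CohortData,
    CohortSpec,
    StratumSpec,
    StratumTable,
    combine_subanalyses,
    joint_marv,
    marv_statistic,
    marv_test,
    mh_odds_ratio,
    simulate_cohorts,
    stratified_counts,
    unstratified_chi2_p,
)


def cohort_from_genotypes(geno_by_stratum, cases_by_stratum):
    """Build a CohortData from explicit per-stratum genotype lists.

    ``geno_by_stratum``: {label: list of genotypes (-1 = missing)};
    ``cases_by_stratum``: {label: number of leading individuals that are cases}.
    """
    geno, is_case, stratum, sids = [], [], [], []
    for lab, gs in geno_by_stratum.items():
        n_cases = cases_by_stratum[lab]
        geno.extend(gs)
        is_case.extend([True] * n_cases + [False] * (len(gs) - n_cases))
        stratum.extend([lab] * len(gs))
        sids.extend(f"{lab}_{i}" for i in range(len(gs)))
    return CohortData(
        genotypes=np.asarray(geno, dtype=np.int8)[None, :],
        is_case=np.asarray(is_case),
        stratum=np.asarray(stratum),
        sample_ids=np.asarray(sids),
        variant_ids=np.asarray(["v0"]),
    )


class TestStratifiedCounts:
    def test_direct_count(self):
        # cases {0,1,2}, controls {0,0,1} -> a=3, b=3, c=1, d=5
        c = cohort_from_genotypes({"s": [0, 1, 2, 0, 0, 1]}, {"s": 3})
        (t,) = stratified_counts(c, 0)
        assert (t.a, t.b, t.c, t.d) == (3, 3, 1, 5)

    def test_missing_genotypes_drop_alleles(self):
        c = cohort_from_genotypes({"s": [1, -1, 2, 0, -1, -1]}, {"s": 3})
        (t,) = stratified_counts(c, 0)
        assert (t.a, t.b, t.c, t.d) == (3, 1, 0, 2)

    def test_fully_missing_stratum_flagged(self):
        c = cohort_from_genotypes(
            {"s1": [1, 0, 0, 0], "s2": [-1, -1, -1, -1]}, {"s1": 2, "s2": 2}
        )
        t1, t2 = stratified_counts(c, 0)
        assert t2.all_missing and (t2.a, t2.b, t2.c, t2.d) == (0, 0, 0, 0)
        assert not t1.all_missing

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, size=40)
        c1 = cohort_from_genotypes({"s": list(g)}, {"s": 15})
        perm = rng.permutation(40)
        c2 = CohortData(
            genotypes=c1.genotypes[:, perm],
            is_case=c1.is_case[perm],
            stratum=c1.stratum[perm],
            sample_ids=c1.sample_ids[perm],
            variant_ids=c1.variant_ids,
        )
        assert stratified_counts(c1, 0) == stratified_counts(c2, 0)

    def test_missing_variant_errors(self):
        c = cohort_from_genotypes({"s": [0, 1]}, {"s": 1})
        with pytest.raises(KeyError):
            stratified_counts(c, "no_such_variant")


class TestMarvTest:
    def test_monomorphic_variant_degenerate(self):
        c = cohort_from_genotypes({"s": [0] * 20}, {"s": 10})
        res = marv_test(c, 0, n_perm=99, seed=0)
        assert res.degenerate and res.statistic == 0.0 and res.p_perm == 1.0

    def test_matches_exhaustive_enumeration(self):
        # 4 cases / 4 controls, two case carriers: C(8,4) = 70 assignments
        geno = [1, 1, 0, 0, 0, 0, 0, 0]
        p_exact = enumerate_single_stratum_p(geno, 4)
        c = cohort_from_genotypes({"s": geno}, {"s": 4})
        res = marv_test(c, 0, n_perm=20_000, seed=3)
        se = np.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert res.p_perm == pytest.approx(p_exact, abs=3 * se + 1e-4)

    @pytest.mark.parametrize(
        "geno,n_cases",
        [
            ([2, 1, 0, 0, 1, 0], 3),
            ([1, 0, 0, 0, 0, 0, 0, 1, 2, 0], 5),
            ([1, -1, 0, 2, 0, 0, -1, 0], 4),  # with missingness
            ([2, 2, 1, 0, 0, 0, 0], 2),
        ],
    )
    def test_enumeration_oracle_small_instances(self, geno, n_cases):
        p_exact = enumerate_single_stratum_p(geno, n_cases)
        c = cohort_from_genotypes({"s": geno}, {"s": n_cases})
        res = marv_test(c, 0, n_perm=40_000, seed=8)
        se = np.sqrt(p_exact * (1 - p_exact) / 40_000)
        assert res.p_perm == pytest.approx(p_exact, abs=3 * se + 2e-3)

    def test_observed_statistic_matches_oracle(self, small_cohort):
        tables = stratified_counts(small_cohort, 0)
        raw = [(t.a, t.b, t.c, t.d) for t in tables]
        assert marv_statistic(tables) == pytest.approx(marv_T(raw))
        res = marv_test(small_cohort, 0, n_perm=49, seed=1)
        assert res.statistic == pytest.approx(marv_T(raw))

    def test_p_floor_and_determinism(self, small_cohort):
        r1 = marv_test(small_cohort, 0, n_perm=199, seed=42)
        r2 = marv_test(small_cohort, 0, n_perm=199, seed=42)
        assert r1.p_perm == r2.p_perm and r1.statistic == r2.statistic
        assert r1.p_perm >= 1 / 200

    def test_minor_major_swap_symmetry(self, small_cohort):
        # recoding the variant 0<->2 flips the statistic's sign, not |T| or p
        flipped = CohortData(
            genotypes=np.where(
                small_cohort.genotypes >= 0, 2 - small_cohort.genotypes, -1
            ).astype(np.int8),
            is_case=small_cohort.is_case,
            stratum=small_cohort.stratum,
            sample_ids=small_cohort.sample_ids,
            variant_ids=small_cohort.variant_ids,
        )
        r = marv_test(small_cohort, 0, n_perm=999, seed=7)
        rf = marv_test(flipped, 0, n_perm=999, seed=7)
        assert rf.statistic == pytest.approx(-r.statistic)
        assert rf.p_perm == pytest.approx(r.p_perm, abs=0.03)

    def test_stratum_relabeling_invariance(self, small_cohort):
        relabeled = CohortData(
            genotypes=small_cohort.genotypes,
            is_case=small_cohort.is_case,
            stratum=np.char.add("x_", small_cohort.stratum.astype(str)),
            sample_ids=small_cohort.sample_ids,
            variant_ids=small_cohort.variant_ids,
        )
        r1 = marv_test(small_cohort, 0, n_perm=499, seed=13)
        r2 = marv_test(relabeled, 0, n_perm=499, seed=13)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_perm == r2.p_perm

    def test_adaptive_stopping_matches_fixed_in_p_scale(self, small_cohort):
        # adaptive mode stops early on clearly-null variants but still
        # returns a valid (coarser) p estimate
        res = marv_test(small_cohort, 0, n_perm=50_000, seed=3,
                        adaptive_min_exceedances=100)
        assert res.n_perm <= 50_000
        full = marv_test(small_cohort, 0, n_perm=2000, seed=4)
        if full.p_perm > 0.05:  # null-ish: adaptive should have stopped early
            assert res.n_perm < 50_000

    def test_requires_informative_stratum(self):
        c = cohort_from_genotypes({"s": [1, 1, 0]}, {"s": 3})  # no controls
        with pytest.raises(ValueError):
            marv_test(c, 0, n_perm=10)


class TestMantelHaenszel:
    def test_symmetric_single_table(self):
        orr, (lo, hi) = mh_odds_ratio([StratumTable("s", 10, 90, 10, 90)])
        assert orr == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_hand_evaluated_sums(self):
        # sum(a*d/n) = 4*98/200 + 6*197/400 = 1.96 + 2.955
        # sum(b*c/n) = 96*2/200 + 194*3/400 = 0.96 + 1.455
        tables = [StratumTable("s1", 4, 96, 2, 98), StratumTable("s2", 6, 194, 3, 197)]
        orr, _ = mh_odds_ratio(tables)
        assert orr == pytest.approx((1.96 + 2.955) / (0.96 + 1.455))

    def test_agrees_with_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        tables = [
            StratumTable("s1", 12, 388, 7, 393),
            StratumTable("s2", 30, 970, 18, 982),
            StratumTable("s3", 5, 195, 9, 191),
        ]
        orr, (lo, hi) = mh_odds_ratio(tables)
        st_tables = [np.array([[t.a, t.b], [t.c, t.d]]) for t in tables]
        ref = sm.StratifiedTable(st_tables)
        assert orr == pytest.approx(ref.oddsratio_pooled)
        ref_lo, ref_hi = ref.oddsratio_pooled_confint()
        assert lo == pytest.approx(ref_lo, rel=1e-6)
        assert hi == pytest.approx(ref_hi, rel=1e-6)

    def test_arm_swap_inverts_or(self):
        tables = [StratumTable("s1", 8, 392, 3, 397), StratumTable("s2", 2, 98, 5, 95)]
        orr, (lo, hi) = mh_odds_ratio(tables)
        orr_s, (lo_s, hi_s) = mh_odds_ratio([t.swapped_arms() for t in tables])
        assert orr_s == pytest.approx(1 / orr)
        assert lo_s == pytest.approx(1 / hi)
        assert hi_s == pytest.approx(1 / lo)

    def test_zero_cell_gets_continuity_correction(self):
        orr, (lo, hi) = mh_odds_ratio([StratumTable("s", 0, 100, 5, 95)])
        assert 0 < orr < 1 and 0 < lo <= orr <= hi and np.isfinite(hi)

    def test_all_empty_errors(self):
        with pytest.raises(ValueError):
            mh_odds_ratio([StratumTable("s", 0, 0, 0, 0)])


class TestCombination:
    def test_single_subanalysis_identity(self):
        assert combine_subanalyses([(0.03, 1, 1000)]) == pytest.approx(0.03)

    def test_stouffer_against_normal_quantile_oracle(self):
        # two consistent signals, equal weights
        p1, p2 = 1.21e-6, 1.81e-6
        z = (stats.norm.isf(p1 / 2) + stats.norm.isf(p2 / 2)) / np.sqrt(2)
        expected = 2 * stats.norm.sf(z)
        got = combine_subanalyses([(p1, 1, 500), (p2, 1, 500)])
        assert got == pytest.approx(expected, rel=1e-9)
        assert got < min(p1, p2)  # consistent evidence strengthens

    def test_opposite_directions_cancel(self):
        assert combine_subanalyses([(0.001, 1, 100), (0.001, -1, 100)]) == pytest.approx(1.0)

    def test_weighting_pulls_toward_larger_study(self):
        # a huge null study should dominate a tiny significant one
        p = combine_subanalyses([(1e-4, 1, 100), (0.9, 1, 100_000)])
        assert p > 0.05

    def test_joint_permutation_over_union_of_strata(self):
        spec1 = CohortSpec(strata=(StratumSpec("a", 100, 100, 0.05),), odds_ratio=3.0, seed=1)
        spec2 = CohortSpec(strata=(StratumSpec("b", 100, 100, 0.08),), odds_ratio=3.0, seed=2)
        c1, c2 = simulate_cohorts(spec1), simulate_cohorts(spec2)
        joint = joint_marv([c1, c2], 0, n_perm=999, seed=5)
        assert len(joint.per_stratum) == 2
        solo = marv_test(c1, 0, n_perm=999, seed=5)
        # pooled evidence from two concordant cohorts is at least as strong
        assert joint.p_perm <= solo.p_perm + 0.05

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            combine_subanalyses([(0.0, 1, 10)])
        with pytest.raises(ValueError):
            combine_subanalyses([])


def test_unstratified_chi2_sees_confounding_signal():
    from rarepool import simulate_confounded_null

    spec = CohortSpec(
        strata=(StratumSpec("A", 900, 100, 0.02), StratumSpec("B", 100, 900, 0.002)),
        seed=33,
    )
    c = simulate_confounded_null(spec)
    # the marginal table is confounded; chi-square sees a spurious signal
    # far more often than the stratified test (full calibration is checked
    # in the acceptance suite)
    p_naive = unstratified_chi2_p(c, 0)
    assert 0.0 <= p_naive <= 1.0
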