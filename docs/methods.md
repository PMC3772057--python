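# Methods

## The association model

The target setting is a low-frequency variant (minor-allele frequency
0.05%–5%) genotyped in K independently recruited case-control collections.
Asymptotic single-collection tests are unreliable at these counts, and
because rare-allele frequencies drift strongly between populations,
pooling collections naively invites confounding.  The test therefore
conditions on collection membership throughout.

Per collection s the data reduce to an allele-count 2×2 table: a_s/b_s
case minor/major alleles, c_s/d_s control minor/major (two alleles per
non-missing diploid).  The score statistic is

    T = Σ_s [ a_s − (a_s + c_s)(a_s + b_s) / n_s ],

the case minor-allele excess over the expectation under each collection's
own pooled frequency — the numerator of the Cochran-Mantel-Haenszel
statistic.  Significance comes from the permutation null: phenotype labels
are shuffled within each collection, keeping its case:control split and
allele pool fixed, and each individual's genotype (including missingness)
attached to that individual.  The two-sided empirical p-value uses the
add-one convention p = (1 + #{|T*| ≥ |T|}) / (1 + n_perm), so p ≥
1/(n_perm + 1) and ties count as exceedances.

Assumptions: biallelic sites, unrelated individuals, missingness
non-informative within collection.  Hardy-Weinberg equilibrium is *not*
assumed — individuals, not alleles, are permuted.

### Permutation engine

The statistic depends on a permutation only through how many individuals
of each genotype class (0/1/2 minor alleles, or missing) land in the case
arm, so within-stratum label shuffling is drawn exactly as sequential
hypergeometrics (missing, then homozygous, then heterozygous counts).
This is an algebraic reformulation, not an approximation; the test suite
checks it against exhaustive enumeration of all label assignments on small
strata.  It makes a 10⁴-permutation run a handful of vectorized draws.

Optional adaptive early stopping (halt once a fixed number of exceedances
has accumulated) is off by default so that results are exactly
reproducible from (data, seed, n_perm).

### Discreteness and test size

An exact permutation test can only reject at attainable p-levels; when a
collection carries a handful of minor alleles the null distribution of T
has large atoms and the achieved size at nominal 0.05 falls below 0.05.
In the package's confounded-null stress scenario (two collections of
1,000 with reversed 9:1 case:control ratios and frequencies 2% vs 0.2%),
the measured size is ≈0.04: conservative, never inflated, while an
unstratified chi-square on the same data rejects essentially always.
This is the expected behaviour of an exact test at extreme discreteness,
and the direction of the error is the safe one for type-I control.

### Effect size

The allele-based Mantel-Haenszel odds ratio OR = Σ(a_s d_s/n_s) /
Σ(b_s c_s/n_s) with the Robins-Breslow-Greenland variance for log OR
(valid under both sparse-strata and large-strata asymptotics).  Any
stratum containing a zero cell gets 0.5 added to all four cells
(Haldane-Anscombe) before entering the sums, and the result is flagged;
this keeps the OR and CI finite when one arm carries no minor alleles, at
the cost of a slight pull toward the null in those strata.

### Combining sub-analyses

When individual-level data exist for every sub-analysis, the preferred
combination is a single permutation run over the union of strata
(`joint_marv`), which needs no distributional assumptions.  For
summary-level inputs, a direction-aware Stouffer combination is provided:
each two-sided p maps to a signed z, combined with weights √n_effective.
The two modes answer slightly different questions (joint permutation tests
the global null of no effect anywhere; Stouffer assumes a common effect
direction is the signal of interest) and can legitimately differ.

## Pooled-sequencing frequency estimation

A pool of N diploids holds k ∈ {0..2N} alternate alleles.  With per-read
miscall rate e, a read reports the alternate with probability
q(k) = k/2N·(1−e) + (1−k/2N)·e.  The estimator maximizes the
Binomial(depth, q(k)) likelihood over the 2N+1 candidates.  The binomial
log-likelihood is strictly concave in q and q(k) is affine increasing in k
(e < 1/2), so the likelihood is unimodal in k: only the two lattice points
bracketing the continuous optimum (alt/depth − e)/(1 − 2e)·2N need
evaluating.  Ties break toward the smaller count, and a zero-depth site
returns an explicit no-data value rather than zero.  Equivalence with the
full likelihood scan is tested for 2N ≤ 200.

Multi-pool estimates sum per-pool MLE counts over total chromosomes; the
frequency-recovery check (R² between estimates and simulated truth across
0.05%–5%) runs on the default discovery geometry of 7 pools × 50
individuals at 1575× mean coverage.

Deliberately out of scope: alignment, base-quality recalibration, indels
and multi-allelic sites; the error rate is a single per-read constant.

## Variant triage

Follow-up filtering removes, in order, recording the first matching
reason: non-validated variants; singletons (exactly one alternate allele
in discovery); MHC-region variants (default window chr6:25–34 Mb,
build-36 coordinates, configurable); variants that are not
missense/nonsense/splice; variants with discovery frequency strictly above
the common threshold (default 5% — a variant at exactly the threshold is
kept).  Summary ratios: NS/S = (missense + nonsense)/synonymous, Ti/Tv
over all SNVs; reported at one decimal, kept at full precision internally;
a zero denominator reports an absent value.

## Study-design statistics

Under the global null the number of tests below nominal α among m is
Binomial(m, α): the package reports E = mα and the exact tail
P(X ≥ k).  Power for a single variant uses the two-proportion normal
approximation on allele counts with unpooled variances:
z = |p₁ − p₀| / √(p₁(1−p₁)/2n₁ + p₀(1−p₀)/2n₀), power =
Φ(z − z_{1−α/2}) + Φ(−z − z_{1−α/2}).  Both rejection tails are kept so
the null returns exactly α; the second term is negligible whenever power
is interesting.  The Monte-Carlo estimator (`simulation_power`) simulates
allele counts and applies the identical z-test, vectorized; a `marv`
backend runs the full permutation test per replicate for small studies.
The case frequency is always derived from the allelic odds ratio as
p₁ = OR·p₀/(1 + p₀(OR − 1)).

## Expression screening

Quantile normalization maps each sample's k-th order statistic to the
across-sample mean of k-th order statistics; ties within a sample receive
the mean of the reference values their positions span.  On tie-free
(continuous) data the defining property — identical sorted values in every
column — and idempotence hold exactly; a tied column deviates slightly, as
in any tie-averaged dialect, which the tests pin down explicitly.
Screening uses Welch's unequal-variance t-test (the robust default when
nothing is known about group variances); genes at p < 0.05 are ranked by
|SNR| with SNR = (μ₁ − μ₂)/(σ₁ + σ₂) (per-group SDs, ddof = 1).  A pooled-SD
denominator and signed ranking are options.  Groups are ordered
lexicographically by label so the sign convention is deterministic.  Genes
with zero SD sum are excluded from ranking and flagged; every gene's t, p
and pass/fail status are reported whether or not it ranks.

## Synthetic data: what it does and does not emulate

The generator draws genotypes Binomial(2, p) per individual with p = p₀
(controls) or p₁ (cases) per stratum — i.e. an allelic
(multiplicative-on-odds) disease model with Hardy-Weinberg structure
within each phenotype-by-stratum cell.  Defaults mirror the targeted
design the package addresses: pools of 50 diploids at 1575× mean coverage
(Poisson depth; only a median is reported for the real experiment, so the
mean is the modelled quantity), per-read error 0.5%, discovery MAFs
log-uniform on 0.05%–5%, follow-up strata of roughly 2,000 cases and
2,000 controls each with baseline frequencies 0.3%–1.5% and OR 1.5.
Per-genotype missingness (default 0) is completely at random, standing in
for assay design failures and markers not typed in every sample set.  The confounded-null generator forces
OR = 1 within strata that differ in both frequency and case:control ratio,
producing a marginal association with no within-stratum effect.

Not emulated: linkage disequilibrium and haplotype structure, relatedness,
batch effects in pooling, genotyping-assay failure mechanisms, and any
realistic microarray noise structure (the expression generator is Gaussian
with a mean-shift truth set).  Passing tests therefore demonstrate the
statistical machinery's correctness and calibration under the stated
model, not robustness to those real-data phenomena.

## Numerical conventions

- One RNG per operation call (`numpy.random.default_rng(seed)`); identical
  spec + seed gives byte-identical output; no global state.
- Permutation exceedance uses |T*| ≥ |T| − 10⁻⁹ to keep genuine ties from
  being lost to float round-off (the statistic is a rational lattice).
- Wilson intervals for Monte-Carlo proportions; exact binomial CIs where a
  single frequency is checked.
- Ratios print at one decimal, thresholds at two significant figures;
  full precision is always available from the returned objects.

## Problem sizes used in the shipped checks

Calibration suites use 500 null replicates at ~600–1,000 individuals per
stratum with 999–2,999 permutations; coverage of the MH interval uses 100
replicates of six 2,000+2,000 strata; power cross-validation uses 5,000
Monte-Carlo replicates; enumeration oracles cover all-assignment scans up
to 10 individuals and likelihood scans up to 2N = 200.  These sizes give
binomial standard errors comfortably inside the asserted bands while
keeping the whole suite in single-digit minutes on one core.
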