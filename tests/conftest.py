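import numpy as np
import pytest

from rarepool import CohortSpec, StratumSpec, simulate_cohorts


@pytest.fixture(scope="session")
def six_strata_spec():
    """Six sub-cohorts with stratum-specific baseline frequencies, OR 1.5."""
    p0s = [0.003, 0.005, 0.007, 0.009, 0.012, 0.015]
    strata = tuple(
        StratumSpec(f"cohort{i}", 2000, 2000, p0) for i, p0 in enumerate(p0s)
    )
    return CohortSpec(strata=strata, odds_ratio=1.5, seed=11, n_variants=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest 3-stratum cohort for fast association runs."""
    strata = (
        StratumSpec("s1", 150, 150, 0.05),
        StratumSpec("s2", 100, 200, 0.03),
        StratumSpec("s3", 200, 100, 0.08),
    )
    return simulate_cohorts(
        CohortSpec(strata=strata, odds_ratio=2.0, missing_rate=0.02, seed=5)
    )
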