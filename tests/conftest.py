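from fractions import Fraction
from math import comb

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def midp_fisher_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """Exact-rational brute-force two-sided mid-P for the 2x2 table
    [[a, b], [c, d]] with rows = assays and columns = ref/alt alleles.

    Enumerates every table with the same margins, computes hypergeometric
    probabilities as Fractions, sums those strictly less probable than the
    observed table plus half of those exactly as probable.  Independent of
    the implementation under test.
    """
    n1, n2 = a + b, c + d
    k = a + c
    denom = comb(n1 + n2, k)
    probs = {}
    for x in range(max(0, k - n2), min(n1, k) + 1):
        probs[x] = Fraction(comb(n1, x) * comb(n2, k - x), denom)
    p_obs = probs[a]
    total = Fraction(0)
    for p in probs.values():
        if p < p_obs:
            total += p
        elif p == p_obs:
            total += Fraction(p, 2)
    return float(total)


@pytest.fixture
def small_cohort():
    """A modest 2-patient cohort reused across module tests."""
    from radpipe.synthetic_data import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_patients=2, n_genes=60, variants_per_gene=3, ase_fraction=0.1,
        ase_delta=0.4, seed=11,
    )
    return simulate_cohort(cfg)
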