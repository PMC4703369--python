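"""Allele fractions, RAD arithmetic, the mid-P exact test and the
per-variant significance calls."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import binom, fisher_exact

from radpipe.rad_core import (
    RADResult,
    ZeroDepthError,
    aggregate_gene_class,
    allele_fraction,
    call_preferential_expression,
    control_correction_discordance,
    exome_af_vs_one_test,
    midp_fisher,
    rad,
)
from conftest import midp_fisher_bruteforce


@pytest.mark.parametrize(
    "ref,alt,expected",
    [(9, 1, 0.9), (0, 10, 0.0), (5, 5, 0.5), (10, 0, 1.0)],
)
def test_allele_fraction_is_reference_share(ref, alt, expected):
    assert allele_fraction(ref, alt) == pytest.approx(expected)


def test_allele_fraction_undefined_at_zero_depth():
    with pytest.raises(ZeroDepthError):
        allele_fraction(0, 0)


@pytest.mark.parametrize(
    "rna,exome,expected",
    [(0.5, 0.9, -0.4), (0.3, 0.3, 0.0), (1.0, 0.0, 1.0), (0.0, 1.0, -1.0)],
)
def test_rad_is_rna_minus_exome(rna, exome, expected):
    assert rad(rna, exome) == pytest.approx(expected)


@given(st.floats(0, 1), st.floats(0, 1))
def test_rad_bounds_and_identity(x, y):
    d = rad(x, y)
    assert -1.0 <= d <= 1.0
    assert rad(x, x) == 0.0


def test_midp_unique_table_gives_half():
    # only one table is compatible with margins (10,0)/(10,0): mid-P = 0.5
    assert midp_fisher(10, 0, 10, 0) == pytest.approx(0.5)


def test_midp_matches_bruteforce_enumeration():
    tables = [(45, 5, 25, 25), (8, 2, 3, 7), (12, 12, 12, 12), (30, 1, 1, 30),
              (5, 0, 0, 5), (20, 20, 40, 2), (1, 9, 9, 1)]
    for a, b, c, d in tables:
        assert midp_fisher(a, b, c, d) == pytest.approx(
            midp_fisher_bruteforce(a, b, c, d), abs=1e-12
        )


def test_midp_not_larger_than_classic_fisher():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n1, n2 = rng.integers(1, 41, size=2)
        a = int(rng.integers(0, n1 + 1))
        c = int(rng.integers(0, n2 + 1))
        p_mid = midp_fisher(a, int(n1) - a, c, int(n2) - c)
        p_classic = fisher_exact([[a, int(n1) - a], [c, int(n2) - c]])[1]
        assert p_mid <= p_classic + 1e-12
        assert 0.0 < p_mid <= 1.0


@given(
    st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
)
def test_midp_invariant_under_allele_swap(a, b, c, d):
    """Swapping ref<->alt in both assays leaves the two-sided p unchanged."""
    if a + b == 0 or c + d == 0:
        return
    assert midp_fisher(a, b, c, d) == pytest.approx(midp_fisher(b, a, d, c))


def test_midp_rejects_empty_rows():
    with pytest.raises(ValueError):
        midp_fisher(0, 0, 5, 5)
    with pytest.raises(ValueError):
        midp_fisher(5, 5, 0, 0)


class TestCallPreferentialExpression:
    def test_negative_call_needs_p_and_cutoff(self):
        # AFs 0.9 (exome) vs 0.5 (RNA) at depth 50: strongly negative
        res = call_preferential_expression(45, 5, 25, 25)
        assert res.klass == "negative"
        assert res.rad == pytest.approx(-0.4)
        assert res.p_midp < 0.1

    def test_small_rad_fails_cutoff_despite_significance(self):
        # ~ -0.1 difference at very high depth: p small but |RAD| < 0.2
        res = call_preferential_expression(500, 500, 400, 600)
        assert res.p_midp < 0.1
        assert abs(res.rad) < 0.2
        assert res.klass == "none"

    def test_zero_rna_depth_is_not_expressed(self):
        res = call_preferential_expression(30, 10, 0, 0)
        assert res.klass == "not_expressed"
        assert res.rna_af is None and res.rad is None

    def test_strict_mode_treats_low_rna_depth_as_not_expressed(self):
        res = call_preferential_expression(30, 10, 3, 2)
        assert res.klass == "not_expressed"
        relaxed = call_preferential_expression(
            30, 10, 3, 2, strict_not_expressed=False
        )
        assert relaxed.klass != "not_expressed"

    def test_exome_depth_below_minimum_is_a_precondition_error(self):
        with pytest.raises(ValueError):
            call_preferential_expression(3, 2, 20, 20)

    def test_zero_cutoff_calls_direction_from_sign(self):
        res = call_preferential_expression(45, 5, 35, 15, rad_cutoff=0.0)
        assert res.rad == pytest.approx(-0.2)
        if res.p_midp < 0.1:
            assert res.klass == "negative"


class TestExomeAfVsOne:
    def test_zero_alt_reads_is_absent(self):
        status, p = exome_af_vs_one_test(20, 0)
        assert status == "absent"
        assert p == pytest.approx(1.0)

    def test_half_alt_reads_is_present(self):
        status, p = exome_af_vs_one_test(10, 10)
        # exact binomial tail P(X >= 10 | n=20, p=0.01)
        expected = float(binom.sf(9, 20, 0.01))
        assert status == "present"
        assert p == pytest.approx(expected, rel=1e-12)

    def test_smaller_error_rate_never_loses_present_calls(self):
        calls = []
        for err in (0.05, 0.01, 0.001):
            present = {
                (r, a)
                for r in range(0, 15)
                for a in range(1, 6)
                if exome_af_vs_one_test(r, a, error_rate=err)[0] == "present"
            }
            calls.append(present)
        assert calls[0] <= calls[1] <= calls[2]


class TestAggregateGeneClass:
    @pytest.mark.parametrize(
        "klasses,expected",
        [
            (["negative", "none", "none"], "negative"),
            (["none", "none"], "none"),
            (["negative", "positive"], "mixed"),
            (["not_expressed", "not_expressed"], "not_expressed"),
            (["not_expressed", "none"], "none"),
            (["positive", "not_expressed"], "positive"),
        ],
    )
    def test_aggregation_rules(self, klasses, expected):
        assert aggregate_gene_class(klasses) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_gene_class([])


def _mk(vid, site, klass):
    return RADResult(
        exome_af=0.5, rna_af=0.5, rad=0.0, p_midp=0.5, klass=klass,
        variant_id=vid, patient="P1", site=site,
    )


class TestControlCorrectionDiscordance:
    def test_identical_results_have_zero_discordance(self):
        res = [_mk("v1", "OV", "negative"), _mk("v2", "OV", "none")]
        assert control_correction_discordance(res, res) == 0.0

    def test_one_changed_call_among_ten_significant(self):
        a = [_mk(f"v{i}", "OV", "negative") for i in range(10)]
        b = [_mk(f"v{i}", "OV", "negative") for i in range(9)]
        b.append(_mk("v9", "OV", "none"))
        assert control_correction_discordance(a, b) == pytest.approx(0.1)

    def test_direction_flip_counts_as_discordant(self):
        a = [_mk("v1", "OV", "negative"), _mk("v2", "OV", "positive")]
        b = [_mk("v1", "OV", "positive"), _mk("v2", "OV", "positive")]
        assert control_correction_discordance(a, b) == pytest.approx(0.5)

    def test_mismatched_pair_sets_rejected(self):
        a = [_mk("v1", "OV", "negative")]
        b = [_mk("v2", "OV", "negative")]
        with pytest.raises(ValueError):
            control_correction_discordance(a, b)
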