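"""Allele fractions, RNA-exome allele-fraction differences (RAD) and the
mid-P exact test.

The central statistic compares, for one variant in one tumor sample, the
reference-allele fraction in the exome reads against the reference-allele
fraction in the RNA reads.  The exome fraction is the genomic baseline: copy
number changes and normal-cell admixture move DNA and (null) RNA fractions
together, so their difference isolates preferential expression of one allele.

    AF      = ref_reads / (ref_reads + alt_reads)
    RAD     = rna_af - exome_af            (in [-1, 1])

RAD < 0 means the alternate (variant) allele is over-expressed relative to
its genomic dosage, RAD > 0 the reference allele.  Significance comes from a
two-sided Fisher exact test on the 2x2 table (assay x allele) with the mid-P
correction: tables strictly less probable than the observed one count fully,
tables exactly as probable count half.  The mid-P variant removes much of the
conservatism of the discrete exact test while keeping close to nominal size.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

from scipy import stats

__all__ = [
    "ZeroDepthError",
    "RADResult",
    "allele_fraction",
    "rad",
    "midp_fisher",
    "call_preferential_expression",
    "exome_af_vs_one_test",
    "aggregate_gene_class",
    "control_correction_discordance",
    "KLASSES",
]

#: Per-site significance classes.  ``negative`` = alternate allele
#: preferentially expressed, ``positive`` = reference allele, ``none`` = no
#: significant difference, ``not_expressed`` = insufficient RNA coverage.
KLASSES = ("negative", "positive", "none", "not_expressed")


class ZeroDepthError(ValueError):
    """Raised when an allele fraction is requested at zero total depth."""


@dataclass(frozen=True)
class RADResult:
    """Preferential-expression call for one variant in one tumor site."""

    exome_af: float | None
    rna_af: float | None
    rad: float | None
    p_midp: float | None
    klass: str
    variant_id: str | None = None
    patient: str | None = None
    site: str | None = None
    origin: str | None = None


def allele_fraction(ref_reads: int, alt_reads: int) -> float:
    """Reference-allele fraction: ref / (ref + alt).

    Raises :class:`ZeroDepthError` at zero depth so callers can route the
    variant to the ``not_expressed`` class instead of propagating a NaN.
    """
    total = ref_reads + alt_reads
    if total <= 0:
        raise ZeroDepthError("allele fraction undefined at zero depth")
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    return ref_reads / total


def rad(rna_af: float, exome_af: float) -> float:
    """RNA reference AF minus exome reference AF, in [-1, 1].

    Negative values mean the alternate allele is preferentially expressed.
    """
    if not (0.0 <= rna_af <= 1.0 and 0.0 <= exome_af <= 1.0):
        raise ValueError("allele fractions must lie in [0, 1]")
    return rna_af - exome_af


@lru_cache(maxsize=1 << 18)
def _midp_curve(n1: int, n2: int, k: int) -> tuple[float, ...]:
    """Mid-P values for every table with margins (n1, n2, k).

    Returns p for each feasible exome-reference count ``a`` in
    ``[max(0, k-n2), min(n1, k)]``.  Probabilities are hypergeometric with
    all margins fixed.  Everything is exact integer arithmetic; the final
    division is a single correctly-rounded bigint ratio, so ties between
    equiprobable tables are classified exactly.
    """
    lo = max(0, k - n2)
    hi = min(n1, k)
    nums = [comb(n1, a) * comb(n2, k - a) for a in range(lo, hi + 1)]
    denom = comb(n1 + n2, k)

    order = sorted(range(len(nums)), key=nums.__getitem__)
    less: dict[int, int] = {}  # pmf numerator -> sum of strictly smaller
    equal: dict[int, int] = {}  # pmf numerator -> sum of equal
    running = 0
    i = 0
    while i < len(order):
        val = nums[order[i]]
        j = i
        tie_sum = 0
        while j < len(order) and nums[order[j]] == val:
            tie_sum += val
            j += 1
        less[val] = running
        equal[val] = tie_sum
        running += tie_sum
        i = j

    two_denom = 2 * denom
    return tuple((2 * less[v] + equal[v]) / two_denom for v in nums)


def midp_fisher(
    exome_ref: int, exome_alt: int, rna_ref: int, rna_alt: int
) -> float:
    """Two-sided mid-P Fisher exact test on the assay x allele 2x2 table.

    p = sum of probabilities of tables strictly less probable than the
    observed one, plus half the probability of tables exactly as probable
    (including the observed table itself).  Always in (0, 1] and never
    larger than the classic two-sided Fisher p for the same table.
    """
    n1 = exome_ref + exome_alt
    n2 = rna_ref + rna_alt
    if n1 <= 0:
        raise ValueError("no exome reads: empty table row")
    if n2 <= 0:
        raise ValueError("no RNA reads: empty table row")
    if min(exome_ref, exome_alt, rna_ref, rna_alt) < 0:
        raise ValueError("read counts must be non-negative")
    k = exome_ref + rna_ref
    lo = max(0, k - n2)
    return _midp_curve(n1, n2, k)[exome_ref - lo]


def call_preferential_expression(
    exome_ref: int,
    exome_alt: int,
    rna_ref: int,
    rna_alt: int,
    *,
    p_threshold: float = 0.1,
    rad_cutoff: float = 0.2,
    min_reads: int = 8,
    strict_not_expressed: bool = True,
) -> RADResult:
    """Classify one variant/sample as negative / positive / none /
    not_expressed.

    The exome side must have at least ``min_reads`` reads (precondition).
    In strict mode an RNA depth below ``min_reads`` yields ``not_expressed``;
    otherwise only zero RNA depth does.  A significant call needs both
    ``p_midp < p_threshold`` and ``|RAD| >= rad_cutoff``; pass
    ``rad_cutoff=0`` to apply the p-threshold alone (the convention used for
    the somatic-only analysis).
    """
    exome_depth = exome_ref + exome_alt
    rna_depth = rna_ref + rna_alt
    if exome_depth < min_reads:
        raise ValueError(
            f"exome depth {exome_depth} below required minimum {min_reads}"
        )
    ne_limit = min_reads if strict_not_expressed else 1
    if rna_depth < ne_limit:
        return RADResult(
            exome_af=allele_fraction(exome_ref, exome_alt),
            rna_af=None,
            rad=None,
            p_midp=None,
            klass="not_expressed",
        )
    e_af = allele_fraction(exome_ref, exome_alt)
    r_af = allele_fraction(rna_ref, rna_alt)
    diff = rad(r_af, e_af)
    p = midp_fisher(exome_ref, exome_alt, rna_ref, rna_alt)
    # with a zero cutoff (somatic-only mode) direction comes from the sign
    is_neg = diff <= -rad_cutoff if rad_cutoff > 0 else diff < 0
    is_pos = diff >= rad_cutoff if rad_cutoff > 0 else diff > 0
    if p < p_threshold and is_neg:
        klass = "negative"
    elif p < p_threshold and is_pos:
        klass = "positive"
    else:
        klass = "none"
    return RADResult(exome_af=e_af, rna_af=r_af, rad=diff, p_midp=p, klass=klass)


def exome_af_vs_one_test(
    ref_reads: int,
    alt_reads: int,
    error_rate: float = 0.01,
    alpha: float = 0.05,
) -> tuple[str, float]:
    """Is the exome reference AF significantly below 1 (alt allele present)?

    One-sided exact binomial test of the alternate read count against a
    sequencing-error null Binomial(depth, error_rate).  Returns
    ``("present", p)`` when p < alpha, else ``("absent", p)``.
    """
    total = ref_reads + alt_reads
    if total <= 0:
        raise ZeroDepthError("test undefined at zero depth")
    res = stats.binomtest(alt_reads, total, error_rate, alternative="greater")
    p = float(res.pvalue)
    return ("present" if p < alpha else "absent", p)


def aggregate_gene_class(klasses) -> str:
    """Aggregate per-site (or per-variant) classes into one label.

    ``negative`` if any member is negative and none positive, symmetrically
    ``positive``; ``mixed`` when both directions occur; ``not_expressed``
    only when every member is; otherwise ``none``.
    """
    klasses = list(klasses)
    if not klasses:
        raise ValueError("cannot aggregate an empty set of classes")
    unknown = set(klasses) - set(KLASSES)
    if unknown:
        raise ValueError(f"unknown classes: {sorted(unknown)}")
    has_neg = "negative" in klasses
    has_pos = "positive" in klasses
    if has_neg and has_pos:
        return "mixed"
    if has_neg:
        return "negative"
    if has_pos:
        return "positive"
    if all(k == "not_expressed" for k in klasses):
        return "not_expressed"
    return "none"


def _result_key(r: RADResult) -> tuple:
    return (r.variant_id, r.patient, r.site)


def control_correction_discordance(tumor_results, normal_corrected_results) -> float:
    """Fraction of significant calls that change when the matched-normal
    exome replaces the tumor exome as the genomic baseline.

    A call is discordant when its significance (negative/positive vs not) or
    its direction differs between the two analyses.  The denominator is the
    union of significant calls from either analysis; with no significant
    calls anywhere the discordance is 0.
    """
    a = {_result_key(r): r.klass for r in tumor_results}
    b = {_result_key(r): r.klass for r in normal_corrected_results}
    if a.keys() != b.keys():
        raise ValueError("result sets cover different (variant, site) pairs")
    sig = {"negative", "positive"}
    union = {k for k in a if a[k] in sig or b[k] in sig}
    if not union:
        return 0.0
    discordant = sum(1 for k in union if a[k] != b[k])
    return discordant / len(union)
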