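"""Per-gene non-synonymous/synonymous count ratios stratified by RAD class.

An excess of protein-changing variants among preferentially expressed
alleles, relative to alleles with no expression difference, is a crude but
assumption-light signal of selection.  The ratio here is a raw count ratio
per (gene, class) — not a codon-model dN/dS: stop-gained counts as
non-synonymous, splice/other variants enter neither count, and a gene only
contributes once it has ``min_variants`` usable variants inside the class.
Genes with non-synonymous variants but no synonymous one get an infinite
ratio, kept as a sentinel and ranked strictly last in the empirical CDF
(dropping them would bias against the most skewed genes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["NonSynRatioRecord", "nonsyn_syn_ratios", "ratio_cdf"]

_NONSYN = {"nonsynonymous", "stop_gained"}
_SYN = {"synonymous"}
_CLASSES = ("positive", "negative", "none")


@dataclass(frozen=True)
class NonSynRatioRecord:
    gene: str
    rad_class: str
    n_nonsyn: int
    n_syn: int

    @property
    def ratio(self) -> float:
        if self.n_syn > 0:
            return self.n_nonsyn / self.n_syn
        return math.inf if self.n_nonsyn > 0 else math.nan


def nonsyn_syn_ratios(
    variant_classes: Iterable[tuple[str, str, str]],
    min_variants: int = 2,
) -> list[NonSynRatioRecord]:
    """Count non-syn/syn per (gene, RAD class) and form ratio records.

    ``variant_classes`` yields (gene, effect, rad_class) triples — one per
    variant in the sample under analysis.  A record is emitted per (gene,
    class) whose usable variant count (non-syn + syn) within that class
    reaches ``min_variants``; classes outside positive/negative/none
    (e.g. not_expressed) are ignored.
    """
    if min_variants < 1:
        raise ValueError("min_variants must be >= 1")
    tallies: dict[tuple[str, str], list[int]] = {}
    for gene, effect, rad_class in variant_classes:
        if rad_class not in _CLASSES:
            continue
        key = (gene, rad_class)
        t = tallies.setdefault(key, [0, 0])
        if effect in _NONSYN:
            t[0] += 1
        elif effect in _SYN:
            t[1] += 1
    out = [
        NonSynRatioRecord(gene, klass, n_nonsyn, n_syn)
        for (gene, klass), (n_nonsyn, n_syn) in sorted(tallies.items())
        if n_nonsyn + n_syn >= min_variants
    ]
    return out


def ratio_cdf(
    records: Sequence[NonSynRatioRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF over the ratios of one class.

    Returns ``(values, cdf)`` where ``values`` is sorted ascending with any
    infinite ratios strictly last; ``cdf`` is nondecreasing and ends at 1.
    Records whose ratio is undefined (0/0 — possible only below
    ``min_variants=1``) are excluded.
    """
    ratios = [r.ratio for r in records if not math.isnan(r.ratio)]
    if not ratios:
        raise ValueError("no ratio records to build a CDF from")
    values = np.sort(np.asarray(ratios, dtype=float))  # inf sorts last
    n = values.size
    cdf = np.arange(1, n + 1) / n
    return values, cdf
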