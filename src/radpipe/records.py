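"""Core record types shared across the pipeline.

Conventions follow VCF: 1-based, fully-closed coordinates; the *reference*
allele fraction is the primary quantity, so a negative RNA-minus-exome
difference means the alternate (variant) allele is preferentially expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: SnpEff functional-severity classes, most severe first.
IMPACT_ORDER = ("HIGH", "MODERATE", "LOW", "MODIFIER")

#: Collapsed coding-effect vocabulary used throughout the analysis.
EFFECTS = ("synonymous", "nonsynonymous", "stop_gained", "splice", "other")

#: Anatomical site labels: normal tissue, ovary (primary), peritoneum and
#: lymph node (metastases), plus cultured lines.
SITES = ("NO", "OV", "PE", "LN", "CELL_LINE")

ASSAYS = ("exome", "rna")

#: Ordering used when concatenating tumor sites into a pattern label.
TUMOR_SITE_ORDER = ("OV", "PE", "LN")


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide coding variant with its chosen annotation."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    gene: str
    effect: str
    impact: str
    in_dbsnp: bool = False
    in_cosmic: bool = False

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(
                f"single-nucleotide variants only: {self.ref_allele}>{self.alt_allele}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele and alt_allele must differ")
        if self.impact not in IMPACT_ORDER:
            raise ValueError(f"unknown impact class: {self.impact!r}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect: {self.effect!r}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_allele}>{self.alt_allele}"


@dataclass(frozen=True)
class AlleleCounts:
    """Reference/alternate read counts for one variant in one sample+assay."""

    variant_id: str
    sample_id: str
    assay: str
    ref_reads: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay: {self.assay!r}")
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced sample: a (patient, site) pair covering both assays."""

    sample_id: str
    patient: str
    site: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site: {self.site!r}")


def impact_rank(impact: str) -> int:
    """Smaller is more severe (HIGH=0 ... MODIFIER=3)."""
    return IMPACT_ORDER.index(impact)
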