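"""Readers for annotated VCFs, allele-count tables and sample sheets, plus
the coverage/coding filters and somatic-vs-germline classification.

Counts are taken as given: base/mapping-quality filtering (>= Q20,
deduplicated reads) is assumed to have happened upstream, in whatever
pipeline produced the per-allele read counts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .records import (
    ASSAYS,
    AlleleCounts,
    IMPACT_ORDER,
    SampleMeta,
    VariantRecord,
    impact_rank,
)

__all__ = [
    "VcfParseError",
    "read_annotated_vcf",
    "read_counts_table",
    "read_sample_sheet",
    "counts_to_frame",
    "filter_variants",
    "classify_origin",
]


class VcfParseError(ValueError):
    pass


# Sequence Ontology terms -> collapsed effect classes.  Multi-term
# annotations ("splice_region_variant&synonymous_variant") resolve by
# severity: stop_gained > nonsynonymous > splice > synonymous.
_SO_MAP = {
    "stop_gained": "stop_gained",
    "missense_variant": "nonsynonymous",
    "synonymous_variant": "synonymous",
}
_EFFECT_PRECEDENCE = ("stop_gained", "nonsynonymous", "splice", "synonymous")


def _map_effect(so_terms: str) -> str:
    found = set()
    for term in so_terms.split("&"):
        term = term.strip()
        if term in _SO_MAP:
            found.add(_SO_MAP[term])
        elif term.startswith("splice"):
            found.add("splice")
    for eff in _EFFECT_PRECEDENCE:
        if eff in found:
            return eff
    return "other"


def _parse_ann_entry(entry: str) -> tuple[str, str, str, str]:
    """ANN entry -> (allele, effect, impact, gene)."""
    fields = entry.split("|")
    if len(fields) < 4:
        raise VcfParseError(f"malformed ANN entry: {entry!r}")
    allele, so_terms, impact, gene = fields[0], fields[1], fields[2], fields[3]
    if impact not in IMPACT_ORDER:
        raise VcfParseError(f"unknown impact {impact!r} in ANN entry: {entry!r}")
    return allele, _map_effect(so_terms), impact, gene


def _parse_eff_entry(entry: str) -> tuple[str, str, str, str]:
    """Legacy EFF entry ``effect(impact|class|...|gene|...)`` -> same tuple.

    EFF carries no per-allele tag, so the allele slot is returned empty and
    matches any alternate.
    """
    if "(" not in entry or not entry.endswith(")"):
        raise VcfParseError(f"malformed EFF entry: {entry!r}")
    name, rest = entry.split("(", 1)
    fields = rest[:-1].split("|")
    if len(fields) < 6:
        raise VcfParseError(f"malformed EFF entry: {entry!r}")
    impact = fields[0]
    if impact not in IMPACT_ORDER:
        raise VcfParseError(f"unknown impact {impact!r} in EFF entry: {entry!r}")
    return "", _map_effect(name), impact, fields[5]


def read_annotated_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a SnpEff-annotated VCF into one record per biallelic SNV.

    Multi-allelic records are split; per alternate allele the highest-impact
    annotation is retained (HIGH > MODERATE > LOW > MODIFIER, ties broken by
    the first listed).  Records lacking both ANN and EFF raise
    :class:`VcfParseError` naming the site.  Non-SNV alleles are skipped.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            raw = rec.info.get("ANN") or rec.info.get("EFF")
            if raw is None:
                raise VcfParseError(
                    f"record {rec.chrom}:{rec.pos} has no ANN/EFF annotation"
                )
            if isinstance(raw, str):
                raw = (raw,)
            parse = _parse_ann_entry if "ANN" in rec.info else _parse_eff_entry
            entries = [parse(e) for e in raw]
            in_dbsnp = bool(rec.id and rec.id.startswith("rs")) or (
                "DB" in rec.info
            )
            in_cosmic = "COSMIC" in rec.info
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or alt == rec.ref:
                    continue  # SNVs only
                matching = [e for e in entries if e[0] in ("", alt)]
                if not matching:
                    matching = entries
                best = min(
                    range(len(matching)),
                    key=lambda i: (impact_rank(matching[i][2]), i),
                )
                _, eff, impact, gene = matching[best]
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        gene=gene,
                        effect=eff,
                        impact=impact,
                        in_dbsnp=in_dbsnp,
                        in_cosmic=in_cosmic,
                    )
                )
    return records


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "patient", "site"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    metas = [
        SampleMeta(r.sample_id, r.patient, r.site, getattr(r, "label", ""))
        for r in df.itertuples(index=False)
    ]
    seen = set()
    for m in metas:
        key = (m.patient, m.site)
        if key in seen:
            raise ValueError(f"duplicate (patient, site) pair: {key}")
        seen.add(key)
    return metas


def read_counts_table(
    path: str | Path, samples: Sequence[SampleMeta] | None = None
) -> list[AlleleCounts]:
    """Read the counts TSV (variant_id, sample_id, assay, ref_reads,
    alt_reads), validating the closed assay vocabulary, non-negative counts
    and — when a sample sheet is supplied — known sample ids.  Errors cite
    the 1-based data row number.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["variant_id", "sample_id", "assay", "ref_reads", "alt_reads"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    known = {s.sample_id for s in samples} if samples is not None else None
    out: list[AlleleCounts] = []
    for i, r in enumerate(df.itertuples(index=False), start=1):
        if r.assay not in ASSAYS:
            raise ValueError(f"row {i}: unknown assay {r.assay!r}")
        if r.ref_reads < 0 or r.alt_reads < 0:
            raise ValueError(f"row {i}: negative read count")
        if known is not None and r.sample_id not in known:
            raise ValueError(f"row {i}: unknown sample_id {r.sample_id!r}")
        out.append(
            AlleleCounts(
                str(r.variant_id), str(r.sample_id), str(r.assay),
                int(r.ref_reads), int(r.alt_reads),
            )
        )
    return out


def counts_to_frame(counts: Iterable[AlleleCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [c.variant_id for c in counts],
            "sample_id": [c.sample_id for c in counts],
            "assay": [c.assay for c in counts],
            "ref_reads": [c.ref_reads for c in counts],
            "alt_reads": [c.alt_reads for c in counts],
        }
    )


_CODING_IMPACTS = {"HIGH", "MODERATE", "LOW"}


def filter_variants(
    records: Sequence[VariantRecord],
    counts: pd.DataFrame | Iterable[AlleleCounts],
    *,
    min_reads: int = 8,
    coding_only: bool = True,
    samples: Sequence[SampleMeta] | None = None,
) -> set[tuple[str, str]]:
    """Coverage + coding filter.

    A (variant, sample) pair survives iff both the exome and the RNA assay
    of that sample have depth >= ``min_reads`` and, with ``coding_only``,
    the variant's impact is HIGH/MODERATE/LOW with a coding effect.  When a
    sample sheet is supplied, normal (NO) samples are excluded — they carry
    no RNA assay and are a baseline, not a test unit.  Returns the set of
    surviving (variant_id, sample_id) pairs; monotone non-increasing in
    ``min_reads``.
    """
    if not isinstance(counts, pd.DataFrame):
        counts = counts_to_frame(counts)
    by_id = {r.variant_id: r for r in records}
    keep_var = {
        vid
        for vid, r in by_id.items()
        if not coding_only
        or (r.impact in _CODING_IMPACTS and r.effect != "other")
    }
    tumor_samples = None
    if samples is not None:
        tumor_samples = {s.sample_id for s in samples if s.site != "NO"}

    depth = (
        counts.assign(depth=counts["ref_reads"] + counts["alt_reads"])
        .pivot_table(
            index=["variant_id", "sample_id"],
            columns="assay",
            values="depth",
            aggfunc="sum",
            fill_value=0,
        )
    )
    for assay in ASSAYS:
        if assay not in depth.columns:
            depth[assay] = 0
    ok = depth[(depth["exome"] >= min_reads) & (depth["rna"] >= min_reads)]
    out = set()
    for vid, sid in ok.index:
        if vid not in by_id or vid not in keep_var:
            continue
        if tumor_samples is not None and sid not in tumor_samples:
            continue
        out.add((vid, sid))
    return out


def classify_origin(
    variant: VariantRecord,
    normal_counts: AlleleCounts | None = None,
    min_reads: int = 8,
) -> str:
    """Somatic / germline call from the matched-normal exome.

    With a normal sample covered at >= ``min_reads``: zero alternate reads
    in the normal means somatic, any alternate read means germline.  Without
    a usable normal the call falls back to database membership: dbSNP
    presence gives ``likely_germline``, otherwise ``unknown``.
    """
    if normal_counts is not None and normal_counts.depth >= min_reads:
        return "somatic" if normal_counts.alt_reads == 0 else "germline"
    return "likely_germline" if variant.in_dbsnp else "unknown"
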