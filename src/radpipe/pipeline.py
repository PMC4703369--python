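"""End-to-end orchestration: read -> filter -> RAD calls -> origin ->
aggregation -> sharing -> selection -> site patterns, with a run manifest.

Every stage is a pure function over data frames so tests and scripts can
call them directly; :func:`run_pipeline` wires them together and writes the
TSV outputs.  A single seed governs all stochastic stages (the resampling
null); outputs are a deterministic function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import __version__
from .records import AlleleCounts, SampleMeta, TUMOR_SITE_ORDER, VariantRecord
from .rad_core import (
    aggregate_gene_class,
    call_preferential_expression,
    exome_af_vs_one_test,
)
from .selection_analysis import nonsyn_syn_ratios, ratio_cdf
from .shared_genes import resample_shared_pvalue, shared_sets
from .site_patterns import assign_site_pattern, build_rad_matrix, cluster_rad_matrix
from .variant_io import (
    classify_origin,
    read_annotated_vcf,
    read_counts_table,
    read_sample_sheet,
    counts_to_frame,
)

__all__ = [
    "PipelineConfig",
    "compute_rad_results",
    "gene_site_classes",
    "gene_patient_classes",
    "significant_sets",
    "tested_pools",
    "site_pattern_table",
    "run_pipeline",
    "run_somatic_analysis",
]

RESULT_COLUMNS = [
    "variant_id", "gene", "patient", "site",
    "exome_ref", "exome_alt", "rna_ref", "rna_alt",
    "exome_af", "rna_af", "rad", "p_midp", "klass", "origin",
]


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags for one pipeline run."""

    vcf: str = ""
    counts: str = ""
    samples: str = ""
    out_dir: str = "radpipe_out"
    min_reads: int = 8
    p_threshold: float = 0.1
    rad_cutoff: float = 0.2
    n_trials: int = 1000
    seed: int = 0
    coding_only: bool = True
    fdr_adjust: bool = False
    sharing_level: str = "gene"  # or "variant"
    strict_not_expressed: bool = True
    min_variants: int = 2  # selection-analysis gene threshold

    def validate(self) -> None:
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError("p_threshold must lie in (0, 1]")
        if not (0.0 <= self.rad_cutoff <= 1.0):
            raise ValueError("rad_cutoff must lie in [0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.sharing_level not in ("gene", "variant"):
            raise ValueError("sharing_level must be 'gene' or 'variant'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _depth_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Wide per-(variant, sample) table of ref/alt counts per assay."""
    wide = counts.pivot_table(
        index=["variant_id", "sample_id"],
        columns="assay",
        values=["ref_reads", "alt_reads"],
        aggfunc="sum",
        fill_value=0,
    )
    wide.columns = [f"{assay}_{val.split('_')[0]}" for val, assay in wide.columns]
    for col in ("exome_ref", "exome_alt", "rna_ref", "rna_alt"):
        if col not in wide.columns:
            wide[col] = 0
    return wide.reset_index()


def _normal_exome_counts(
    counts: pd.DataFrame, samples: Sequence[SampleMeta]
) -> dict[str, dict[str, tuple[int, int]]]:
    """patient -> variant_id -> (ref, alt) from the NO exome, if present."""
    normals = {s.sample_id: s.patient for s in samples if s.site == "NO"}
    sub = counts[
        (counts["sample_id"].isin(normals)) & (counts["assay"] == "exome")
    ]
    out: dict[str, dict[str, tuple[int, int]]] = {}
    for r in sub.itertuples(index=False):
        out.setdefault(normals[r.sample_id], {})[r.variant_id] = (
            int(r.ref_reads),
            int(r.alt_reads),
        )
    return out


_CODING_IMPACTS = {"HIGH", "MODERATE", "LOW"}


def compute_rad_results(
    variants: Sequence[VariantRecord],
    counts: pd.DataFrame | Iterable[AlleleCounts],
    samples: Sequence[SampleMeta],
    *,
    min_reads: int = 8,
    p_threshold: float = 0.1,
    rad_cutoff: float = 0.2,
    coding_only: bool = True,
    strict_not_expressed: bool = True,
    baseline: str = "tumor",
    fdr_adjust: bool = False,
) -> pd.DataFrame:
    """Per-(variant, tumor sample) preferential-expression calls.

    Pairs whose exome depth reaches ``min_reads`` are called; of those,
    pairs with insufficient RNA depth become ``not_expressed`` rows, the
    rest are tested.  With ``baseline="normal"`` the matched-normal exome
    replaces the tumor exome as the genomic side (pairs whose patient lacks
    a covered normal are dropped) — used for the control-correction
    discordance estimate.  ``fdr_adjust`` re-classifies significance on
    Benjamini-Hochberg-adjusted p-values.
    """
    if baseline not in ("tumor", "normal"):
        raise ValueError("baseline must be 'tumor' or 'normal'")
    if not isinstance(counts, pd.DataFrame):
        counts = counts_to_frame(counts)
    by_id = {v.variant_id: v for v in variants}
    meta = {s.sample_id: s for s in samples}
    tumor_ids = {s.sample_id for s in samples if s.site != "NO"}
    normal_counts = _normal_exome_counts(counts, samples)

    wide = _depth_table(counts)
    wide = wide[wide["sample_id"].isin(tumor_ids)]
    rows = []
    for r in wide.itertuples(index=False):
        v = by_id.get(r.variant_id)
        if v is None:
            continue
        if coding_only and not (
            v.impact in _CODING_IMPACTS and v.effect != "other"
        ):
            continue
        sm = meta[r.sample_id]
        e_ref, e_alt = int(r.exome_ref), int(r.exome_alt)
        nc = normal_counts.get(sm.patient, {}).get(r.variant_id)
        if baseline == "normal":
            if nc is None or nc[0] + nc[1] < min_reads:
                continue
            e_ref, e_alt = nc
        if e_ref + e_alt < min_reads:
            continue
        nc_rec = (
            AlleleCounts(r.variant_id, f"{sm.patient}_NO", "exome", nc[0], nc[1])
            if nc is not None
            else None
        )
        origin = classify_origin(v, nc_rec, min_reads=min_reads)
        call = call_preferential_expression(
            e_ref, e_alt, int(r.rna_ref), int(r.rna_alt),
            p_threshold=p_threshold, rad_cutoff=rad_cutoff,
            min_reads=min_reads, strict_not_expressed=strict_not_expressed,
        )
        rows.append(
            {
                "variant_id": r.variant_id,
                "gene": v.gene,
                "patient": sm.patient,
                "site": sm.site,
                "exome_ref": e_ref,
                "exome_alt": e_alt,
                "rna_ref": int(r.rna_ref),
                "rna_alt": int(r.rna_alt),
                "exome_af": call.exome_af,
                "rna_af": call.rna_af,
                "rad": call.rad,
                "p_midp": call.p_midp,
                "klass": call.klass,
                "origin": origin,
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df = df.sort_values(["variant_id", "patient", "site"], ignore_index=True)
    if fdr_adjust and len(df):
        tested = df["p_midp"].notna()
        if tested.any():
            _, q, _, _ = multipletests(
                df.loc[tested, "p_midp"], method="fdr_bh"
            )
            df.loc[tested, "q_value"] = q
            sig = tested & (df["q_value"] < p_threshold)
            neg = sig & (
                df["rad"] <= -rad_cutoff if rad_cutoff > 0 else df["rad"] < 0
            )
            pos = sig & (
                df["rad"] >= rad_cutoff if rad_cutoff > 0 else df["rad"] > 0
            )
            df.loc[tested, "klass"] = "none"
            df.loc[neg, "klass"] = "negative"
            df.loc[pos, "klass"] = "positive"
    return df


def gene_site_classes(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate variant calls to one class per (gene, patient, site)."""
    if results.empty:
        return pd.DataFrame(columns=["gene", "patient", "site", "klass"])
    agg = (
        results.groupby(["gene", "patient", "site"])["klass"]
        .apply(lambda k: aggregate_gene_class(list(k)))
        .reset_index()
    )
    return agg


def gene_patient_classes(results: pd.DataFrame) -> pd.DataFrame:
    """One aggregate class per (gene, patient), shading across all sites."""
    if results.empty:
        return pd.DataFrame(columns=["gene", "patient", "klass"])
    per_site = gene_site_classes(results)
    # mixed at site level participates as both directions at patient level
    def _agg(klasses: list[str]) -> str:
        expanded: list[str] = []
        for k in klasses:
            if k == "mixed":
                expanded.extend(["negative", "positive"])
            else:
                expanded.append(k)
        return aggregate_gene_class(expanded)

    return (
        per_site.groupby(["gene", "patient"])["klass"]
        .apply(lambda k: _agg(list(k)))
        .reset_index()
    )


def significant_sets(
    results: pd.DataFrame,
    level: str = "gene",
    direction: str = "negative",
    group_by: str = "patient",
) -> dict[str, set]:
    """Per-group sets of significant genes or variants (union across sites)."""
    if level not in ("gene", "variant"):
        raise ValueError("level must be 'gene' or 'variant'")
    key = "gene" if level == "gene" else "variant_id"
    sig = results[results["klass"] == direction]
    out: dict[str, set] = {g: set() for g in results[group_by].unique()}
    for g, sub in sig.groupby(group_by):
        out[g] = set(sub[key])
    return out


def tested_pools(
    results: pd.DataFrame, level: str = "gene", group_by: str = "patient"
) -> dict[str, set]:
    """Per-group universes of tested genes/variants (klass != not_expressed)."""
    key = "gene" if level == "gene" else "variant_id"
    tested = results[results["klass"] != "not_expressed"]
    out: dict[str, set] = {g: set() for g in results[group_by].unique()}
    for g, sub in tested.groupby(group_by):
        out[g] = set(sub[key])
    return out


def site_pattern_table(results: pd.DataFrame) -> pd.DataFrame:
    """Site-combination labels per (gene, patient).

    For pattern assignment a site counts as negative whenever *any* variant
    of the gene is called negative there — a co-occurring positive call at
    the same site does not veto it (unlike the patient-level shading
    aggregate, where both directions yield ``mixed``).
    """
    if results.empty:
        return pd.DataFrame(columns=["gene", "patient", "pattern"])
    any_negative = (
        results.assign(neg=results["klass"] == "negative")
        .groupby(["gene", "patient", "site"])["neg"]
        .any()
    )
    per_site = gene_site_classes(results)
    per_site["klass"] = np.where(
        [any_negative[(g, p, s)] for g, p, s in
         zip(per_site["gene"], per_site["patient"], per_site["site"])],
        "negative",
        per_site["klass"],
    )
    rad_by = results.groupby(["gene", "patient", "site"])["rad"].mean()
    rows = []
    for (gene, patient), sub in per_site.groupby(["gene", "patient"]):
        classes = dict(zip(sub["site"], sub["klass"]))
        per_site_rad = {
            s: rad_by.get((gene, patient, s), np.nan)
            for s in classes
        }
        a = assign_site_pattern(gene, patient, classes, per_site_rad)
        rows.append({"gene": gene, "patient": patient, "pattern": a.pattern})
    return pd.DataFrame(rows, columns=["gene", "patient", "pattern"])


def _selection_tables(
    results: pd.DataFrame,
    effects: Mapping[str, str],
    min_variants: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    ratio_rows, cdf_rows = [], []
    for (patient, site), sub in results.groupby(["patient", "site"]):
        triples = [
            (r.gene, effects.get(r.variant_id, "other"), r.klass)
            for r in sub.itertuples(index=False)
        ]
        recs = nonsyn_syn_ratios(triples, min_variants=min_variants)
        for rec in recs:
            ratio_rows.append(
                {
                    "patient": patient,
                    "site": site,
                    "gene": rec.gene,
                    "rad_class": rec.rad_class,
                    "n_nonsyn": rec.n_nonsyn,
                    "n_syn": rec.n_syn,
                    "ratio": rec.ratio,
                }
            )
        for klass in ("negative", "positive", "none"):
            klass_recs = [r for r in recs if r.rad_class == klass]
            if not klass_recs:
                continue
            values, cdf = ratio_cdf(klass_recs)
            for v, c in zip(values, cdf):
                cdf_rows.append(
                    {
                        "patient": patient,
                        "site": site,
                        "rad_class": klass,
                        "ratio": v,
                        "cdf": c,
                    }
                )
    ratios = pd.DataFrame(
        ratio_rows,
        columns=["patient", "site", "gene", "rad_class", "n_nonsyn", "n_syn", "ratio"],
    )
    cdfs = pd.DataFrame(
        cdf_rows, columns=["patient", "site", "rad_class", "ratio", "cdf"]
    )
    return ratios, cdfs


def _sharing_table(
    results: pd.DataFrame, level: str, n_trials: int, seed: int
) -> pd.DataFrame:
    rows = []
    for direction in ("negative", "positive"):
        sig = significant_sets(results, level=level, direction=direction)
        pools = tested_pools(results, level=level)
        sig = {k: v for k, v in sig.items() if pools.get(k)}
        pools = {k: pools[k] for k in sig}
        if len(sig) < 2:
            continue
        shared = resample_shared_pvalue(
            sig, pools, n_trials=n_trials, seed=seed,
            level=level, direction=direction,
        )
        for group, res in sorted(shared.items()):
            rows.append(
                {
                    "group": "+".join(group),
                    "level": level,
                    "direction": direction,
                    "observed_shared": res.observed_shared,
                    "pseudo_p": res.pseudo_p,
                    "null_mean": float(np.mean(res.null_counts)),
                    "n_trials": res.n_trials,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "level", "direction", "observed_shared",
            "pseudo_p", "null_mean", "n_trials",
        ],
    )


def _write_tsv(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# radpipe {__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all module TSVs plus a manifest.

    Returns the result bundle (data frames and clustering) keyed by stage.
    Rerunning with the same inputs, config and seed reproduces every output.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    variants = read_annotated_vcf(config.vcf)
    samples = read_sample_sheet(config.samples)
    count_recs = read_counts_table(config.counts, samples)
    counts = counts_to_frame(count_recs)

    results = compute_rad_results(
        variants, counts, samples,
        min_reads=config.min_reads,
        p_threshold=config.p_threshold,
        rad_cutoff=config.rad_cutoff,
        coding_only=config.coding_only,
        strict_not_expressed=config.strict_not_expressed,
        fdr_adjust=config.fdr_adjust,
    )
    gene_classes = gene_patient_classes(results)
    sharing = _sharing_table(
        results, config.sharing_level, config.n_trials, config.seed
    )
    effects = {v.variant_id: v.effect for v in variants}
    ratios, cdfs = _selection_tables(results, effects, config.min_variants)
    patterns = site_pattern_table(results)

    sig_mask = results["klass"].isin(["negative", "positive"])
    sig_variants = results.loc[sig_mask, "variant_id"].unique()
    matrix_rows = results[results["variant_id"].isin(sig_variants)]
    clustering = None
    matrix, flags = build_rad_matrix(matrix_rows) if len(matrix_rows) else (
        pd.DataFrame(), pd.DataFrame()
    )
    if matrix.shape[0] >= 2:
        clustering = cluster_rad_matrix(matrix)

    bundle = {
        "results": results,
        "gene_classes": gene_classes,
        "sharing": sharing,
        "selection_ratios": ratios,
        "selection_cdfs": cdfs,
        "site_patterns": patterns,
        "rad_matrix": matrix,
        "rad_matrix_flags": flags,
        "clustering": clustering,
    }

    seed = config.seed
    _write_tsv(results, out_dir / "rad_results.tsv", seed)
    _write_tsv(gene_classes, out_dir / "gene_classes.tsv", seed)
    _write_tsv(sharing, out_dir / "sharing.tsv", seed)
    _write_tsv(ratios, out_dir / "selection_ratios.tsv", seed)
    _write_tsv(cdfs, out_dir / "selection_cdfs.tsv", seed)
    _write_tsv(patterns, out_dir / "site_patterns.tsv", seed)
    if len(matrix):
        _write_tsv(matrix.reset_index(), out_dir / "rad_matrix.tsv", seed)
        _write_tsv(flags.reset_index(), out_dir / "rad_matrix_flags.tsv", seed)
    if clustering is not None:
        (out_dir / "rows.nwk").write_text(clustering["row_newick"] + "\n")
        if clustering["col_newick"]:
            (out_dir / "cols.nwk").write_text(clustering["col_newick"] + "\n")

    n_tested = int((results["klass"] != "not_expressed").sum()) if len(results) else 0
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "stages": {
            "variants_input": len(variants),
            "count_rows_input": len(counts),
            "samples_input": len(samples),
            "rad_rows": len(results),
            "tested_pairs": n_tested,
            "not_expressed_pairs": len(results) - n_tested,
            "significant_pairs": int(sig_mask.sum()) if len(results) else 0,
            "gene_class_rows": len(gene_classes),
            "sharing_rows": len(sharing),
            "selection_ratio_rows": len(ratios),
            "site_pattern_rows": len(patterns),
            "matrix_variants": int(matrix.shape[0]) if len(matrix) else 0,
        },
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    bundle["manifest"] = manifest
    return bundle


def run_somatic_analysis(config: PipelineConfig) -> dict:
    """Somatic-only preferential expression (matched-normal patients only).

    Restricts to variants classified somatic from the normal exome, applies
    the p-threshold without the RAD cutoff, relaxes the no-expression rule
    to zero RNA depth, and adds the exome-AF-vs-1 presence test per call.
    """
    config.validate()
    variants = read_annotated_vcf(config.vcf)
    samples = read_sample_sheet(config.samples)
    counts = counts_to_frame(read_counts_table(config.counts, samples))

    patients_with_normal = {s.patient for s in samples if s.site == "NO"}
    if not patients_with_normal:
        raise ValueError(
            "somatic analysis requires at least one patient with a matched "
            "normal (NO) sample"
        )
    excluded = {s.patient for s in samples} - patients_with_normal
    kept_samples = [s for s in samples if s.patient in patients_with_normal]

    results = compute_rad_results(
        variants, counts, kept_samples,
        min_reads=config.min_reads,
        p_threshold=config.p_threshold,
        rad_cutoff=0.0,
        coding_only=config.coding_only,
        strict_not_expressed=False,
    )
    somatic = results[results["origin"] == "somatic"].reset_index(drop=True)
    if len(somatic):
        presence = [
            exome_af_vs_one_test(int(r.exome_ref), int(r.exome_alt))
            for r in somatic.itertuples(index=False)
        ]
        somatic = somatic.assign(
            exome_presence=[p[0] for p in presence],
            exome_presence_p=[p[1] for p in presence],
        )
    gene_classes = gene_patient_classes(somatic)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_tsv(somatic, out_dir / "somatic_results.tsv", config.seed)
    _write_tsv(gene_classes, out_dir / "somatic_gene_classes.tsv", config.seed)
    return {
        "somatic_results": somatic,
        "somatic_gene_classes": gene_classes,
        "patients_excluded": sorted(excluded),
    }
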