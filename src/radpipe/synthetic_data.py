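"""Synthetic matched multi-site tumor cohorts with ground truth.

Emulates the data model of a combined genome-and-transcriptome study: each
patient contributes one normal exome (NO) and several tumor sites (OV, PE,
LN), each tumor site sequenced with both an exome and an RNA assay.  The
generator plants the statistical structure the downstream analysis assumes:

* germline heterozygous variants with DNA reference AF near 0.5, perturbed
  per tumor site by a logit-normal skew (a copy-number / admixture
  surrogate) that is *shared* between the DNA and the null RNA of that
  site — so subtracting the exome AF cancels it;
* a minority of somatic variants, absent from the normal and present in
  tumor sites at a cellularity-scaled alternate fraction;
* allele-specific expression planted on a configurable subset of variants:
  the RNA reference AF is shifted by +-ase_delta (clipped to [0, 1]) in a
  per-gene set of tumor sites, all other variants expressing both alleles
  at their genomic dosage;
* read counts drawn binomially at Poisson-distributed depths, depth 0
  included so the no-expression path is exercised.

ASE direction and site set are drawn per gene and applied to all of that
gene's planted variants: allele-specific expression is a cis-regulatory,
gene-level phenomenon, and this makes site-pattern recovery well defined.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .records import SampleMeta, TUMOR_SITE_ORDER, VariantRecord

__all__ = ["SimulationConfig", "SimulatedCohort", "simulate_cohort", "write_cohort"]

_BASES = np.array(["A", "C", "G", "T"])


class ConfigError(ValueError):
    """A SimulationConfig field is out of range."""


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Proportions are fractions of the variant universe; depths are Poisson
    means per assay.  ``cn_skew_sd`` is the standard deviation of the
    logit-scale perturbation applied to each (variant, tumor site) DNA
    reference AF.
    """

    n_patients: int = 3
    sites_per_patient: tuple[str, ...] = ("OV", "PE", "LN")
    n_genes: int = 400
    variants_per_gene: int | tuple[int, int] = 3
    het_fraction: float = 0.95
    somatic_fraction: float = 0.05
    ase_fraction: float = 0.05
    ase_delta: float = 0.4
    cn_skew_sd: float = 0.3
    nonsyn_prob_ase: float = 0.5
    nonsyn_prob_null: float = 0.5
    depth_mean_exome: float = 60.0
    depth_mean_rna: float = 60.0
    somatic_dna_alt_af: float = 0.3
    stop_gained_frac: float = 0.05  # of non-synonymous variants
    dbsnp_rate_germline: float = 0.95
    dbsnp_rate_somatic: float = 0.02
    cosmic_rate_somatic: float = 0.30
    cosmic_rate_germline: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "het_fraction", "somatic_fraction", "ase_fraction", "ase_delta",
            "nonsyn_prob_ase", "nonsyn_prob_null", "somatic_dna_alt_af",
            "stop_gained_frac", "dbsnp_rate_germline", "dbsnp_rate_somatic",
            "cosmic_rate_somatic", "cosmic_rate_germline",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.het_fraction + self.somatic_fraction > 1.0 + 1e-12:
            raise ConfigError("het_fraction + somatic_fraction exceeds 1")
        for name in ("n_patients", "n_genes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not self.sites_per_patient:
            raise ConfigError("sites_per_patient must be nonempty")
        bad = set(self.sites_per_patient) - set(TUMOR_SITE_ORDER)
        if bad:
            raise ConfigError(f"sites_per_patient has unknown sites: {sorted(bad)}")
        for name in ("depth_mean_exome", "depth_mean_rna"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.cn_skew_sd < 0:
            raise ConfigError("cn_skew_sd must be >= 0")
        vpg = self.variants_per_gene
        if isinstance(vpg, int):
            if vpg < 1:
                raise ConfigError("variants_per_gene must be >= 1")
        else:
            lo, hi = vpg
            if lo < 1 or hi < lo:
                raise ConfigError("variants_per_gene range must satisfy 1 <= lo <= hi")


@dataclass
class SimulatedCohort:
    """In-memory cohort: variants, samples, per-assay counts and truth.

    ``counts`` has one row per (variant, sample, assay) with coverage
    attempted (depth may be 0): columns variant_id, sample_id, assay,
    ref_reads, alt_reads.  ``truth`` has one row per variant with the
    planted labels: origin, zygosity, is_ase, ase_direction, ase_sites
    (concatenated in OV/PE/LN order, empty when not ASE) and the per-site
    true allele fractions are recoverable from the config.
    """

    config: SimulationConfig
    variants: list[VariantRecord]
    samples: list[SampleMeta]
    counts: pd.DataFrame
    truth: pd.DataFrame

    @property
    def n_variants(self) -> int:
        return len(self.variants)


def _site_subsets(sites: tuple[str, ...]) -> list[tuple[str, ...]]:
    ordered = tuple(s for s in TUMOR_SITE_ORDER if s in sites)
    out = []
    for r in range(1, len(ordered) + 1):
        out.extend(itertools.combinations(ordered, r))
    return out


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a reproducible cohort; identical config+seed => identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- variant universe -------------------------------------------------
    if isinstance(config.variants_per_gene, int):
        vpg = np.full(config.n_genes, config.variants_per_gene, dtype=int)
    else:
        lo, hi = config.variants_per_gene
        vpg = rng.integers(lo, hi + 1, size=config.n_genes)
    n_var = int(vpg.sum())
    gene_idx = np.repeat(np.arange(config.n_genes), vpg)
    genes = np.array([f"GENE{i + 1:05d}" for i in range(config.n_genes)])

    chroms = np.array([f"chr{(i % 22) + 1}" for i in gene_idx])
    # unique, increasing positions within each chromosome
    pos = np.zeros(n_var, dtype=int)
    for c in np.unique(chroms):
        mask = chroms == c
        pos[mask] = 1000 + 500 * np.arange(mask.sum())
    ref_i = rng.integers(0, 4, size=n_var)
    alt_i = (ref_i + rng.integers(1, 4, size=n_var)) % 4

    # --- origin / zygosity -------------------------------------------------
    u = rng.random(n_var)
    origin = np.where(u < config.somatic_fraction, "somatic", "germline")
    zygosity = np.where(
        u < config.somatic_fraction,
        "het",
        np.where(u < config.somatic_fraction + config.het_fraction, "het", "hom"),
    )

    # --- planted ASE (per-gene direction and site set) ---------------------
    n_ase = int(round(config.ase_fraction * n_var))
    eligible = np.flatnonzero(zygosity == "het")
    if n_ase > eligible.size:
        raise ConfigError(
            "ase_fraction too large for the heterozygous variant pool"
        )
    ase_idx = rng.choice(eligible, size=n_ase, replace=False) if n_ase else np.array([], dtype=int)
    is_ase = np.zeros(n_var, dtype=bool)
    is_ase[ase_idx] = True

    subsets = _site_subsets(config.sites_per_patient)
    gene_dir: dict[int, str] = {}
    gene_sites: dict[int, tuple[str, ...]] = {}
    for g in sorted(set(gene_idx[ase_idx])):
        gene_dir[g] = "negative" if rng.random() < 0.5 else "positive"
        gene_sites[g] = subsets[rng.integers(0, len(subsets))]
    ase_direction = np.array(
        [gene_dir.get(g, "") if a else "" for g, a in zip(gene_idx, is_ase)],
        dtype=object,
    )
    ase_sites = [gene_sites.get(g, ()) if a else () for g, a in zip(gene_idx, is_ase)]

    # --- annotation --------------------------------------------------------
    p_nonsyn = np.where(is_ase, config.nonsyn_prob_ase, config.nonsyn_prob_null)
    nonsyn = rng.random(n_var) < p_nonsyn
    stopg = nonsyn & (rng.random(n_var) < config.stop_gained_frac)
    effect = np.where(stopg, "stop_gained", np.where(nonsyn, "nonsynonymous", "synonymous"))
    impact = np.where(stopg, "HIGH", np.where(nonsyn, "MODERATE", "LOW"))

    is_somatic = origin == "somatic"
    in_dbsnp = np.where(
        is_somatic,
        rng.random(n_var) < config.dbsnp_rate_somatic,
        rng.random(n_var) < config.dbsnp_rate_germline,
    )
    in_cosmic = np.where(
        is_somatic,
        rng.random(n_var) < config.cosmic_rate_somatic,
        rng.random(n_var) < config.cosmic_rate_germline,
    )

    variants = [
        VariantRecord(
            chrom=chroms[i],
            pos=int(pos[i]),
            ref_allele=str(_BASES[ref_i[i]]),
            alt_allele=str(_BASES[alt_i[i]]),
            gene=str(genes[gene_idx[i]]),
            effect=str(effect[i]),
            impact=str(impact[i]),
            in_dbsnp=bool(in_dbsnp[i]),
            in_cosmic=bool(in_cosmic[i]),
        )
        for i in range(n_var)
    ]
    vids = np.array([v.variant_id for v in variants])

    # --- samples -----------------------------------------------------------
    samples: list[SampleMeta] = []
    for p in range(1, config.n_patients + 1):
        samples.append(SampleMeta(f"P{p}_NO", f"P{p}", "NO", label="normal"))
        for s in config.sites_per_patient:
            samples.append(SampleMeta(f"P{p}_{s}", f"P{p}", s))

    # --- allele fractions and counts ---------------------------------------
    het = zygosity == "het"
    hom = zygosity == "hom"
    som = is_somatic
    base_logit = np.where(som, logit(1.0 - config.somatic_dna_alt_af), 0.0)

    frames = []
    for sm in samples:
        if sm.site == "NO":
            dna_af = np.where(som, 1.0, np.where(hom, 0.0, 0.5))
            assays = [("exome", config.depth_mean_exome, dna_af)]
        else:
            skew = rng.normal(0.0, config.cn_skew_sd, size=n_var) if config.cn_skew_sd > 0 else 0.0
            dna_af = expit(base_logit + skew)
            dna_af = np.where(hom, 0.0, dna_af)
            rna_af = dna_af.copy()
            in_site = np.array(
                [a and sm.site in ss for a, ss in zip(is_ase, ase_sites)]
            )
            shift = np.where(ase_direction == "negative", -config.ase_delta, config.ase_delta)
            rna_af = np.where(in_site, np.clip(dna_af + shift, 0.0, 1.0), rna_af)
            assays = [
                ("exome", config.depth_mean_exome, dna_af),
                ("rna", config.depth_mean_rna, rna_af),
            ]
        for assay, mean_depth, af in assays:
            depth = rng.poisson(mean_depth, size=n_var)
            ref = rng.binomial(depth, af)
            frames.append(
                pd.DataFrame(
                    {
                        "variant_id": vids,
                        "sample_id": sm.sample_id,
                        "assay": assay,
                        "ref_reads": ref,
                        "alt_reads": depth - ref,
                    }
                )
            )
    counts = pd.concat(frames, ignore_index=True)

    truth = pd.DataFrame(
        {
            "variant_id": vids,
            "gene": genes[gene_idx],
            "origin": origin,
            "zygosity": zygosity,
            "is_ase": is_ase,
            "ase_direction": ase_direction,
            "ase_sites": ["".join(ss) for ss in ase_sites],
            "effect": effect,
        }
    )

    return SimulatedCohort(
        config=config, variants=variants, samples=samples, counts=counts, truth=truth
    )


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: 'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | Feature_Type | Feature_ID | Transcript_BioType | Rank | HGVS.c | HGVS.p | cDNA.pos / cDNA.length | CDS.pos / CDS.length | AA.pos / AA.length | Distance | ERRORS / WARNINGS / INFO'">
##INFO=<ID=COSMIC,Number=0,Type=Flag,Description="Variant present in COSMIC">
"""

_EFFECT_TO_SO = {
    "synonymous": "synonymous_variant",
    "nonsynonymous": "missense_variant",
    "stop_gained": "stop_gained",
    "splice": "splice_region_variant",
    "other": "intron_variant",
}


def write_cohort(cohort: SimulatedCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as plain-text files readable by :mod:`radpipe.variant_io`.

    Emits ``variants.vcf`` (SnpEff-style ANN entries), ``counts.tsv``,
    ``samples.tsv`` and ``truth.tsv``; returns the path of each.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": directory / "variants.vcf",
        "counts": directory / "counts.tsv",
        "samples": directory / "samples.tsv",
        "truth": directory / "truth.tsv",
    }

    contigs = sorted({v.chrom for v in cohort.variants}, key=lambda c: (len(c), c))
    lines = [_VCF_HEADER.rstrip("\n")]
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    rs_counter = 0
    order = sorted(range(len(cohort.variants)),
                   key=lambda i: (contigs.index(cohort.variants[i].chrom),
                                  cohort.variants[i].pos))
    for i in order:
        v = cohort.variants[i]
        if v.in_dbsnp:
            rs_counter += 1
            vid = f"rs{900000 + i}"
        else:
            vid = "."
        ann = "|".join(
            [
                v.alt_allele,
                _EFFECT_TO_SO[v.effect],
                v.impact,
                v.gene,
                v.gene,
                "transcript",
                f"{v.gene}.t1",
                "protein_coding",
            ]
            + [""] * 8
        )
        info = f"ANN={ann}"
        if v.in_cosmic:
            info += ";COSMIC"
        lines.append(
            f"{v.chrom}\t{v.pos}\t{vid}\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t{info}"
        )
    paths["vcf"].write_text("\n".join(lines) + "\n")

    cohort.counts.to_csv(paths["counts"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"sample_id": s.sample_id, "patient": s.patient, "site": s.site, "label": s.label}
            for s in cohort.samples
        ]
    ).to_csv(paths["samples"], sep="\t", index=False)
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
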