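#!/usr/bin/env python
"""Generate the reference synthetic cohort used by the downstream analyses.

Three patients, each with a normal exome and three tumor sites (OV, PE, LN)
sequenced with exome + RNA at mean depth 60: germline-het dominated, 5%
somatic, copy-number skew sd 0.3, and allele-specific expression planted on
5% of variants at |delta AF| = 0.4.  Writes the cohort (VCF, counts TSV,
sample sheet, truth TSV) under results/cohort/.
"""

from pathlib import Path

from radpipe.synthetic_data import SimulationConfig, simulate_cohort, write_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 7


def main() -> None:
    config = SimulationConfig(
        n_patients=3,
        sites_per_patient=("OV", "PE", "LN"),
        n_genes=400,
        variants_per_gene=3,
        ase_fraction=0.05,
        ase_delta=0.4,
        cn_skew_sd=0.3,
        depth_mean_exome=60.0,
        depth_mean_rna=60.0,
        seed=SEED,
    )
    cohort = simulate_cohort(config)
    paths = write_cohort(cohort, OUT)
    truth = cohort.truth
    print(f"cohort: {cohort.n_variants} variants in {config.n_genes} genes, "
          f"{len(cohort.samples)} samples, seed={SEED}")
    print(f"  somatic variants: {(truth['origin'] == 'somatic').sum()}")
    print(f"  planted ASE variants: {truth['is_ase'].sum()} "
          f"({truth.loc[truth['is_ase'], 'ase_direction'].value_counts().to_dict()})")
    for name, p in paths.items():
        print(f"  wrote {name}: {p}")


if __name__ == "__main__":
    main()
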