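#!/usr/bin/env python
"""Site-combination patterns of negative-RAD genes and RAD-matrix clustering.

Labels every (gene, patient) by the combination of tumor sites (OV, PE, LN)
showing significant preferential expression of the variant allele, tallies
the seven possible non-empty patterns, and hierarchically clusters the
variants x sample-sites RAD matrix (significant variants only).  Writes
results/patterns/.
"""

from pathlib import Path

import pandas as pd

from radpipe.pipeline import compute_rad_results, site_pattern_table
from radpipe.site_patterns import build_rad_matrix, cluster_rad_matrix
from radpipe.variant_io import (
    counts_to_frame,
    read_annotated_vcf,
    read_counts_table,
    read_sample_sheet,
)

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "patterns"


def main() -> None:
    variants = read_annotated_vcf(COHORT / "variants.vcf")
    samples = read_sample_sheet(COHORT / "samples.tsv")
    counts = counts_to_frame(read_counts_table(COHORT / "counts.tsv", samples))
    results = compute_rad_results(variants, counts, samples)

    OUT.mkdir(parents=True, exist_ok=True)
    patterns = site_pattern_table(results)
    patterns.to_csv(OUT / "site_patterns.tsv", sep="\t", index=False)
    tallies = (
        patterns[patterns["pattern"] != "none"]["pattern"]
        .value_counts()
        .reindex(["OV", "PE", "LN", "OVPE", "OVLN", "PELN", "OVPELN"])
        .fillna(0)
        .astype(int)
    )
    print("gene-patient pattern counts (negative-RAD sites):")
    for pattern, n in tallies.items():
        print(f"  {pattern:>6}: {n}")

    sig = results[results["klass"].isin(["negative", "positive"])]
    matrix_rows = results[results["variant_id"].isin(sig["variant_id"].unique())]
    matrix, flags = build_rad_matrix(matrix_rows)
    matrix.reset_index().to_csv(OUT / "rad_matrix.tsv", sep="\t", index=False)
    if matrix.shape[0] >= 2:
        clust = cluster_rad_matrix(matrix)
        (OUT / "rows.nwk").write_text(clust["row_newick"] + "\n")
        if clust["col_newick"]:
            (OUT / "cols.nwk").write_text(clust["col_newick"] + "\n")
        print(f"clustered {matrix.shape[0]} significant variants x "
              f"{matrix.shape[1]} sample-sites; column order: "
              f"{clust['col_order']}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
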