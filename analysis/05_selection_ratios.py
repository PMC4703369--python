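#!/usr/bin/env python
"""Non-synonymous/synonymous count ratios per gene, stratified by RAD class.

For every sample-site, genes with at least two usable variants inside a RAD
class contribute a non-syn/syn count ratio; comparing the ratio CDFs of the
negative-RAD class against the no-difference class probes for selection on
preferentially expressed alleles.  Writes results/selection/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from radpipe.pipeline import PipelineConfig, compute_rad_results
from radpipe.selection_analysis import nonsyn_syn_ratios, ratio_cdf
from radpipe.variant_io import (
    counts_to_frame,
    read_annotated_vcf,
    read_counts_table,
    read_sample_sheet,
)

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "selection"


def main() -> None:
    variants = read_annotated_vcf(COHORT / "variants.vcf")
    samples = read_sample_sheet(COHORT / "samples.tsv")
    counts = counts_to_frame(read_counts_table(COHORT / "counts.tsv", samples))
    results = compute_rad_results(variants, counts, samples)
    effects = {v.variant_id: v.effect for v in variants}

    OUT.mkdir(parents=True, exist_ok=True)
    ratio_rows = []
    for min_variants in (2, 4):
        for (patient, site), sub in results.groupby(["patient", "site"]):
            triples = [
                (r.gene, effects[r.variant_id], r.klass)
                for r in sub.itertuples(index=False)
            ]
            for rec in nonsyn_syn_ratios(triples, min_variants=min_variants):
                ratio_rows.append(
                    {
                        "min_variants": min_variants,
                        "patient": patient,
                        "site": site,
                        "gene": rec.gene,
                        "rad_class": rec.rad_class,
                        "n_nonsyn": rec.n_nonsyn,
                        "n_syn": rec.n_syn,
                        "ratio": rec.ratio,
                    }
                )
    df = pd.DataFrame(ratio_rows)
    df.to_csv(OUT / "ratios.tsv", sep="\t", index=False)

    at2 = df[df["min_variants"] == 2]
    for klass in ("negative", "positive", "none"):
        vals = at2.loc[at2["rad_class"] == klass, "ratio"]
        finite = vals[np.isfinite(vals)]
        print(f"{klass:>8}: {len(vals)} gene records, median ratio "
              f"{finite.median() if len(finite) else float('nan'):.2f}, "
              f"{np.isinf(vals).sum()} all-nonsynonymous genes")
    print(f"wrote {OUT / 'ratios.tsv'}")


if __name__ == "__main__":
    main()
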