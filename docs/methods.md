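# Methods

## Model

The unit of analysis is a biallelic single-nucleotide coding variant
observed in one tumor sample with two assays: exome sequencing (the
genomic dosage) and RNA sequencing (the expressed dosage).  Writing
`ref`/`alt` for reference/alternate read counts, the reference allele
fraction per assay is `AF = ref / (ref + alt)` and the statistic of
interest is

    RAD = AF_rna - AF_exome,   RAD in [-1, 1].

The null hypothesis is that RNA reads sample the same allele proportion as
DNA reads: expression proportional to genomic dosage.  Copy-number change,
loss of heterozygosity and normal-cell admixture shift `AF_exome` away
from 0.5, but they shift the null `AF_rna` identically, so the subtraction
— and the exact test below, which conditions on both assay totals — is
insensitive to them.  This is the central assumption: **the exome of the
same specimen is the correct expression baseline**.  It fails only where
DNA and RNA were sampled from cell populations with different genotype
mixtures, which matched aliquots make unlikely.

### Significance

The 2x2 table (rows: exome/RNA; columns: ref/alt) is tested with a
two-sided Fisher exact test under the mid-P rule.  With all margins fixed,
table probabilities are hypergeometric; the p-value is

    p = sum{ Pr(t) : Pr(t) < Pr(obs) } + 0.5 * sum{ Pr(t) : Pr(t) = Pr(obs) }.

Mid-P counts half of the equiprobable class (including the observed table
itself), giving a test with close-to-nominal size instead of the marked
conservatism of the classic exact test; it is not guaranteed conservative,
which the raw p < 0.1 threshold tolerates.  The implementation enumerates
the support with exact integer numerators (`math.comb`), classifies
strictly-less / exactly-equal by integer comparison — so ties between
equiprobable tables are never misclassified by float rounding — and
performs one correctly-rounded big-integer division at the end.  Curves
are cached per margin triple `(n_exome, n_rna, ref_total)`.

### Calling rules

A (variant, tumor sample) pair is **tested** when both assays have >= 8
reads (`min_reads`).  A tested pair is called

- `negative` if p < 0.1 and RAD <= -0.2 (alternate allele preferentially
  expressed),
- `positive` if p < 0.1 and RAD >= +0.2,
- `none` otherwise,
- `not_expressed` when the exome is covered but RNA depth is below the
  threshold (strict mode; the somatic analysis relaxes this to RNA depth
  exactly 0, matching the convention of shading unexpressed genes
  separately).

The 0.2 RAD cutoff guards against significant-but-tiny imbalances at high
depth; the somatic-only analysis drops it (direction from the sign of RAD
alone) and adds a presence test of the exome AF against 1: a one-sided
exact binomial test of the alternate count under an error null
`Binomial(depth, error_rate)`, with `error_rate = 0.01` and `alpha = 0.05`
as defaults — the error rate is an assumed Illumina-scale substitution
rate, not an estimate, and both are configurable.

No multiple-testing adjustment is applied by default (raw p < 0.1);
Benjamini-Hochberg FDR re-classification is available behind
`fdr_adjust=true`.

### Origin classification

With a matched normal exome covered at >= `min_reads` (symmetric with the
tumor coverage rule): zero alternate reads in the normal -> `somatic`, any
alternate read -> `germline`.  Simple absence is used rather than a formal
somatic test; at the default depths the misclassification probability is
dominated by binomial sampling of the somatic alternate fraction and is
below 1% (checked in the tests).  Without a usable normal, dbSNP
membership gives `likely_germline`, otherwise `unknown`.

### Aggregation, sharing, selection, patterns

*Gene aggregation*: a gene is significant for a patient if any of its
variants is at any site; both directions at once give `mixed`;
`not_expressed` only when every call is.

*Sharing*: per direction and per patient, the significant set is the union
over that patient's sites (gene level by default, variant level by
option).  The null preserves each patient's set size and tested universe:
per trial, draw `|S_p|` items without replacement from patient p's tested
pool, intersect, and count trials with shared >= observed; pseudo_p is
that fraction over 1000 trials (so pseudo_p = 1 whenever nothing is
observed shared, and its granularity is 1/n_trials).

*Selection*: per sample-site and RAD class, genes with >= `min_variants`
(2 by default, 4 for the stricter view) usable variants inside the class
contribute `n_nonsyn / n_syn`; stop-gained counts as non-synonymous,
splice/other enter neither count.  Genes with no synonymous variant yield
an infinite ratio kept as a sentinel ranked strictly last in the CDF —
dropping them would bias against exactly the most skewed genes.  This is a
raw count ratio, not a codon-model dN/dS: no correction for site counts or
mutational opportunity.

*Site patterns*: per (gene, patient), the pattern is the concatenation in
OV, PE, LN order of exactly the sites where some variant of the gene is
called negative (a co-occurring positive call at the same site does not
veto the site; missing sites count as non-negative — absence of evidence
is not negative RAD).  Patterns are assigned at gene level; the matrix
route below works at variant level.

*Clustering*: the RAD matrix has one row per significant variant and one
column per sample-site; cells hold RAD, the sentinel -2 for
expressed-nowhere calls (visibly outside [-1, 1]), and NaN where untested.
For distance computation only, NaN is imputed as 0 (no preferential
expression); agglomerative clustering uses Euclidean distance with average
linkage by default (both configurable), is deterministic with ties broken
by original index order, and dendrograms are exported as Newick.

## Synthetic cohorts

The generator emulates the data model the analysis assumes, with truth
labels for every planted property.

| parameter | default | meaning |
|---|---|---|
| `n_patients`, `sites_per_patient` | 3, (OV, PE, LN) | each patient also gets a normal (NO) exome |
| `n_genes`, `variants_per_gene` | 400, 3 | int or (lo, hi) uniform range |
| `het_fraction` / `somatic_fraction` | 0.95 / 0.05 | remainder (if any) is homozygous-alternate germline |
| `ase_fraction`, `ase_delta` | 0.05, 0.4 | planted |RNA-DNA| AF shift, clipped to [0, 1] |
| `cn_skew_sd` | 0.3 | sd of the logit-scale DNA-AF perturbation per (variant, tumor site) |
| `depth_mean_exome`, `depth_mean_rna` | 60, 60 | Poisson means; depth 0 occurs and exercises the no-expression path |
| `somatic_dna_alt_af` | 0.3 | cellularity-scaled somatic alternate fraction in tumor DNA |
| `nonsyn_prob_ase`, `nonsyn_prob_null` | 0.5, 0.5 | per-class probability a variant is protein-changing |

Construction, per (variant, patient, site):

- germline het: normal DNA AF fixed at 0.5; tumor DNA AF
  `expit(N(0, cn_skew_sd))` — the copy-number surrogate, drawn per site
  and **shared** between DNA and null RNA so the RAD subtraction must
  cancel it;
- somatic: absent from the normal (alt = 0), tumor DNA AF
  `expit(logit(0.7) + N(0, cn_skew_sd))`;
- ASE variants: RNA AF = site DNA AF +- `ase_delta` (clipped) in the
  variant's active sites, = DNA AF elsewhere.  Direction and active-site
  set are drawn **per gene** (uniform over the 7 non-empty OV/PE/LN
  subsets) and applied to all of the gene's planted variants, since
  cis-regulatory allele-specific expression is a gene-level phenomenon;
  the planted-variant count is exactly `round(ase_fraction * n_variants)`;
- read counts: `Binomial(Poisson(depth_mean), AF)` per assay.

Variants are cohort-level — the same germline set segregates in every
patient — which gives the sharing analysis non-trivial structure without a
population model of private variants.  Deliberately **not** emulated: raw
reads and alignment artifacts, mapping bias toward the reference allele,
RNA editing, overdispersion beyond binomial (no extra-Poisson depth
structure), linkage between nearby variants, and per-patient private
variant sets.  Passing tests therefore demonstrate the statistical
machinery under its own assumptions, not robustness to alignment bias or
library artifacts in real data.

With `ase_delta = 0` (or `ase_fraction = 0`) the cohort is an exact null
for type-I-error measurement.  With clipping, a planted shift near an AF
boundary delivers less than `ase_delta` of true effect; this attenuation
is part of the study conditions and bounds attainable sensitivity.

## Numerical and design choices

- Mid-P two-sidedness uses the "probability <= observed" enumeration rule;
  tie classification is exact-integer, so no tolerance parameter exists.
- `allele_fraction` raises at zero depth rather than returning NaN; the
  caller routes to `not_expressed`.
- The control-correction discordance (re-basing significance on the
  matched-normal exome) is computed over germline variants only — a
  somatic variant has no alternate allele in the normal, so its
  normal-based "RAD" measures variant presence, not expression.  The
  discordance fraction counts calls whose significance *or* direction
  changes, over the union of significant calls.  Near the 0.2 cutoff it is
  noise-dominated: the two exome baselines are independent binomial draws,
  so borderline calls flip either way regardless of skew; the skew-driven
  component dominates only once calls are depth-resolved (>= ~150x at
  these settings).
- Pipeline determinism: one seed governs all stochastic stages; every
  output TSV carries the seed in its header and reruns are bit-identical.
- Test and driver problem sizes (3 patients x 3 sites, 400-1000 genes x
  3-5 variants, depth 60, 100 replicate cohorts for the selection null,
  10^4 resampling trials) were chosen as the smallest scales at which the
  binomial/hypergeometric asymptotics stabilize the measured rates; the
  statistics themselves are scale-free.

## Known limitations

- Counts are taken as given; base/mapping quality filtering (>= Q20,
  deduplication) is assumed upstream, and reference-mapping bias is not
  corrected.
- No haplotype phasing: each variant is tested marginally, so multiple
  variants of one gene are not combined into a single allelic signal.
- The mid-P test assumes independent reads; UMI-less RNA duplicates or
  fragment-level correlation would overstate significance.
- The non-synonymous/synonymous ratio ignores mutational opportunity per
  gene; its CDFs are comparable across RAD classes only at matched
  per-record variant counts (the directional classes are the exchangeable
  pair under the no-selection null).
- `likely_germline` from dbSNP mislabels recurrent somatic variants
  present in dbSNP; with a covered normal the direct rule takes
  precedence.
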