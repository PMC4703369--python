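"""VCF/TSV parsing, the coverage+coding filter and origin classification."""

import textwrap

import pytest

from radpipe.records import AlleleCounts, SampleMeta, VariantRecord
from radpipe.variant_io import (
    VcfParseError,
    classify_origin,
    counts_to_frame,
    filter_variants,
    read_annotated_vcf,
    read_counts_table,
)

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">
    ##INFO=<ID=EFF,Number=.,Type=String,Description="Legacy annotations">
    ##INFO=<ID=COSMIC,Number=0,Type=Flag,Description="In COSMIC">
    ##contig=<ID=chr1>
    ##contig=<ID=chr17>
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
    """
)


def _write_vcf(tmp_path, body):
    path = tmp_path / "test.vcf"
    path.write_text(VCF_HEADER + textwrap.dedent(body))
    return path


def test_ann_missense_maps_to_nonsynonymous(tmp_path):
    path = _write_vcf(
        tmp_path,
        "chr17\t7577120\trs1042522\tG\tA\t.\tPASS\t"
        "ANN=A|missense_variant|MODERATE|TP53|TP53|transcript|t1|protein_coding\n",
    )
    (rec,) = read_annotated_vcf(path)
    assert rec.gene == "TP53"
    assert rec.effect == "nonsynonymous"
    assert rec.impact == "MODERATE"
    assert rec.in_dbsnp  # rs identifier


def test_highest_impact_annotation_wins(tmp_path):
    path = _write_vcf(
        tmp_path,
        "chr1\t100\t.\tC\tT\t.\tPASS\t"
        "ANN=T|intron_variant|MODIFIER|G1|G1|transcript|t1|protein_coding,"
        "T|stop_gained|HIGH|G1|G1|transcript|t2|protein_coding\n",
    )
    (rec,) = read_annotated_vcf(path)
    assert rec.impact == "HIGH"
    assert rec.effect == "stop_gained"


def test_multiallelic_records_split_per_alt(tmp_path):
    path = _write_vcf(
        tmp_path,
        "chr1\t200\t.\tA\tC,G\t.\tPASS\t"
        "ANN=C|missense_variant|MODERATE|G2|G2|transcript|t1|protein_coding,"
        "G|synonymous_variant|LOW|G2|G2|transcript|t1|protein_coding\n",
    )
    recs = read_annotated_vcf(path)
    assert {(r.alt_allele, r.effect) for r in recs} == {
        ("C", "nonsynonymous"),
        ("G", "synonymous"),
    }


def test_legacy_eff_entries_accepted(tmp_path):
    path = _write_vcf(
        tmp_path,
        "chr1\t300\t.\tG\tT\t.\tPASS\t"
        "EFF=missense_variant(MODERATE|MISSENSE|gaA/gaT|p.Glu12Asp|100|BRCA1|protein_coding|CODING|t1|1)\n",
    )
    (rec,) = read_annotated_vcf(path)
    assert rec.gene == "BRCA1"
    assert rec.effect == "nonsynonymous"


def test_missing_annotation_is_a_parse_error(tmp_path):
    path = _write_vcf(tmp_path, "chr1\t400\t.\tA\tG\t.\tPASS\tCOSMIC\n")
    with pytest.raises(VcfParseError, match="chr1:400"):
        read_annotated_vcf(path)


def test_splice_and_combined_terms(tmp_path):
    path = _write_vcf(
        tmp_path,
        "chr1\t500\t.\tA\tG\t.\tPASS\t"
        "ANN=G|splice_region_variant&synonymous_variant|LOW|G3|G3|transcript|t1|protein_coding\n",
    )
    (rec,) = read_annotated_vcf(path)
    assert rec.effect == "splice"


SAMPLES = [
    SampleMeta("P1_NO", "P1", "NO"),
    SampleMeta("P1_OV", "P1", "OV"),
    SampleMeta("P1_PE", "P1", "PE"),
]


class TestReadCountsTable:
    def _write(self, tmp_path, rows):
        path = tmp_path / "counts.tsv"
        header = "variant_id\tsample_id\tassay\tref_reads\talt_reads\n"
        path.write_text(header + "".join(rows))
        return path

    def test_well_formed_rows_parse(self, tmp_path):
        rows = [
            f"chr1:{100 + i}:A>G\tP1_OV\texome\t{10 + i}\t{i}\n" for i in range(5)
        ]
        path = self._write(tmp_path, rows)
        counts = read_counts_table(path, SAMPLES)
        assert len(counts) == 5
        assert counts[0] == AlleleCounts("chr1:100:A>G", "P1_OV", "exome", 10, 0)

    def test_unknown_assay_rejected_with_row_number(self, tmp_path):
        path = self._write(tmp_path, ["chr1:100:A>G\tP1_OV\twes\t10\t0\n"])
        with pytest.raises(ValueError, match="row 1.*wes"):
            read_counts_table(path, SAMPLES)

    def test_negative_counts_rejected(self, tmp_path):
        path = self._write(tmp_path, ["chr1:100:A>G\tP1_OV\texome\t-1\t0\n"])
        with pytest.raises(ValueError, match="row 1"):
            read_counts_table(path, SAMPLES)

    def test_unknown_sample_rejected(self, tmp_path):
        path = self._write(tmp_path, ["chr1:100:A>G\tP9_OV\texome\t1\t0\n"])
        with pytest.raises(ValueError, match="P9_OV"):
            read_counts_table(path, SAMPLES)


def _variant(vid_pos, effect="nonsynonymous", impact="MODERATE", dbsnp=False):
    return VariantRecord(
        "chr1", vid_pos, "A", "G", "G1", effect, impact, in_dbsnp=dbsnp
    )


def _counts(vid, sample, exome_depth, rna_depth):
    return [
        AlleleCounts(vid, sample, "exome", exome_depth // 2, exome_depth - exome_depth // 2),
        AlleleCounts(vid, sample, "rna", rna_depth // 2, rna_depth - rna_depth // 2),
    ]


class TestFilterVariants:
    def test_pairs_with_thin_rna_are_dropped(self):
        records = [_variant(100 + i) for i in range(10)]
        counts = []
        for i, r in enumerate(records):
            rna = 5 if i < 3 else 30
            counts += _counts(r.variant_id, "P1_OV", 30, rna)
        kept = filter_variants(records, counts, min_reads=8)
        assert len(kept) == 7

    def test_zero_thresholds_keep_everything(self):
        records = [_variant(100, effect="other", impact="MODIFIER"), _variant(101)]
        counts = _counts(records[0].variant_id, "P1_OV", 2, 2) + _counts(
            records[1].variant_id, "P1_OV", 2, 2
        )
        kept = filter_variants(records, counts, min_reads=0, coding_only=False)
        assert len(kept) == 2

    def test_noncoding_excluded_by_default(self):
        records = [_variant(100, effect="other", impact="MODIFIER"), _variant(101)]
        counts = _counts(records[0].variant_id, "P1_OV", 30, 30) + _counts(
            records[1].variant_id, "P1_OV", 30, 30
        )
        kept = filter_variants(records, counts)
        assert kept == {(records[1].variant_id, "P1_OV")}

    def test_monotone_in_min_reads(self, small_cohort):
        records = small_cohort.variants
        counts = small_cohort.counts
        at8 = filter_variants(records, counts, min_reads=8, samples=small_cohort.samples)
        at20 = filter_variants(records, counts, min_reads=20, samples=small_cohort.samples)
        assert at20 <= at8

    def test_normal_samples_never_form_pairs(self, small_cohort):
        kept = filter_variants(
            small_cohort.variants, small_cohort.counts,
            samples=small_cohort.samples, min_reads=0, coding_only=False,
        )
        assert all(not sid.endswith("_NO") for _, sid in kept)


class TestClassifyOrigin:
    def test_absent_from_covered_normal_is_somatic(self):
        v = _variant(100)
        nc = AlleleCounts(v.variant_id, "P1_NO", "exome", 30, 0)
        assert classify_origin(v, nc) == "somatic"

    def test_alt_in_normal_is_germline(self):
        v = _variant(100)
        nc = AlleleCounts(v.variant_id, "P1_NO", "exome", 20, 10)
        assert classify_origin(v, nc) == "germline"

    def test_dbsnp_without_normal_is_likely_germline(self):
        v = _variant(100, dbsnp=True)
        assert classify_origin(v, None) == "likely_germline"

    def test_thin_normal_and_no_dbsnp_is_unknown(self):
        v = _variant(100)
        nc = AlleleCounts(v.variant_id, "P1_NO", "exome", 3, 1)
        assert classify_origin(v, nc) == "unknown"

    def test_planted_origins_recovered_on_synthetic_cohort(self):
        from radpipe.synthetic_data import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(
            n_patients=1, n_genes=300, variants_per_gene=2,
            somatic_fraction=0.2, het_fraction=0.8, depth_mean_exome=50.0,
            seed=9,
        )
        cohort = simulate_cohort(cfg)
        truth = cohort.truth.set_index("variant_id")["origin"]
        normal = cohort.counts[
            (cohort.counts["sample_id"] == "P1_NO")
            & (cohort.counts["assay"] == "exome")
        ].set_index("variant_id")
        correct = total = 0
        for v in cohort.variants:
            row = normal.loc[v.variant_id]
            nc = AlleleCounts(
                v.variant_id, "P1_NO", "exome", int(row.ref_reads), int(row.alt_reads)
            )
            call = classify_origin(v, nc)
            if call in ("somatic", "germline"):
                total += 1
                correct += call == truth[v.variant_id]
        assert total > 500
        assert correct / total >= 0.99
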