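import numpy as np
import pytest

from dcm_phenolink.linkage import GenotypeTable, VariantRecord, filter_variants, shared_roh
from dcm_phenolink.linkage.varfilter import RULE_ORDER
from dcm_phenolink.synth.genedrop import planted_roh_panel


class TestSharedROH:
    def test_planted_run_detected_with_tight_boundaries(self):
        table = planted_roh_panel(run_start_cM=10.0, run_length_cM=10.0, spacing_cM=0.5, seed=3)
        segs = shared_roh(table, ["A1", "A2"], min_cM=4.0, unaffected_ids=["U1"])
        assert len(segs) == 1
        seg = segs[0]
        truth = table.meta["truth"]
        assert abs(seg.start_cM - truth["run_start_cM"]) <= 0.5  # one marker spacing
        assert abs(seg.end_cM - truth["run_end_cM"]) <= 0.5
        assert seg.unaffected_sharing == ()  # U1 heterozygous inside the run

    def test_short_run_rejected_at_four_centimorgan_threshold(self):
        table = planted_roh_panel(run_length_cM=3.0, seed=4)
        assert shared_roh(table, ["A1", "A2"], min_cM=4.0) == []

    def test_all_heterozygous_yields_no_segments(self):
        table = planted_roh_panel(run_length_cM=0.4, seed=5)  # below one spacing: effectively none
        markers = table.markers
        rng = np.random.default_rng(0)
        het = {}
        for iid in ("A1", "A2"):
            a = rng.integers(1, 4, size=(len(markers), 1))
            het[iid] = np.hstack([a, a + 1])
        table2 = GenotypeTable(markers=markers, genotypes=het)
        assert shared_roh(table2, ["A1", "A2"], min_cM=4.0) == []

    def test_unaffected_sharing_is_reported_as_exclusion_evidence(self):
        table = planted_roh_panel(run_length_cM=10.0, seed=6)
        # make U1 homozygous for the shared allele across the run
        in_run = (table.markers["cM"] >= 10.0) & (table.markers["cM"] <= 20.0)
        g = table.genotypes["U1"].copy()
        g[in_run.to_numpy()] = (1, 1)
        table.genotypes["U1"] = g
        segs = shared_roh(table, ["A1", "A2"], min_cM=4.0, unaffected_ids=["U1"])
        assert segs[0].unaffected_sharing == ("U1",)

    def test_different_homozygous_alleles_do_not_form_shared_run(self):
        table = planted_roh_panel(run_length_cM=10.0, seed=7)
        g = table.genotypes["A2"].copy()
        in_run = ((table.markers["cM"] >= 10.0) & (table.markers["cM"] <= 20.0)).to_numpy()
        g[in_run] = (2, 2)  # homozygous but for another allele
        table.genotypes["A2"] = g
        assert shared_roh(table, ["A1", "A2"], min_cM=4.0) == []
        relaxed = shared_roh(table, ["A1", "A2"], min_cM=4.0, require_same_allele=False)
        assert len(relaxed) == 1

    def test_unordered_map_rejected(self):
        table = planted_roh_panel(seed=8)
        table.markers.loc[5, "cM"] = 100.0
        with pytest.raises(ValueError, match="ordered"):
            shared_roh(table, ["A1", "A2"])

    def test_result_invariant_under_row_permutation_after_sorting(self):
        table = planted_roh_panel(seed=9)
        ref = shared_roh(table, ["A1", "A2"], min_cM=4.0)
        perm = np.random.default_rng(1).permutation(len(table.markers))
        markers = table.markers.iloc[perm].reset_index(drop=True)
        genotypes = {iid: g[perm] for iid, g in table.genotypes.items()}
        order = np.argsort(markers["cM"].to_numpy(), kind="stable")
        table2 = GenotypeTable(
            markers=markers.iloc[order].reset_index(drop=True),
            genotypes={iid: g[order] for iid, g in genotypes.items()},
        )
        segs = shared_roh(table2, ["A1", "A2"], min_cM=4.0)
        assert [(s.start_cM, s.end_cM) for s in segs] == [(s.start_cM, s.end_cM) for s in ref]


def published_candidates():
    """The four coding candidates in the mapped chr2 interval with their
    database annotations, as reported for the index family."""
    aff = ["III3", "III5", "III6"]
    base = {a: "1/1" for a in aff}
    return (
        [
            VariantRecord("chr2", 220037393, "a", "g", "C2orf24", {**base, "II4": "0/1"}, pop_af=0.99),
            VariantRecord("chr2", 220250147, "a", "g", "DNPEP", {**base, "II4": "0/1"}, pop_af=1.0),
            VariantRecord("chr2", 220343876, "g", "a", "SPEG", {**base, "II4": "0/1"}, pop_af=None, n_healthy_homozygotes=None),
            VariantRecord("chr2", 225721677, "c", "t", "DOCK10", {**base, "II4": "0/1"}, pop_af=0.0072, n_healthy_homozygotes=9),
        ],
        aff,
        ["II4"],
    )


class TestVariantFilter:
    def test_published_worked_example_leaves_only_speg(self):
        variants, aff, unaff = published_candidates()
        survivors, audit = filter_variants(variants, ("chr2", 218_317_008, 227_728_735), aff, unaff)
        assert [v.gene for v in survivors] == ["SPEG"]
        assert survivors[0].pos == 220343876
        failed = {a.variant.gene: a.failed_rule for a in audit if not a.passed}
        assert failed == {"C2orf24": "pop_af", "DNPEP": "pop_af", "DOCK10": "healthy_hom"}

    def test_empty_input_allowed(self):
        assert filter_variants([], ("1", 0, 10), ["A"]) == ([], [])

    def test_order_independent(self):
        variants, aff, unaff = published_candidates()
        interval = ("chr2", 218_317_008, 227_728_735)
        fwd, _ = filter_variants(variants, interval, aff, unaff)
        rev, _ = filter_variants(variants[::-1], interval, aff, unaff)
        assert {v.id for v in fwd} == {v.id for v in rev}

    def test_first_failing_rule_attribution(self):
        # fails both segregation and frequency rules: segregation is first
        v = VariantRecord("1", 5, "A", "T", "G", {"P1": "0/1", "U1": "1/1"}, pop_af=0.9)
        _, audit = filter_variants([v], ("1", 0, 10), ["P1"], ["U1"])
        assert audit[0].failed_rule == "hom_in_affected"
        assert RULE_ORDER.index("hom_in_affected") < RULE_ORDER.index("pop_af")

    def test_missing_annotations_pass_frequency_rules(self):
        v = VariantRecord("1", 5, "A", "T", "G", {"P1": "1/1"}, pop_af=None, n_healthy_homozygotes=None)
        survivors, _ = filter_variants([v], ("1", 0, 10), ["P1"])
        assert survivors == [v]

    def test_missing_affected_genotype_fails_segregation(self):
        v = VariantRecord("1", 5, "A", "T", "G", {"P1": "1/1"}, pop_af=None)
        _, audit = filter_variants([v], ("1", 0, 10), ["P1", "P2"])
        assert audit[0].failed_rule == "hom_in_affected"


class TestVariantIO:
    def test_tsv_round_trip(self, tmp_path):
        from dcm_phenolink.linkage.io import read_variants_tsv, write_variants_tsv

        variants, _, _ = published_candidates()
        path = tmp_path / "variants.tsv"
        write_variants_tsv(variants, path)
        back = read_variants_tsv(path)
        assert [v.id for v in back] == [v.id for v in variants]
        assert back[2].pop_af is None
        assert back[3].n_healthy_homozygotes == 9
        assert back[0].genotypes["III3"] == "1/1"

    def test_vcf_reading(self, tmp_path):
        pytest.importorskip("cyvcf2")
        from dcm_phenolink.linkage.io import read_variants_vcf

        vcf = tmp_path / "test.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=POPAF,Number=1,Type=Float,Description="population AF">\n'
            '##INFO=<ID=NHOM,Number=1,Type=Integer,Description="healthy homozygotes">\n'
            '##INFO=<ID=GENE,Number=1,Type=String,Description="gene">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "chr2\t100\t.\tG\tA\t.\t.\tPOPAF=0.0072;NHOM=9;GENE=DOCK10\tGT\t1/1\t0/1\n"
            "chr2\t200\t.\tC\tT\t.\t.\tGENE=SPEG\tGT\t1/1\t0/1\n"
        )
        records = read_variants_vcf(vcf)
        assert len(records) == 2
        assert records[0].pop_af == pytest.approx(0.0072)
        assert records[0].n_healthy_homozygotes == 9
        assert records[0].genotypes == {"S1": "1/1", "S2": "0/1"}
        assert records[1].pop_af is None
        assert records[1].gene == "SPEG"
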