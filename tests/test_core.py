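"""Ingestion, normalization and equivalence-key behavior."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionexome.core import (
    CallSet,
    Caller,
    NormalizationError,
    ParseReport,
    ReferenceGenome,
    TargetRegion,
    TargetSet,
    VarClass,
    VariantRecord,
    VcfParseError,
    classify_alleles,
    normalize_variant,
    read_pindel,
    read_vcf,
    variant_key,
    write_pindel,
    write_vcf,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
    "##contig=<ID=chr01,length=100000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
)


def _vcf(tmp_path, body, name="t.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestReadVcf:
    def test_snv_depth_mapping(self, tmp_path):
        p = _vcf(tmp_path, "chr01\t100\t.\tC\tA\t.\tPASS\t.\tGT:AD\t0/1:3,97\n")
        cs = read_vcf(p, "m1")
        (v,) = cs.records
        assert v.var_class is VarClass.SNV
        assert (v.alt_reads, v.ref_reads) == (97, 3)
        assert v.pos == 99  # converted to 0-based
        assert v.line_id == "m1" and v.caller is Caller.SNV_CALLER

    def test_deletion_size_from_length_difference(self, tmp_path):
        p = _vcf(tmp_path, "chr01\t100\t.\tATTG\tA\t.\tPASS\t.\tGT:AD\t0/1:2,60\n")
        (v,) = read_vcf(p, "m1").records
        assert v.var_class is VarClass.DEL and v.size_bp == 3
        assert (v.ref_allele, v.alt_allele) == ("ATTG", "A")  # verbatim before normalization

    def test_multiallelic_expansion(self, tmp_path):
        p = _vcf(tmp_path, "chr01\t100\t.\tC\tA,T\t.\tPASS\t.\tGT:AD\t1/2:0,40,45\n")
        recs = read_vcf(p, "m1").records
        assert len(recs) == 2
        assert all(r.n_alt_alleles == 2 for r in recs)
        assert {r.alt_allele for r in recs} == {"A", "T"}
        assert {r.alt_reads for r in recs} == {40, 45}

    def test_missing_depth_flagged_unknown(self, tmp_path):
        p = _vcf(tmp_path, "chr01\t100\t.\tC\tA\t.\tPASS\t.\tGT\t0/1\n")
        (v,) = read_vcf(p, "m1").records
        assert not v.depth_known

    def test_malformed_line_raises_named_error(self, tmp_path):
        p = _vcf(tmp_path, "chr01\tNOT_A_POS\t.\tC\tA\t.\tPASS\t.\tGT:AD\t0/1:3,97\n")
        with pytest.raises(VcfParseError):
            read_vcf(p, "m1")


class TestRoundTrip:
    def test_write_read_preserves_fields(self, tmp_path, small_cohort):
        _, genome, _, _, _, paths = small_cohort
        line_id = next(iter(paths))
        cs = read_vcf(paths[line_id]["vcf"], line_id)
        out = tmp_path / "rt.vcf"
        write_vcf(cs, out, reference=genome)
        back = read_vcf(out, line_id)
        assert len(back) == len(cs)
        for a, b in zip(cs, back):
            assert (a.chrom, a.pos, a.ref_allele, a.alt_allele) == (
                b.chrom,
                b.pos,
                b.ref_allele,
                b.alt_allele,
            )
            assert (a.alt_reads, a.ref_reads, a.n_alt_alleles) == (
                b.alt_reads,
                b.ref_reads,
                b.n_alt_alleles,
            )

    def test_pindel_round_trip(self, tmp_path):
        recs = [
            VariantRecord("m", Caller.SV_CALLER, "chr09", 999, "", "", VarClass.DEL, 212, 30, 0),
            VariantRecord("m", Caller.SV_CALLER, "chr01", 50, "", "ACGTACGTACGTACG", VarClass.INS, 15, 22, 0),
            VariantRecord("m", Caller.SV_CALLER, "chr02", 10, "", "", VarClass.TD, 40, 12, 0),
        ]
        p = tmp_path / "p.txt"
        write_pindel(CallSet("m", recs), p)
        back = read_pindel(p, "m")
        assert {(v.var_class, v.pos, v.size_bp) for v in back} == {
            (VarClass.DEL, 999, 212),
            (VarClass.INS, 50, 15),
            (VarClass.TD, 10, 40),
        }


class TestReadPindel:
    def test_event_mapping(self, tmp_path):
        p = tmp_path / "p.txt"
        p.write_text(
            "#type\tchrom\tstart\tend\tsize\tinserted\tsupports\n"
            "D\tchr09\t1001\t1212\t212\t.\t33\n"
            "I\tchr01\t500\t500\t15\tACGTACGTACGTACG\t20\n"
            "TD\tchr02\t100\t140\t41\t.\t11\n"
        )
        cs = read_pindel(p, "m1")
        by_class = {v.var_class: v for v in cs}
        assert by_class[VarClass.DEL].size_bp == 212
        assert by_class[VarClass.INS].size_bp == 15
        assert by_class[VarClass.INS].alt_allele == "ACGTACGTACGTACG"
        assert by_class[VarClass.TD].var_class is VarClass.TD
        assert by_class[VarClass.DEL].alt_reads == 33

    def test_unknown_code_skipped_and_counted(self, tmp_path):
        p = tmp_path / "p.txt"
        p.write_text("D\tchr01\t10\t12\t3\t.\t15\nXX\tchr01\t99\t99\t1\t.\t5\n")
        report = ParseReport()
        with pytest.warns(UserWarning, match="unknown event code"):
            cs = read_pindel(p, "m1", report)
        assert len(cs) == 1
        assert report.n_skipped == 1 and report.skipped_codes == {"XX": 1}


def _brute_force_left_shift(seq, pos, deleted):
    """Exhaustive oracle: leftmost equivalent placement of a deletion."""
    best = (pos, deleted)
    p, d = pos, deleted
    while p > 0 and seq[p - 1] == d[-1]:
        d = seq[p - 1] + d[:-1]
        p -= 1
        # equivalence check: removing d at p yields the same sequence
        assert seq[:p] + seq[p + len(d):] == seq[:best[0]] + seq[best[0] + len(best[1]):]
        best = (p, d)
    return best


class TestNormalize:
    def test_left_aligns_deletion_in_repeat_run(self):
        # context ...TCAAA...: deleting any single A is equivalent; the
        # normalized record must sit at the start of the A-run.
        seq = "GGTCAAAGG"
        ref = ReferenceGenome({"c": seq})
        run_start = 4  # first A (0-based)
        for vcf_style_pos in (3, 4, 5):  # anchored CA->C at different A's
            v = VariantRecord("m", Caller.SNV_CALLER, "c", vcf_style_pos,
                              seq[vcf_style_pos: vcf_style_pos + 2], seq[vcf_style_pos], VarClass.DEL, 1)
            n = normalize_variant(v, ref)
            exp_pos, exp_del = _brute_force_left_shift(seq, n.pos, n.ref_allele)
            assert (n.pos, n.ref_allele) == (exp_pos, exp_del)
            assert n.pos == run_start
            assert n.alt_allele == "" and n.size_bp == 1

    def test_snv_unchanged(self):
        v = VariantRecord("m", Caller.SNV_CALLER, "c", 5, "C", "A", VarClass.SNV, 0)
        n = normalize_variant(v)
        assert (n.pos, n.ref_allele, n.alt_allele) == (5, "C", "A")

    def test_prefix_suffix_trim_to_snv(self):
        v = VariantRecord("m", Caller.SNV_CALLER, "c", 10, "CAT", "CGT", VarClass.RPL, 1)
        n = normalize_variant(v)
        assert n.var_class is VarClass.SNV
        assert (n.pos, n.ref_allele, n.alt_allele) == (11, "A", "G")

    def test_idempotent(self, small_cohort):
        _, genome, _, _, _, paths = small_cohort
        line_id = next(iter(paths))
        cs = read_vcf(paths[line_id]["vcf"], line_id)
        for v in cs:
            once = normalize_variant(v, genome)
            twice = normalize_variant(once, genome)
            assert once == twice
            if v.var_class is VarClass.SNV:
                assert once.var_class is VarClass.SNV

    def test_reference_mismatch_raises(self):
        ref = ReferenceGenome({"c": "AAAA"})
        v = VariantRecord("m7", Caller.SNV_CALLER, "c", 1, "G", "T", VarClass.SNV, 0)
        with pytest.raises(NormalizationError, match="m7"):
            normalize_variant(v, ref)


class TestVariantKey:
    def test_caller_and_line_excluded(self):
        a = VariantRecord("m1", Caller.SNV_CALLER, "c", 9, "AT", "", VarClass.DEL, 2)
        b = VariantRecord("m2", Caller.SV_CALLER, "c", 9, "AT", "", VarClass.DEL, 2)
        assert variant_key(a) == variant_key(b)

    def test_different_alt_distinct(self):
        a = VariantRecord("m", Caller.SNV_CALLER, "c", 9, "A", "T", VarClass.SNV, 0)
        b = VariantRecord("m", Caller.SNV_CALLER, "c", 9, "A", "G", VarClass.SNV, 0)
        assert variant_key(a) != variant_key(b)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["c1", "c2"]),
                st.integers(0, 30),
                st.sampled_from(["A", "C", "AT", ""]),
                st.sampled_from(["G", "T", "", "GG"]),
            ),
            min_size=2,
            max_size=12,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_key_partition_matches_brute_force_equality(self, raw):
        recs = []
        for chrom, pos, ref, alt in raw:
            if ref == alt:
                continue
            vc, size = classify_alleles(ref or "N", alt or "N") if ref and alt else (
                (VarClass.DEL, len(ref)) if ref else (VarClass.INS, len(alt))
            )
            recs.append(VariantRecord("m", Caller.SNV_CALLER, chrom, pos, ref, alt, vc, size))
        for a, b in itertools.combinations(recs, 2):
            same_fields = (a.chrom, a.pos, a.ref_allele, a.alt_allele, a.var_class) == (
                b.chrom,
                b.pos,
                b.ref_allele,
                b.alt_allele,
                b.var_class,
            )
            assert same_fields == (variant_key(a) == variant_key(b))


class TestTargetSet:
    def test_merge_and_total_bases(self):
        # overlapping and bookended intervals collapse
        ts = TargetSet(
            TargetRegion("c1", s, e, f"r{i}")
            for i, (s, e) in enumerate([(0, 10), (5, 20), (20, 30), (40, 50)])
        )
        assert [(r.start, r.end) for r in ts.regions] == [(0, 30), (40, 50)]
        assert ts.total_bases == 40

    def test_bed_round_trip(self, tmp_path, small_cohort):
        _, _, _, targets, _, _ = small_cohort
        p = tmp_path / "t.bed"
        targets.to_bed(p)
        back = TargetSet.from_bed(p)
        assert [(r.chrom, r.start, r.end) for r in back] == [
            (r.chrom, r.start, r.end) for r in targets
        ]
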