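"""VCF/TSV reading, multi-allelic decomposition and key-join tests."""

import pytest

from conftest import VCF_BODY, het, make_variant
from varburden.cohort_io import (
    FormatError,
    VariantKey,
    join_annotations,
    read_annotation_table,
    read_case_vcf,
    read_control_table,
    read_variants_tsv,
    write_variants_tsv,
)


CONTROL_TSV = """CHROM\tPOS\tREF\tALT\tAC\tAN\tAF\tAF_nfe
17\t100\tC\tT\t466\t267908\t0.0017394030786687968\t0.002
17\t300\tCT\tC\t3\t267000\t1.1235955056179776e-05\t
"""

ANNOTATION_TSV = """CHROM\tPOS\tREF\tALT\tGENE\tCONSEQUENCE\tHGVSP\tCADD_PHRED\tREVEL\tACMG\tDDG\tDOMAIN
17\t100\tC\tT\tRPA1\tmissense_variant\tp.M46V\t22.2\t0.28\tVUS\t1.9\tF
17\t200\tG\tA\tRPA1\tmissense_variant\tp.X1Y\t30\t\t\t\t
17\t200\tG\tT\tRPA1\tmissense_variant\tp.X1Z\t30\t\t\t\t
17\t300\tCT\tC\tRPA1\tframeshift_variant\tp.L53Ifs*53\t\t\t\t\t
"""


class TestVariantKey:
    def test_invariants(self):
        with pytest.raises(ValueError):
            VariantKey("1", 0, "C", "T")
        with pytest.raises(ValueError):
            VariantKey("1", 5, "C", "C")
        with pytest.raises(ValueError):
            VariantKey("1", 5, "C", "T,A")

    def test_chr_prefix_strip(self):
        assert VariantKey("chr17", 5, "C", "T").strip_chr().chrom == "17"
        assert VariantKey("17", 5, "C", "T").strip_chr().chrom == "17"


class TestReadCaseVcf:
    def test_simple_site_field_mapping(self, small_vcf):
        sites = list(read_case_vcf(small_vcf))
        site = sites[0]
        assert site.key == VariantKey("17", 100, "C", "T")
        s1 = site.calls[0]
        assert (s1.gt_class, s1.ref_reads, s1.alt_reads, s1.gq) == ("het", 10, 10, 99)

    def test_missing_genotype_counts_in_call_rate(self, small_vcf):
        site = list(read_case_vcf(small_vcf))[0]
        assert site.calls[2].gt_class == "missing"
        assert site.call_rate == pytest.approx(3 / 4)

    def test_multiallelic_decomposition(self, small_vcf):
        sites = {s.key: s for s in read_case_vcf(small_vcf)}
        a = sites[VariantKey("17", 200, "G", "A")]
        t = sites[VariantKey("17", 200, "G", "T")]
        # GT=1/2 contributes one het to each decomposed record with per-allele AD
        assert a.calls[0].gt_class == "het" and a.calls[0].alt_reads == 8
        assert t.calls[0].gt_class == "het" and t.calls[0].alt_reads == 9
        assert a.calls[0].ref_reads == t.calls[0].ref_reads == 2

    def test_decomposition_conserves_alt_calls(self, small_vcf):
        sites = list(read_case_vcf(small_vcf))
        multi = [s for s in sites if s.key.pos == 200]
        n_alt_calls = sum(
            1 for s in multi for c in s.calls if c.gt_class in ("het", "hom_alt")
        )
        assert n_alt_calls == 3  # 1/2 sample counted once per allele + one 0/1

    def test_input_order_preserved(self, small_vcf):
        positions = [s.key.pos for s in read_case_vcf(small_vcf)]
        assert positions == sorted(positions) == [100, 200, 200, 300]

    def test_garbled_header_raises(self, tmp_path):
        bad = tmp_path / "bad.vcf"
        bad.write_text("this is not a vcf\n")
        with pytest.raises(FormatError):
            list(read_case_vcf(bad))

    def test_bad_ad_arity_skips_record(self, tmp_path, caplog):
        body = VCF_BODY.replace("0/1:10,10:99\t0/0:20,0:99", "0/1:10,10,3:99\t0/0:20,0:99")
        p = tmp_path / "arity.vcf"
        p.write_text(body)
        sites = list(read_case_vcf(p))
        assert VariantKey("17", 100, "C", "T") not in {s.key for s in sites}
        assert len([s for s in sites if s.key.pos == 200]) == 2


class TestReadControlTable:
    def test_roundtrip_values(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(CONTROL_TSV)
        table = read_control_table(p)
        rec = table[VariantKey("17", 100, "C", "T")]
        assert rec.ac == 466 and rec.an == 267908
        assert rec.af == pytest.approx(466 / 267908)
        assert rec.ancestry_afs == {"nfe": 0.002}

    def test_af_recomputed_when_absent(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("CHROM\tPOS\tREF\tALT\tAC\tAN\n1\t5\tA\tG\t0\t1000\n")
        rec = read_control_table(p)[VariantKey("1", 5, "A", "G")]
        assert rec.af == 0.0

    def test_duplicate_key_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(
            "CHROM\tPOS\tREF\tALT\tAC\tAN\n1\t5\tA\tG\t1\t100\n1\t5\tA\tG\t2\t100\n"
        )
        with pytest.raises(FormatError, match="duplicate"):
            read_control_table(p)

    def test_ac_above_an_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("CHROM\tPOS\tREF\tALT\tAC\tAN\n1\t5\tA\tG\t101\t100\n")
        with pytest.raises(FormatError, match="row 2"):
            read_control_table(p)

    def test_non_integer_counts_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("CHROM\tPOS\tREF\tALT\tAC\tAN\n1\t5\tA\tG\t1.5\t100\n")
        with pytest.raises(FormatError, match="non-integer"):
            read_control_table(p)


class TestJoin:
    def _inputs(self, tmp_path, small_vcf):
        cpath, apath = tmp_path / "c.tsv", tmp_path / "a.tsv"
        cpath.write_text(CONTROL_TSV)
        apath.write_text(ANNOTATION_TSV)
        return (
            list(read_case_vcf(small_vcf)),
            read_control_table(cpath),
            read_annotation_table(apath),
        )

    def test_full_join(self, tmp_path, small_vcf):
        sites, controls, anns = self._inputs(tmp_path, small_vcf)
        joined, stats = join_annotations(sites, controls, anns)
        by_key = {v.key: v for v in joined}
        v100 = by_key[VariantKey("17", 100, "C", "T")]
        assert v100.control.ac == 466 and v100.gene == "RPA1"
        assert [c.gt_class for c in v100.carriers] == ["het"]
        assert v100.missing_samples == frozenset({"S3"})

    def test_absent_from_controls_is_novel(self, tmp_path, small_vcf):
        sites, controls, anns = self._inputs(tmp_path, small_vcf)
        joined, stats = join_annotations(sites, controls, anns)
        v200 = next(v for v in joined if v.key == VariantKey("17", 200, "G", "A"))
        assert v200.control is None and v200.control_af == 0.0
        assert stats.n_absent_from_controls == 2

    def test_unannotated_dropped_and_counted(self, tmp_path, small_vcf):
        sites, controls, anns = self._inputs(tmp_path, small_vcf)
        del anns[VariantKey("17", 300, "CT", "C")]
        joined, stats = join_annotations(sites, controls, anns)
        assert stats.n_unannotated == 1
        assert VariantKey("17", 300, "CT", "C") not in {v.key for v in joined}

    def test_order_independent_result_set(self, tmp_path, small_vcf):
        sites, controls, anns = self._inputs(tmp_path, small_vcf)
        fwd, _ = join_annotations(sites, controls, anns)
        rev, _ = join_annotations(list(reversed(sites)), controls, anns)
        assert {v.key for v in fwd} == {v.key for v in rev}

    def test_zero_join_mismatch_heuristic(self):
        sites = [
            type("S", (), {"key": VariantKey("chr1", i + 1, "A", "G"), "calls": ()})()
            for i in range(150)
        ]
        with pytest.raises(FormatError, match="naming"):
            join_annotations(sites, {}, {})


class TestInterchangeRoundTrip:
    def test_roundtrip_identity(self, tmp_path):
        variants = [
            make_variant(pos=100, control_ac=466, carriers=[het("S1")], missing=["S3"]),
            make_variant(pos=200, ref="G", alt="A", control_ac=None,
                         carriers=[het("S1", 2, 8, 80), het("S2")], ddg=2.2),
        ]
        p = tmp_path / "interchange.tsv"
        write_variants_tsv(variants, p)
        back = read_variants_tsv(p)
        assert back == variants
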