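"""Collapsing, contingency construction and report-format tests."""

import pytest

from conftest import het, make_variant
from varburden.burden import (
    BurdenCell,
    CohortSubset,
    TierGroup,
    case_allele_counts,
    control_allele_counts,
    format_results_table,
    read_subsets_tsv,
    results_from_counts,
    run_burden,
)
from varburden.cohort_io import GenotypeCall


def subset(name, ids):
    return CohortSubset(name, frozenset(ids))


TEN = subset("Pan", [f"S{i}" for i in range(10)])


class TestCaseCounts:
    def test_hand_counted_hets(self):
        v = make_variant(control_ac=None, carriers=[het("S1"), het("S2")], n_samples=10)
        alt, total = case_allele_counts("RPA1", TEN, TierGroup.ULTRA_RARE_PLUS_NOVEL, [v])
        assert (alt, total) == (2, 20)

    def test_hom_alt_contributes_two_alleles(self):
        v = make_variant(
            control_ac=None,
            carriers=[het("S1"), GenotypeCall("S2", "hom_alt", 0, 30, 99)],
            n_samples=10,
        )
        alt, _ = case_allele_counts("RPA1", TEN, TierGroup.ULTRA_RARE_PLUS_NOVEL, [v])
        assert alt == 3

    def test_no_qualifying_variants_full_denominator(self):
        alt, total = case_allele_counts("RPA1", TEN, TierGroup.ULTRA_RARE_PLUS_NOVEL, [])
        assert (alt, total) == (0, 20)

    def test_missing_samples_shrink_site_mean_denominator(self):
        v = make_variant(control_ac=None, carriers=[het("S1")],
                         missing=["S2", "S3"], n_samples=10)
        _, total = case_allele_counts("RPA1", TEN, TierGroup.ULTRA_RARE_PLUS_NOVEL, [v])
        assert total == 16  # 2 * (10 - 2)

    def test_2n_policy(self):
        v = make_variant(control_ac=None, carriers=[het("S1")], missing=["S2"], n_samples=10)
        _, total = case_allele_counts(
            "RPA1", TEN, TierGroup.ULTRA_RARE_PLUS_NOVEL, [v], an_policy="2n"
        )
        assert total == 20

    def test_subset_restriction(self):
        v = make_variant(control_ac=None, carriers=[het("S1"), het("S9")], n_samples=10)
        half = subset("HEM", ["S0", "S1", "S2", "S3", "S4"])
        alt, _ = case_allele_counts("RPA1", half, TierGroup.ULTRA_RARE_PLUS_NOVEL, [v])
        assert alt == 1

    def test_mutually_exclusive_hets_equal_carrier_cases(self):
        # one qualifying het per carrier: collapsed alt count == carrier count
        variants = [
            make_variant(pos=100 + i, control_ac=None, carriers=[het(f"S{i}")], n_samples=10)
            for i in range(5)
        ]
        alt, _ = case_allele_counts("RPA1", TEN, TierGroup.ULTRA_RARE_PLUS_NOVEL, variants)
        assert alt == 5

    def test_disjoint_subset_additivity(self):
        variants = [
            make_variant(pos=100 + i, control_ac=None, carriers=[het(f"S{i}")], n_samples=10)
            for i in range(6)
        ]
        left = subset("L", [f"S{i}" for i in range(3)])
        right = subset("R", [f"S{i}" for i in range(3, 10)])
        union = subset("U", [f"S{i}" for i in range(10)])
        g = TierGroup.ULTRA_RARE_PLUS_NOVEL
        a_l, _ = case_allele_counts("RPA1", left, g, variants)
        a_r, _ = case_allele_counts("RPA1", right, g, variants)
        a_u, _ = case_allele_counts("RPA1", union, g, variants)
        assert a_l + a_r == a_u


class TestControlCounts:
    def test_hand_summed_ac(self):
        variants = [
            make_variant(pos=100 + i, control_ac=ac, control_an=100000)
            for i, ac in enumerate([1, 2, 0])
        ]
        control_map = {v.key: v.control for v in variants}
        ann_map = {v.key: v.annotation for v in variants}
        alt, total = control_allele_counts(
            "RPA1", TierGroup.RARE_UNDER_0_1, control_map, ann_map
        )
        assert (alt, total) == (3, 100000)

    def test_counts_include_variants_unseen_in_cases(self):
        # the control footprint is filter-defined, not case-defined
        variants = [make_variant(pos=p, control_ac=5, control_an=100000) for p in (1, 2)]
        control_map = {v.key: v.control for v in variants}
        ann_map = {v.key: v.annotation for v in variants}
        alt, _ = control_allele_counts(
            "RPA1", TierGroup.RARE_UNDER_0_1, control_map, ann_map
        )
        assert alt == 10

    def test_empty_footprint_errors(self):
        with pytest.raises(ValueError, match="footprint"):
            control_allele_counts("RPA9", TierGroup.RARE_UNDER_0_1, {}, {})

    def test_zero_qualifying_uses_footprint_an(self):
        v = make_variant(pos=1, control_ac=900, control_an=1000)  # AF 0.9: excluded
        alt, total = control_allele_counts(
            "RPA1", TierGroup.RARE_UNDER_0_1, {v.key: v.control}, {v.key: v.annotation}
        )
        assert (alt, total) == (0, 1000)


class TestRunBurden:
    def _toy(self):
        variants = [
            make_variant(pos=100, control_ac=None, carriers=[het("S1")], n_samples=10),
            make_variant(pos=101, control_ac=30, control_an=100000,  # AF 3e-4: very rare
                         carriers=[het("S2"), het("S3")], n_samples=10),
        ]
        control_map = {v.key: v.control for v in variants if v.control}
        ann_map = {v.key: v.annotation for v in variants}
        return variants, control_map, ann_map

    def test_tier_nesting_alt_counts(self):
        variants, control_map, ann_map = self._toy()
        results = run_burden(variants, [TEN], control_map, ann_map)
        by_group = {r.cell.tier_group: r.cell for r in results}
        ultra = by_group[TierGroup.ULTRA_RARE_PLUS_NOVEL]
        rare = by_group[TierGroup.RARE_UNDER_0_1]
        assert ultra.case_alt == 1  # only the novel site
        assert rare.case_alt == 3 and rare.case_alt >= ultra.case_alt

    def test_deterministic_and_order_independent(self):
        variants, control_map, ann_map = self._toy()
        a = run_burden(variants, [TEN], control_map, ann_map)
        b = run_burden(list(reversed(variants)), [TEN], control_map, ann_map)
        assert a == b

    def test_family_adjustment_identity_for_single_cell(self):
        results = results_from_counts(
            [("G1", "Pan", "ULTRA_RARE_PLUS_NOVEL", 2, 100, 5, 1000)]
        )
        r = results[0]
        assert r.adj_greater == pytest.approx(r.test.p_greater)

    def test_published_counts_reproduce_printed_row(self):
        results = results_from_counts(
            [("RPA1", "PanCancer_UltraRare", "ULTRA_RARE_PLUS_NOVEL", 35, 11951, 466, 267908),
             ("RPA1", "HEM_UltraRare", "ULTRA_RARE_PLUS_NOVEL", 15, 6889, 466, 267908),
             ("RPA1", "ST_UltraRare", "ULTRA_RARE_PLUS_NOVEL", 13, 3935, 466, 267908),
             ("RPA1", "CNS_UltraRare", "ULTRA_RARE_PLUS_NOVEL", 7, 2129, 466, 267908)],
            family_size=8,
        )
        top = results[0]
        assert top.test.p_greater == pytest.approx(0.00350858, rel=1e-6)
        assert top.test.or_cmle == pytest.approx(1.6837, abs=5e-5)
        assert top.adj_greater == pytest.approx(0.028068639, rel=1e-6)

    def test_invalid_cell_rejected(self):
        with pytest.raises(ValueError):
            BurdenCell("G", "S", TierGroup.RARE_UNDER_0_1, 5, 4, 0, 10)


class TestReport:
    def test_formatted_columns_and_af_rounding(self):
        results = results_from_counts(
            [("RPA1", "PanCancer_UltraRare", "ULTRA_RARE_PLUS_NOVEL", 35, 11951, 466, 267908)],
            family_size=8,
        )
        df = format_results_table(results)
        row = df.iloc[0]
        assert row["Cancer_AF"] == "0.0029" and row["Control_AF"] == "0.0017"
        assert float(row["p_greater"]) == pytest.approx(0.00350858, rel=1e-6)

    def test_empty_gene_prints_p_one(self):
        df = format_results_table(
            results_from_counts([("G1", "Pan", "RARE_UNDER_0_1", 0, 100, 0, 1000)])
        )
        assert float(df.iloc[0]["p_greater"]) == 1.0

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            format_results_table([])


def test_read_subsets_tsv(tmp_path):
    p = tmp_path / "subsets.tsv"
    p.write_text("sample_id\tHEM\tST\nS1\t1\t0\nS2\t0\t1\nS3\t1\t0\n")
    subsets = read_subsets_tsv(p)
    names = {s.name: s for s in subsets}
    assert names["PanCancer"].sample_ids == frozenset({"S1", "S2", "S3"})
    assert names["HEM"].sample_ids == frozenset({"S1", "S3"})
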