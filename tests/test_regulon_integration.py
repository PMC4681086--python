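"""Peak context, operon inference, regulation assignment, and summaries."""

import numpy as np
import pytest

from regulonseq.differential_expression import DEGRecord
from regulonseq.genome_model import Gene, GenomeAnnotation, Interval
from regulonseq.peak_calling import Peak
from regulonseq.regulon_integration import (assign_regulation,
                                            classify_peaks, infer_operons,
                                            load_table1, summarize_regulon,
                                            summit_to_start_distance,
                                            venn_counts)


def peak_at(summit, half=100, pid="p1"):
    return Peak(Interval(summit - half, summit + half), summit, 50.0,
                peak_id=pid)


class TestSummitDistance:
    def test_plus_gene_upstream_negative(self):
        # summit 90 bp before a + start codon, as for the pleC-type row
        g = Gene("g", 1000, 2000, "+")
        assert summit_to_start_distance(peak_at(909), g) == -90

    def test_minus_gene_inside_positive(self):
        # summit 36 bp past a - start codon, the exoP-type +36 case
        g = Gene("g", 1000, 2000, "-")
        assert summit_to_start_distance(peak_at(1963), g) == 36

    def test_summit_on_start_codon_zero(self):
        gp = Gene("gp", 1000, 2000, "+")
        gm = Gene("gm", 1000, 2000, "-")
        assert summit_to_start_distance(peak_at(999), gp) == 0
        assert summit_to_start_distance(peak_at(1999), gm) == 0


class TestClassifyPeaks:
    def annotation(self):
        return GenomeAnnotation(20_000, [
            Gene("left", 1000, 3000, "-"),
            Gene("right", 3500, 5000, "+"),
            Gene("big", 6000, 12_000, "+"),
            Gene("after", 12_300, 13_000, "+"),
            Gene("rrna", 15_000, 16_000, "+", kind="rRNA"),
        ])

    def test_divergent_pair_two_candidates(self):
        ctx = classify_peaks([peak_at(3200)], self.annotation())[0]
        assert ctx.category == "intergenic_divergent"
        assert {g.locus_id for g, _ in ctx.candidate_genes} \
            == {"left", "right"}
        assert {g.strand for g, _ in ctx.candidate_genes} == {"+", "-"}

    def test_upstream_of_single_gene(self):
        ann = GenomeAnnotation(20_000, [Gene("a", 5000, 8000, "+")])
        ctx = classify_peaks([peak_at(4500)], ann)[0]
        assert ctx.category == "intergenic_upstream"
        assert ctx.candidate_genes[0][1] == pytest.approx(-499)

    def test_mid_gene_far_from_next_start_is_intragenic(self):
        ctx = classify_peaks([peak_at(8000)], self.annotation())[0]
        assert ctx.category == "intragenic"
        assert ctx.candidate_genes == []

    def test_intragenic_upstream_of_downstream_gene(self):
        ctx = classify_peaks([peak_at(11_500)], self.annotation())[0]
        assert ctx.category == "intragenic_upstream"
        assert ctx.candidate_genes[0][0].locus_id == "after"

    def test_rna_locus_wins(self):
        ctx = classify_peaks([peak_at(15_500)], self.annotation())[0]
        assert ctx.category == "rna_locus"

    def test_categories_partition_peaks(self):
        rng = np.random.default_rng(5)
        peaks = [peak_at(int(s)) for s in rng.integers(300, 19_500, 40)]
        ctxs = classify_peaks(peaks, self.annotation())
        assert len(ctxs) == len(peaks)
        from collections import Counter
        counts = Counter(c.category for c in ctxs)
        assert sum(counts.values()) == len(peaks)


class TestInferOperons:
    def ann(self, gap, strands=("+", "+")):
        g1 = Gene("a", 1000, 2000, strands[0])
        g2 = Gene("b", 2001 + gap, 3500 + gap, strands[1])
        return GenomeAnnotation(10_000, [g1, g2])

    def test_small_gap_equal_expression_one_operon(self):
        ops = infer_operons(self.ann(30), {"a": 100.0, "b": 100.0})
        assert ops == [["a", "b"]]

    def test_gap_at_60bp_breaks_operon(self):
        assert infer_operons(self.ann(60), {"a": 100.0, "b": 100.0}) == []

    def test_gap_boundary_exactly_50_breaks(self):
        assert infer_operons(self.ann(50), {"a": 100.0, "b": 100.0}) == []
        assert infer_operons(self.ann(49), {"a": 100.0, "b": 100.0}) \
            == [["a", "b"]]

    def test_opposite_strands_never_operon(self):
        ops = infer_operons(self.ann(30, ("+", "-")), {"a": 1.0, "b": 1.0})
        assert ops == []

    def test_dissimilar_expression_breaks_operon(self):
        assert infer_operons(self.ann(30), {"a": 100.0, "b": 500.0}) == []
        assert infer_operons(self.ann(30), {"a": 100.0, "b": 150.0}) \
            == [["a", "b"]]

    def test_minus_strand_transcription_order(self):
        ops = infer_operons(self.ann(30, ("-", "-")),
                            {"a": 50.0, "b": 50.0})
        assert ops == [["b", "a"]]

    def test_recovers_generated_operons(self, default_dataset):
        ann, truth, *_ = default_dataset
        expr = truth.expression
        got = infer_operons(ann, expr)
        assert sorted(map(tuple, got)) == sorted(map(tuple, truth.operons))


class TestAssignRegulation:
    def fixture(self):
        ann = GenomeAnnotation(30_000, [
            Gene("gm", 2000, 4000, "-"),            # divergent pair left
            Gene("gp", 4500, 6000, "+"),            # divergent pair right
            Gene("op1", 10_000, 11_000, "+"),       # operon first
            Gene("op2", 11_020, 12_000, "+"),       # operon follower
            Gene("far", 20_000, 21_000, "+"),       # no peak anywhere near
        ])
        degs = [DEGRecord(x, -2.0, 1e-6, 1e-5, "activated")
                for x in ("gm", "gp", "op1", "op2", "far")]
        operons = [["op1", "op2"]]
        return ann, degs, operons

    def test_no_peaks_every_deg_indirect(self):
        ann, degs, operons = self.fixture()
        records = assign_regulation([], degs, operons, ann=ann)
        assert all(r.regulation == "indirect" for r in records)

    def test_divergent_peak_two_direct_records(self):
        ann, degs, operons = self.fixture()
        ctxs = classify_peaks([peak_at(4200, pid="pk1")], ann)
        assert ctxs[0].category == "intergenic_divergent"
        records = assign_regulation(ctxs, degs, operons, ann=ann)
        direct = {r.locus_id: r for r in records if r.regulation == "direct"}
        assert set(direct) == {"gm", "gp"}
        assert direct["gm"].peak_id == direct["gp"].peak_id == "pk1"

    def test_operon_expansion(self):
        ann, degs, operons = self.fixture()
        ctxs = classify_peaks([peak_at(9800, pid="pk2")], ann)
        records = assign_regulation(ctxs, degs, operons, ann=ann)
        by = {r.locus_id: r for r in records}
        assert by["op1"].regulation == "direct"
        assert by["op1"].operon_role == "first_in_operon"
        assert by["op2"].regulation == "direct_via_operon"
        assert by["op2"].operon_role == "in_operon"
        assert by["far"].regulation == "indirect"

    def test_regulation_partitions_degs(self):
        ann, degs, operons = self.fixture()
        ctxs = classify_peaks([peak_at(4200), peak_at(9800)], ann)
        records = assign_regulation(ctxs, degs, operons, ann=ann)
        assert len(records) == len(degs)
        kinds = [r.regulation for r in records]
        assert all(k in ("direct", "direct_via_operon", "indirect")
                   for k in kinds)

    def test_window_shrink_monotone(self):
        ann, degs, operons = self.fixture()
        peaks = [peak_at(4200), peak_at(9800)]
        n_direct = []
        for win in [(-1000, 50), (-500, 50), (-200, 10)]:
            ctxs = classify_peaks(peaks, ann, win)
            records = assign_regulation(ctxs, degs, operons, win, ann)
            n_direct.append(sum(r.regulation != "indirect" for r in records))
        assert n_direct == sorted(n_direct, reverse=True)

    def test_unknown_deg_locus_raises(self):
        ann, degs, operons = self.fixture()
        degs.append(DEGRecord("ghost", -2.0, 1e-6, 1e-5, "activated"))
        with pytest.raises(ValueError, match="ghost"):
            assign_regulation([], degs, operons, ann=ann)

    def test_synthetic_truth_recovery(self, default_dataset, consensus,
                                      default_count_matrix):
        """Direct targets recovered; site-free indirects never direct."""
        from regulonseq.differential_expression import rpkm, run_deg_analysis
        ann, truth, *_ = default_dataset
        _, _, peaks = consensus
        cm = default_count_matrix
        degs = run_deg_analysis(cm)
        expr = rpkm(cm)[cm.samples("wt")].mean(axis=1).to_dict()
        operons = infer_operons(ann, expr)
        ctxs = classify_peaks(peaks, ann)
        records = assign_regulation(ctxs, degs, operons, ann=ann)
        got_direct = {r.locus_id for r in records
                      if r.regulation in ("direct", "direct_via_operon")}
        td = set(truth.direct_targets)
        assert len(got_direct & td) >= 0.9 * len(td)
        direct_only = {r.locus_id for r in records
                       if r.regulation == "direct"}
        assert not direct_only & set(truth.indirect_targets)


class TestSummaries:
    def test_all_intergenic_binomial_closed_form(self):
        ann = GenomeAnnotation(10_000, [Gene("a", 1, 5000, "+")])
        peaks = [peak_at(6000 + 150 * i, half=50, pid=f"p{i}")
                 for i in range(20)]
        ctxs = classify_peaks(peaks, ann)
        summary = summarize_regulon([], ctxs, ann)
        assert summary["intergenic_peak_fraction"] == 1.0
        assert summary["intergenic_enrichment_p"] == pytest.approx(
            0.5 ** 20, rel=1e-9)

    def test_identical_heights_utest_p_near_one(self):
        ann = GenomeAnnotation(10_000, [Gene("a", 4001, 6000, "+")])
        inter = [peak_at(1000 + 200 * i, half=50) for i in range(5)]
        intra = [peak_at(4500 + 200 * i, half=50) for i in range(5)]
        ctxs = classify_peaks(inter + intra, ann)
        summary = summarize_regulon([], ctxs, ann)
        assert summary["height_mannwhitney_p"] > 0.9


class TestVenn:
    def test_disjoint_sets_only_singletons(self):
        v = venn_counts({"a"}, {"b"}, {"c", "d"})
        assert (v["a_only"], v["b_only"], v["c_only"]) == (1, 1, 2)
        assert v["ab_only"] == v["ac_only"] == v["bc_only"] == v["abc"] == 0

    def test_identical_sets_only_triple(self):
        v = venn_counts({"x", "y"}, {"x", "y"}, {"x", "y"})
        assert v["abc"] == 2
        assert sum(v.values()) == 2

    def test_random_sets_match_membership_enumeration(self):
        rng = np.random.default_rng(7)
        universe = [f"g{i}" for i in range(60)]
        a = {g for g in universe if rng.random() < 0.4}
        b = {g for g in universe if rng.random() < 0.4}
        c = {g for g in universe if rng.random() < 0.4}
        v = venn_counts(a, b, c)
        oracle = {"a_only": 0, "b_only": 0, "c_only": 0, "ab_only": 0,
                  "ac_only": 0, "bc_only": 0, "abc": 0}
        for g in universe:
            key = (g in a, g in b, g in c)
            name = {(1, 0, 0): "a_only", (0, 1, 0): "b_only",
                    (0, 0, 1): "c_only", (1, 1, 0): "ab_only",
                    (1, 0, 1): "ac_only", (0, 1, 1): "bc_only",
                    (1, 1, 1): "abc"}.get(tuple(map(int, key)))
            if name:
                oracle[name] += 1
        assert v == oracle


class TestReferenceTable:
    def test_every_row_passes_deg_threshold(self):
        df = load_table1()
        assert (df["log2fc"].abs() >= 1.32).all()

    def test_unique_loci_and_roles(self):
        df = load_table1()
        assert df["locus_id"].nunique() == 45
        assert set(df["role"]) <= {"single", "first_in_operon", "in_operon"}
        assert set(df["strand"]) == {"+", "-"}
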