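import numpy as np
import pytest
from scipy import stats

from soxcomp.conservation import (annotate_features, annotate_nearest_gene,
                                  category_distribution,
                                  classify_conservation,
                                  common_unique_analysis,
                                  conservation_by_category, detect_turnover,
                                  intron_rank_enrichment,
                                  map_targets_via_orthologs, overlaps_any,
                                  pearson_chi2, ConservationRecord)
from soxcomp.io_core import GeneModel, GenomicInterval


def iv(s, e, chrom="c"):
    return GenomicInterval(chrom, s, e)


class TestOverlapsAny:
    def test_half_open_boundaries(self):
        assert overlaps_any([iv(10, 20)], [iv(19, 30)]).tolist() == [True]
        assert overlaps_any([iv(10, 20)], [iv(20, 30)]).tolist() == [False]

    def test_min_overlap_threshold(self):
        assert overlaps_any([iv(10, 20)], [iv(15, 30)],
                            min_overlap=5).tolist() == [True]
        assert overlaps_any([iv(10, 20)], [iv(16, 30)],
                            min_overlap=5).tolist() == [False]

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            def random_set(n):
                out = []
                for _ in range(n):
                    s = int(rng.integers(0, 500))
                    out.append(iv(s, s + int(rng.integers(1, 40)),
                                  chrom=str(rng.integers(0, 2))))
                return out
            q, s = random_set(100), random_set(100)
            fast = overlaps_any(q, s)
            brute = [any(a.overlaps(b) for b in s) for a in q]
            assert fast.tolist() == brute


class TestClassifyConservation:
    def test_three_way_and_unique(self):
        sets = {
            "mel": [iv(100, 200), iv(500, 600)],
            "sim": [iv(150, 250)],
            "yak": [iv(120, 180)],
        }
        records = classify_conservation(sets)
        cats = {(r.interval.start, r.interval.end): r.category
                for r in records}
        assert cats[(100, 250)] == 3
        assert cats[(500, 600)] == 1

    def test_union_deduplication(self):
        sets = {sp: [iv(10, 50)] for sp in ("a", "b", "c")}
        records = classify_conservation(sets)
        assert len(records) == 1 and records[0].category == 3
        assert category_distribution(records) == {3: 1.0}

    def test_distribution_sums_to_one(self, rng):
        sets = {}
        for sp in ("a", "b", "c"):
            starts = rng.integers(0, 5000, size=30)
            sets[sp] = [iv(int(s), int(s) + 50) for s in starts]
        dist = category_distribution(classify_conservation(sets))
        assert np.isclose(sum(dist.values()), 1.0)

    def test_mismatched_chromosomes_warn(self):
        sets = {"a": [iv(0, 10, chrom="x")], "b": [iv(0, 10, chrom="y")]}
        with pytest.warns(UserWarning):
            records = classify_conservation(sets)
        assert all(r.category == 1 for r in records)


@pytest.fixture()
def genes():
    return [
        GeneModel("gA", "c", "+", 1000, 2000, ((1000, 1200), (1800, 2000))),
        GeneModel("gB", "c", "-", 3000, 4500,
                  ((3000, 3200), (3600, 3800), (4300, 4500))),
    ]


class TestGeneAnnotation:
    def test_overlapping_interval_distance_zero(self, genes):
        ann = annotate_nearest_gene([iv(1500, 1600)], genes)[0]
        assert ann.gene_id == "gA" and ann.distance == 0

    def test_equidistant_tie_lexicographic(self, genes):
        # midpoint gap between gA end (2000) and gB start (3000)
        ann = annotate_nearest_gene([iv(2490, 2510)], genes)[0]
        assert ann.gene_id == "gA" and ann.tie

    def test_gene_free_chromosome_flagged(self, genes):
        ann = annotate_nearest_gene([iv(0, 10, chrom="z")], genes)[0]
        assert ann.gene_id is None and ann.feature == "unannotated"

    def test_feature_classes(self, genes):
        # gA promoter window is [-1000, 1500), so the intron/exon probes
        # sit beyond it
        anns = annotate_features(
            [iv(1600, 1700),       # first intron of gA, past the promoter
             iv(900, 950),         # 100 bp upstream of gA TSS
             iv(9000, 9100),       # far from everything
             iv(1850, 1900)],      # inside gA exon 2
            genes)
        assert anns[0].feature == "intron" and anns[0].intron_rank == 1
        assert anns[1].feature == "promoter"
        assert anns[2].feature == "intergenic"
        assert anns[3].feature == "exon"

    def test_minus_strand_intron_ranks(self, genes):
        # gB introns: [3200,3600) rank 2, [3800,4300) rank 1
        anns = annotate_features([iv(3900, 4000), iv(3300, 3400)], genes)
        assert anns[0].intron_rank == 1
        assert anns[1].intron_rank == 2

    def test_minus_strand_promoter_upstream(self, genes):
        # gB TSS at 4499; upstream means larger coordinates
        ann = annotate_features([iv(4600, 4700)], genes)[0]
        assert ann.feature == "promoter"


class TestIntronRankEnrichment:
    def _genes_equal_lengths(self):
        # rank-1 and rank-2 introns of identical genomic length (500 bp each)
        return [GeneModel("g", "c", "+", 0, 2500,
                          ((0, 500), (1000, 1500), (2000, 2500)))]

    def _ann(self, ranks):
        anns = annotate_features([iv(0, 10)] * len(ranks),
                                 self._genes_equal_lengths())
        for a, r in zip(anns, ranks):
            a.feature = "intron"
            a.intron_rank = r
        return anns

    def test_all_rank_one_chi2(self):
        res = intron_rank_enrichment(self._ann([1] * 50),
                                     self._genes_equal_lengths())
        assert np.isclose(res.chi2, 50.0)
        assert res.pvalue < 1e-10

    def test_proportional_hits_null(self):
        res = intron_rank_enrichment(self._ann([1] * 25 + [2] * 25),
                                     self._genes_equal_lengths())
        assert res.chi2 < 1.0 and res.pvalue > 0.3

    def test_single_hit_uses_binomial(self):
        res = intron_rank_enrichment(self._ann([1]),
                                     self._genes_equal_lengths())
        assert res.warning == "small-sample binomial path"
        assert 0 < res.pvalue <= 1

    def test_no_intronic_intervals_untestable(self):
        anns = annotate_features([iv(9000, 9010)],
                                 self._genes_equal_lengths())
        with pytest.raises(ValueError):
            intron_rank_enrichment(anns, self._genes_equal_lengths())


class TestTurnover:
    def _annotated(self, genes, intervals):
        return annotate_nearest_gene(intervals, genes)

    def test_non_overlapping_same_gene_is_turnover(self, genes):
        a = self._annotated(genes, [iv(1100, 1200)])
        b = self._annotated(genes, [iv(1500, 1600)])
        events = detect_turnover(a, b)
        assert [e.gene_id for e in events] == ["gA"]

    def test_overlap_cancels_event(self, genes):
        a = self._annotated(genes, [iv(1100, 1200)])
        b = self._annotated(genes, [iv(1150, 1250)])
        assert detect_turnover(a, b) == []

    def test_any_overlap_suffices(self, genes):
        a = self._annotated(genes, [iv(1100, 1200), iv(1500, 1600)])
        b = self._annotated(genes, [iv(1150, 1250)])
        assert detect_turnover(a, b) == []

    def test_gene_needs_intervals_in_both(self, genes):
        a = self._annotated(genes, [iv(1100, 1200)])
        b = self._annotated(genes, [iv(3500, 3550)])  # gB only
        assert detect_turnover(a, b) == []


class TestChi2:
    def test_hand_computed_example(self):
        res = pearson_chi2(np.array([[15, 5], [30, 50]]))
        assert abs(res.chi2 - 9.09) < 0.01 and res.dof == 1

    def test_independence_gives_zero(self):
        res = pearson_chi2(np.array([[10, 10], [10, 10]]))
        assert res.chi2 == 0 and np.isclose(res.pvalue, 1.0)

    def test_degrees_of_freedom(self):
        res = pearson_chi2(np.arange(8).reshape(2, 4) + 5.0)
        assert res.dof == 3

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2(np.array([[0, 0], [3, 4]]))

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(1000):
            shape = (int(rng.integers(2, 4)), int(rng.integers(2, 5)))
            table = rng.integers(1, 60, size=shape).astype(float)
            ours = pearson_chi2(table)
            ref = stats.chi2_contingency(table, correction=False)
            assert abs(ours.chi2 - ref.statistic) < 1e-8 * max(1, ref.statistic)
            assert np.isclose(ours.pvalue, ref.pvalue, rtol=1e-8)


class TestConservationByCategory:
    def test_cross_tabulation(self):
        records = []
        for cat, flag, n in ((3, True, 15), (1, True, 5),
                             (3, False, 30), (1, False, 50)):
            sp = frozenset(list("abc")[:cat])
            for k in range(n):
                records.append(ConservationRecord(
                    interval=iv(k * 10, k * 10 + 5), species=sp,
                    flags={"crm": flag}))
        res = conservation_by_category(records, "crm")
        assert res.table.sum() == 100 and res.dof == 1
        assert abs(res.chi2 - 9.09) < 0.01

    def test_missing_flag_rejected(self):
        rec = ConservationRecord(interval=iv(0, 5),
                                 species=frozenset("a"), flags={})
        with pytest.raises(ValueError):
            conservation_by_category([rec], "crm")


class TestCommonUnique:
    def test_identical_sets_all_common(self):
        f1 = {"mel": [iv(0, 100)], "sim": [iv(0, 100)]}
        f2 = {"mel": [iv(0, 100)], "sim": [iv(0, 100)]}
        translated = {"mel": {"Dichaete": [iv(0, 100)],
                              "SoxN": [iv(0, 100)]}}
        results, _ = common_unique_analysis(f1, f2, translated)
        assert results["mel"]["classes"]["common"] == 1
        assert results["mel"]["classes"]["unique_Dichaete"] == 0
        assert results["mel"]["conservation_rates"]["common"] == 1.0

    def test_disjoint_sets_no_common(self):
        f1 = {"mel": [iv(0, 100)], "sim": [iv(0, 100)]}
        f2 = {"mel": [iv(500, 600)], "sim": [iv(500, 600)]}
        translated = {"mel": {"Dichaete": [iv(0, 100)],
                              "SoxN": [iv(500, 600)]}}
        results, _ = common_unique_analysis(f1, f2, translated)
        assert results["mel"]["classes"]["common"] == 0
        assert results["mel"]["classes"]["unique_Dichaete"] == 1
        assert results["mel"]["classes"]["unique_SoxN"] == 1


class TestOrthologMapping:
    def test_many_to_one_deduplicated(self):
        image, dropped, overlap = map_targets_via_orthologs(
            {"m1", "m2"}, [("m1", "f1"), ("m2", "f1")])
        assert image == {"f1"} and dropped == 0

    def test_unmapped_counted(self):
        image, dropped, _ = map_targets_via_orthologs(
            {"m1", "m2"}, [("m1", "f1")])
        assert image == {"f1"} and dropped == 1

    def test_overlap_with_reference(self):
        _, _, overlap = map_targets_via_orthologs(
            {"m1", "m2"}, [("m1", "f1"), ("m2", "f2")],
            reference_set={"f2", "f3"})
        assert overlap == 1
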