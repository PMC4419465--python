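import itertools

import numpy as np
import pytest
from scipy import stats

from soxcomp.io_core import GenomicInterval, GenomeSequence, MultipleAlignment
from soxcomp.motifs import (PWM, ScoreDistribution, log_odds,
                            motif_density_compare,
                            nucleotide_conservation_rate,
                            positional_conservation, reverse_complement,
                            scan_alignment, scan_sequence,
                            shuffle_intervals, shuffle_pwm_columns,
                            wilcoxon_rank_sum)


def uniform_pwm(width):
    return PWM("u", np.full((width, 4), 0.25), pseudocount=0.0)


class TestLogOdds:
    def test_uniform_matrix_all_zero(self):
        assert np.allclose(log_odds(uniform_pwm(3)), 0.0)

    def test_pseudocount_plug_in(self):
        pwm = PWM("x", np.array([[1.0, 0, 0, 0]]), pseudocount=0.01)
        w = log_odds(pwm)
        expected = np.log2((1 + 0.01 * 0.25) / (1.01 * 0.25))
        assert np.isclose(w[0, 0], expected)
        assert np.isclose(w[0, 0], 1.989, atol=1e-3)

    def test_pseudocount_shrinks_towards_zero(self):
        probs = np.array([[0.9, 0.04, 0.03, 0.03]])
        mags = []
        for c in (0.01, 0.1, 1.0, 10.0):
            mags.append(np.abs(log_odds(PWM("x", probs, pseudocount=c))).max())
        assert mags == sorted(mags, reverse=True)


class TestScoreDistribution:
    def test_width_one_uniform(self):
        dist = ScoreDistribution(log_odds(uniform_pwm(1)), np.full(4, 0.25))
        assert np.isclose(dist.pmf.sum(), 1.0)
        assert np.isclose(dist.pvalue(0.0), 1.0)

    @pytest.mark.parametrize("width", [2, 4, 6, 8])
    def test_matches_exhaustive_enumeration(self, width, rng):
        probs = rng.dirichlet(np.ones(4) * 2, size=width)
        pwm = PWM("r", probs)
        weights = log_odds(pwm)
        bg = np.full(4, 0.25)
        dist = ScoreDistribution(weights, bg)
        words = np.array(list(itertools.product(range(4), repeat=width)))
        word_scores = weights[np.arange(width)[None, :], words].sum(axis=1)
        desc = np.sort(word_scores)[::-1]
        mass = 0.25 ** width

        def exact_p(threshold):
            return mass * np.searchsorted(-desc, -threshold, side="right")

        # the DP works on a rounded score grid, so each word's score may
        # shift by up to granularity/2 per position
        tol = width * 5e-4 + 1e-6
        for s0 in np.unique(word_scores):
            p_dp = dist.pvalue(s0)
            assert exact_p(s0 + tol) - 1e-9 <= p_dp <= exact_p(s0 - tol) + 1e-9

    def test_pvalue_at_max_score_is_consensus_probability(self):
        probs = np.array([[0.97, 0.01, 0.01, 0.01]] * 3)
        bg = np.array([0.4, 0.3, 0.2, 0.1])
        pwm = PWM("x", probs, background=bg)
        dist = ScoreDistribution(log_odds(pwm), bg)
        max_score = log_odds(pwm).max(axis=1).sum()
        assert np.isclose(dist.pvalue(max_score), 0.4 ** 3, atol=1e-9)

    def test_width_limit_enforced(self):
        with pytest.raises(ValueError):
            ScoreDistribution(np.zeros((25, 4)), np.full(4, 0.25))


@pytest.fixture()
def caaag_pwm():
    probs = np.full((5, 4), 0.02)
    for i, b in enumerate("CAAAG"):
        probs[i, "ACGT".index(b)] = 0.94
    return PWM("caaag", probs)


class TestScanSequence:
    def test_forward_match(self, caaag_pwm):
        matches = scan_sequence("TTCAAAGTT", caaag_pwm, 4.0, 1e-3)
        assert len(matches) == 1
        m = matches[0]
        assert (m.offset, m.strand) == (2, "+")

    def test_reverse_strand_match(self, caaag_pwm):
        matches = scan_sequence("TTCTTTGTT", caaag_pwm, 4.0, 1e-3)
        assert len(matches) == 1
        assert (matches[0].offset, matches[0].strand) == (2, "-")

    def test_strand_symmetry(self, caaag_pwm, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        fwd = scan_sequence(seq, caaag_pwm, 4.0, 1e-3)
        rev = scan_sequence(reverse_complement(seq), caaag_pwm, 4.0, 1e-3)
        n = len(seq)
        w = caaag_pwm.width
        mirrored = sorted((n - w - m.offset, {"+": "-", "-": "+"}[m.strand])
                          for m in rev)
        assert mirrored == sorted((m.offset, m.strand) for m in fwd)

    def test_n_windows_skipped(self, caaag_pwm):
        assert scan_sequence("NNNNNNN", caaag_pwm, 0.0, 1.0) == []
        assert scan_sequence("TTCANAGTT", caaag_pwm, 4.0, 1e-3) == []

    def test_short_sequence_empty(self, caaag_pwm):
        assert scan_sequence("CAA", caaag_pwm) == []


class TestShuffles:
    def test_width_one_pwm_unchanged(self):
        pwm = PWM("x", np.array([[0.7, 0.1, 0.1, 0.1]]))
        assert np.array_equal(shuffle_pwm_columns(pwm, 3).probs, pwm.probs)

    def test_deterministic_and_composition_preserving(self, caaag_pwm):
        s1 = shuffle_pwm_columns(caaag_pwm, 42)
        s2 = shuffle_pwm_columns(caaag_pwm, 42)
        assert np.array_equal(s1.probs, s2.probs)
        orig = sorted(map(tuple, caaag_pwm.probs))
        assert sorted(map(tuple, s1.probs)) == orig

    def test_interval_shuffle_preserves_lengths(self, rng):
        ivs = [GenomicInterval("c", int(s), int(s) + 25)
               for s in rng.integers(0, 900, size=40)]
        out = shuffle_intervals(ivs, {"c": 1000}, seed=5)
        assert [len(o) for o in out] == [25] * 40
        assert shuffle_intervals(ivs, {"c": 1000}, seed=5)[3].start == \
            out[3].start

    def test_exclusion_forces_placement(self):
        ivs = [GenomicInterval("c", 0, 10)]
        excluded = [GenomicInterval("c", 0, 40),
                    GenomicInterval("c", 50, 100)]
        out = shuffle_intervals(ivs, {"c": 100}, seed=1, excluded=excluded)
        assert (out[0].start, out[0].end) == (40, 50)

    def test_interval_longer_than_chromosome_rejected(self):
        with pytest.raises(ValueError):
            shuffle_intervals([GenomicInterval("c", 0, 200)], {"c": 100}, 1)


class TestWilcoxon:
    def test_exact_small_sample(self):
        w, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert w == 3 and np.isclose(p, 2 / 6)

    def test_maximal_separation_n5(self):
        w, p = wilcoxon_rank_sum([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
        assert np.isclose(p, 2 / 252)

    def test_identical_samples_p_one(self):
        _, p = wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_exact_matches_scipy(self, rng):
        for _ in range(100):
            nx = int(rng.integers(1, 7))
            ny = int(rng.integers(1, 13 - nx))
            vals = rng.permutation(np.arange(nx + ny, dtype=float))
            x, y = vals[:nx], vals[nx:]
            w, p = wilcoxon_rank_sum(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact")
            assert np.isclose(p, ref.pvalue, atol=1e-12)

    def test_normal_approximation_close_to_exact(self, rng):
        worst = 0.0
        for _ in range(200):
            nx = int(rng.integers(3, 7))
            ny = int(rng.integers(3, 13 - nx))
            vals = rng.permutation(np.arange(nx + ny, dtype=float))
            x, y = vals[:nx], vals[nx:]
            _, p_exact = wilcoxon_rank_sum(x, y)
            # force the approximation path via a tiny jitter-free large call
            w = np.sum(stats.rankdata(np.concatenate([x, y]))[:nx])
            mean = nx * (nx + ny + 1) / 2
            var = nx * ny * (nx + ny + 1) / 12
            z = (abs(w - mean) - 0.5) / np.sqrt(var)
            p_norm = 2 * stats.norm.sf(max(z, 0.0))
            if p_exact > 0.01:
                worst = max(worst, abs(p_norm - p_exact) / p_exact)
        assert worst < 0.35  # approximation is close on mid-range p


class TestDensityCompare:
    def test_planted_motifs_dominate(self, caaag_pwm, rng):
        bases = np.array(list("ACGT"))
        def random_seq(n):
            return "".join(bases[rng.integers(0, 4, n)])
        chrom = []
        intervals_with, intervals_without = [], []
        pos = 0
        for k in range(100):
            block = list(random_seq(120))
            if k < 50:
                for off in (10, 50, 90):
                    block[off:off + 5] = "CAAAG"
            chrom.extend(block)
            iv = GenomicInterval("c", pos, pos + 120)
            (intervals_with if k < 50 else intervals_without).append(iv)
            pos += 120
        genome = GenomeSequence({"c": "".join(chrom)})
        mean1, mean2, _, p = motif_density_compare(
            intervals_with, intervals_without, genome, caaag_pwm,
            score_cutoff=4.0, p_cutoff=1e-3)
        assert mean1 >= mean2 + 2
        assert p < 1e-6


class TestAlignmentScanning:
    def test_column_mapping_with_gap(self, caaag_pwm):
        aln = MultipleAlignment({
            "a": "TTCAAAGTT",
            "b": "TT-CAAAGT",   # one fewer leading base
        })
        matches = scan_alignment(aln, caaag_pwm, 4.0, 1e-3)
        assert matches["a"][0].alignment_column == 2
        assert matches["b"][0].alignment_column == 3
        assert matches["a"][0].offset == 2 and matches["b"][0].offset == 2

    def test_gap_inside_motif_flagged(self, caaag_pwm):
        aln = MultipleAlignment({
            "a": "TTCAA-AGT",
            "b": "TTCAATAGT",
        })
        matches = scan_alignment(aln, caaag_pwm, 4.0, 1e-3)
        assert matches["a"][0].gapped_span

    def test_positional_conservation_grouping(self, caaag_pwm):
        aln = MultipleAlignment({
            "a": "TTCAAAGTTTTTTTTTTTTT",
            "b": "TTCAAAGTTTTTTTTTTTTT",
            "c": "TTTTTTTTTTTTTCAAAGTT",
            "d": "TTCAAAGTTTTTTTTTTTTT",
        })
        matches = scan_alignment(aln, caaag_pwm, 4.0, 1e-3)
        records = positional_conservation(aln, matches)
        by_col = {r.column: r for r in records if r.strand == "+"}
        assert by_col[2].positionally_conserved
        assert not by_col[2].fully_conserved   # c matches elsewhere
        assert by_col[2].species == frozenset("abd")
        assert not by_col[13].positionally_conserved

    def test_perfect_conservation_implies_rate_one(self, caaag_pwm):
        aln = MultipleAlignment({sp: "TTCAAAGTT" for sp in "abc"})
        matches = scan_alignment(aln, caaag_pwm, 4.0, 1e-3)
        rec = positional_conservation(aln, matches)[0]
        assert rec.fully_conserved and rec.perfectly_conserved
        assert rec.conservation_rate == 1.0


class TestNucleotideConservation:
    def test_identical_rows(self):
        aln = MultipleAlignment({"a": "ACGT", "b": "ACGT"})
        assert nucleotide_conservation_rate(aln, 0, 4) == 1.0

    def test_half_diverged(self):
        aln = MultipleAlignment({"a": "AAAA", "b": "AATT"})
        assert nucleotide_conservation_rate(aln, 0, 4) == 0.5

    def test_gap_columns_never_conserved(self):
        aln = MultipleAlignment({"a": "A-GT", "b": "A-GT"})
        assert nucleotide_conservation_rate(aln, 0, 4) == 0.75

    def test_empty_range_rejected(self):
        aln = MultipleAlignment({"a": "ACGT", "b": "ACGT"})
        with pytest.raises(ValueError):
            nucleotide_conservation_rate(aln, 2, 2)
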