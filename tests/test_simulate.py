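import numpy as np
import pytest

from soxcomp import pipeline
from soxcomp.conservation import annotate_nearest_gene
from soxcomp.crossmap import STATUS_MAPPED, translate_interval
from soxcomp.io_core import (GenomicInterval, read_chain, read_fasta,
                             read_gff_genes, read_intervals)
from soxcomp.motifs import wilcoxon_rank_sum
from soxcomp.simulate import (default_three_species, emit_dataset,
                              plant_sites, simulate_damid_reads,
                              simulate_genomes)


def _zero_branch_phylogeny():
    from soxcomp.simulate import PhylogenySpec, TreeNode
    return PhylogenySpec(root=TreeNode(0.0, children=[
        TreeNode(0.0, "a"), TreeNode(0.0, "b")]))


class TestGenomeEvolution:
    def test_zero_branch_lengths_identical_genomes(self):
        ds = simulate_genomes(_zero_branch_phylogeny(), length=60_000,
                              n_genes=5, seed=1)
        assert ds.genomes["a"]["chr1"] == ds.genomes["b"]["chr1"]
        chain = ds.chains[("a", "b")].chains[0]
        assert chain.aligned_bases == 60_000
        assert chain.src_starts.tolist() == [0]

    def test_jukes_cantor_identity_expectation(self):
        from soxcomp.simulate import PhylogenySpec, TreeNode
        t = 0.1
        phylo = PhylogenySpec(root=TreeNode(0.0, children=[
            TreeNode(0.0, "a"), TreeNode(t, "b")]))
        ds = simulate_genomes(phylo, length=1_000_000, n_genes=10, seed=2)
        chain = ds.chains[("a", "b")].chains[0]
        sa, sb = ds.genomes["a"]["chr1"], ds.genomes["b"]["chr1"]
        matched = total = 0
        for s0, t0, size in zip(chain.src_starts, chain.tgt_starts,
                                chain.sizes):
            a = np.frombuffer(sa[s0:s0 + size].encode(), dtype=np.uint8)
            b = np.frombuffer(sb[t0:t0 + size].encode(), dtype=np.uint8)
            matched += int((a == b).sum())
            total += size
        expected = 0.25 + 0.75 * np.exp(-4 * t / 3)
        assert abs(matched / total - expected) < 0.02 * expected

    def test_fixed_seed_reproducible(self):
        phylo = default_three_species()
        d1 = simulate_genomes(phylo, length=80_000, n_genes=8, seed=7)
        d2 = simulate_genomes(phylo, length=80_000, n_genes=8, seed=7)
        for sp in phylo.species:
            assert d1.genomes[sp]["chr1"] == d2.genomes[sp]["chr1"]

    def test_infeasible_gene_placement_rejected(self):
        with pytest.raises(ValueError):
            simulate_genomes(default_three_species(), length=30_000,
                             n_genes=50, seed=1)

    def test_exons_survive_in_every_species(self):
        ds = simulate_genomes(default_three_species(), length=100_000,
                              n_genes=10, seed=3)
        for sp in ds.phylogeny.species:
            assert len(ds.genes[sp]) == len(ds.genes_root)


class TestPlantSites:
    def test_sites_recorded_and_constraint_zero_identical(self, sox_pwm):
        from soxcomp.simulate import default_three_species
        phylo = default_three_species(constraint_factor=0.0)
        ds = simulate_genomes(phylo, length=150_000, n_genes=15, seed=9)
        truth = plant_sites(ds, sox_pwm, n_sites=20, seed=10,
                            factor_mix={"common": 1.0})
        assert len(truth.sites) <= 20
        assert len(truth.sites) >= 16  # placement may skip crowded genes
        # constraint factor 0 freezes conserved motif instances (window
        # flanks still evolve); site windows are indel-protected, so motif
        # offsets within the window are stable across species
        width = sox_pwm.width
        for site in truth.by_class("conserved"):
            for off in site.motif_offsets:
                rel = off - site.root_start
                seqs = set()
                for sp in phylo.species:
                    lo, _ = site.presence[sp]
                    seqs.add(ds.genomes[sp]["chr1"][lo + rel:lo + rel + width])
                assert len(seqs) == 1

    def test_class_mix_must_sum_to_one(self, small_dataset, sox_pwm):
        with pytest.raises(ValueError):
            plant_sites(small_dataset, sox_pwm, n_sites=5,
                        class_mix={"conserved": 0.5})

    def test_conserved_sites_translate_through_truth_chains(
            self, small_dataset):
        ds = small_dataset
        for site in ds.truth.by_class("conserved"):
            lo, hi = site.presence["mel"]
            entry = translate_interval(GenomicInterval("chr1", lo, hi),
                                       ds.chains[("mel", "yak")], 0.7)
            assert entry.status == STATUS_MAPPED
            ylo, yhi = site.presence["yak"]
            assert entry.target.start < yhi and ylo < entry.target.end

    def test_turnover_windows_same_gene_no_overlap(self, small_dataset):
        ds = small_dataset
        genes_mel = ds.genes["mel"]
        for site in ds.truth.by_class("turnover"):
            (sp_a, sp_b) = sorted(site.species_present())
            win_a = site.presence[sp_a]
            win_b = site.presence[sp_b]
            # translate B's window onto A's genome: must not overlap A's
            if sp_a != "mel":
                continue
            entry = translate_interval(
                GenomicInterval("chr1", win_b[0], win_b[1]),
                ds.chains[(sp_b, "mel")], 0.7)
            assert entry.status == STATUS_MAPPED
            assert not (entry.target.start < win_a[1]
                        and win_a[0] < entry.target.end)
            anns = annotate_nearest_gene(
                [GenomicInterval("chr1", *win_a), entry.target], genes_mel)
            assert anns[0].gene_id == anns[1].gene_id == site.gene_id

    def test_binding_drift_grows_with_distance(self, small_dataset):
        ds = small_dataset
        lf = np.array([[np.log(s.species_fold(sp))
                        for sp in ("mel", "sim", "yak")]
                       for s in ds.truth.sites])
        d_close = np.var(lf[:, 0] - lf[:, 1])
        d_far = np.var(lf[:, 0] - lf[:, 2])
        assert d_far > d_close


class TestReads:
    def test_depth_conserved(self, small_dataset):
        for sample in small_dataset.samples["Dichaete"]:
            n = len(sample.reads)
            # NB total: mean = depth, sd ~ sqrt(depth (1 + alpha mu))
            assert abs(n - 30_000) < 6 * np.sqrt(30_000 * 7)

    def test_enrichment_localized_to_sites(self, small_dataset, sox_pwm):
        ds = small_dataset
        from soxcomp.gatc_quant import build_gatc_fragment_map
        frag_map = build_gatc_fragment_map(ds.genomes["mel"])
        mids = frag_map.midpoints("chr1")
        site_mids = np.array([(s.presence["mel"][0] + s.presence["mel"][1]) // 2
                              for s in ds.truth.sites
                              if s.presence["mel"] is not None])
        dist = np.min(np.abs(mids[:, None] - site_mids[None, :]), axis=1)
        fusion = [s for s in ds.samples["Dichaete"]
                  if s.condition == "fusion" and s.species == "mel"]
        control = [s for s in ds.samples["Dichaete"]
                   if s.condition == "control" and s.species == "mel"]
        from soxcomp.gatc_quant import count_fragment_coverage, extend_reads
        f = sum(count_fragment_coverage(
            frag_map, extend_reads(s, 200, ds.genomes["mel"].lengths))
            for s in fusion)
        c = sum(count_fragment_coverage(
            frag_map, extend_reads(s, 200, ds.genomes["mel"].lengths))
            for s in control)
        near = dist < 300
        far = dist > 1500
        ratio_near = f[near].sum() / max(c[near].sum(), 1)
        ratio_far = f[far].sum() / max(c[far].sum(), 1)
        assert ratio_near > 2.0 * ratio_far

    def test_null_fold_gives_equal_distributions(self, sox_pwm):
        ds = simulate_genomes(default_three_species(), length=100_000,
                              n_genes=10, seed=20)
        plant_sites(ds, sox_pwm, n_sites=8, seed=21,
                    factor_mix={"common": 1.0}, fold_range=(1.0, 1.0),
                    binding_drift=0.0)
        samples = simulate_damid_reads(ds, depth=20_000, seed=22)
        from soxcomp.gatc_quant import (build_gatc_fragment_map,
                                        count_fragment_coverage, extend_reads)
        frag_map = build_gatc_fragment_map(ds.genomes["mel"])
        per_cond = {}
        for s in samples["mel"]:
            cov = count_fragment_coverage(
                frag_map, extend_reads(s, 200, ds.genomes["mel"].lengths))
            per_cond.setdefault(s.condition, []).append(cov)
        f = np.mean(per_cond["fusion"], axis=0)
        c = np.mean(per_cond["control"], axis=0)
        _, p = wilcoxon_rank_sum(f, c)
        assert p > 0.01

    def test_invalid_parameters_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            simulate_damid_reads(small_dataset, spread=0, depth=20_000)
        with pytest.raises(ValueError):
            simulate_damid_reads(small_dataset, depth=100)


class TestEmission:
    def test_round_trip_and_manifest(self, small_dataset, tmp_path):
        ds = small_dataset
        emit_dataset(ds, tmp_path)
        genome = read_fasta(tmp_path / "mel.fa")
        assert genome["chr1"] == ds.genomes["mel"]["chr1"]
        genes = read_gff_genes(tmp_path / "mel.gff3")
        assert {g.gene_id for g in genes} == \
            {g.gene_id for g in ds.genes["mel"]}
        assert genes[0].exons == ds.genes["mel"][0].exons
        chains = read_chain(tmp_path / "sim_to_mel.chain")
        orig = ds.chains[("sim", "mel")].chains[0]
        assert np.array_equal(chains.chains[0].src_starts, orig.src_starts)
        sample = ds.samples["Dichaete"][0]
        reads = read_intervals(tmp_path / f"{sample.label}.bed", "BED6")
        assert len(reads) == len(sample.reads)
        assert (reads[0].start, reads[0].strand) == \
            (sample.reads[0].start, sample.reads[0].strand)
        import json
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["seed"] == ds.seed
        assert manifest["n_sites"] == len(ds.truth.sites)

    def test_truth_table_lists_all_sites(self, small_dataset, tmp_path):
        emit_dataset(small_dataset, tmp_path)
        lines = (tmp_path / "truth.tsv").read_text().strip().split("\n")
        assert len(lines) - 1 == len(small_dataset.truth.sites)


class TestPhylogeny:
    def test_newick_round_trip_distances(self):
        phylo = default_three_species()
        assert phylo.species == ["mel", "sim", "yak"]
        assert np.isclose(phylo.pairwise_distance("mel", "sim"), 0.05)
        assert np.isclose(phylo.pairwise_distance("mel", "yak"), 0.2)

    def test_invalid_constraint_rejected(self):
        with pytest.raises(ValueError):
            default_three_species(constraint_factor=1.5)
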