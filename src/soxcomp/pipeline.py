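"""End-to-end analyses on simulated data with known ground truth.

These functions wire the pipeline stages together exactly as they would run
on real data — fragment counting, NB enrichment calling, chain liftover,
conservation/turnover classification, joint quantitative comparison and
motif-conservation scoring — and score every stage against the planted
truth.  They back the example scripts and the package's validation suite.
"""

from __future__ import annotations

import numpy as np

from . import conservation as cons
from . import crossmap, enrichment, motifs, quantcompare
from .gatc_quant import (FragmentCountTable, GatcFragmentMap, SampleReads,
                         assemble_count_table, build_gatc_fragment_map)
from .io_core import GenomicInterval, MultipleAlignment
from .simulate import (CHROM, PhylogenySpec, SimulatedDataset, TreeNode,
                       _evolve_branch, default_four_species,
                       default_three_species, plant_sites, simulate_damid_reads,
                       simulate_genomes)


# ---------------------------------------------------------------------------
# per-species binding calls
# ---------------------------------------------------------------------------

def call_species_binding(dataset: SimulatedDataset, factor: str,
                         threshold: float = 0.05, merge_gap: int = 100,
                         extension_length: int = 200):
    """Count, test and call binding intervals per species for one factor.

    Returns {species: (fragment_map, count_table, enrichment_result,
    binding_interval_set)}.
    """
    out = {}
    by_species: dict[str, list[SampleReads]] = {}
    for sample in dataset.samples[factor]:
        by_species.setdefault(sample.species, []).append(sample)
    for sp, samples in by_species.items():
        frag_map = build_gatc_fragment_map(dataset.genomes[sp])
        table = assemble_count_table(frag_map, samples, extension_length)
        result = enrichment.test_enrichment(table)
        calls = enrichment.call_binding_intervals(
            result, frag_map, threshold=threshold, merge_gap=merge_gap,
            species=sp, factor=factor)
        out[sp] = (frag_map, table, result, calls)
    return out


def translate_calls_to_reference(dataset: SimulatedDataset, calls: dict,
                                 reference: str, min_match: float = 0.7
                                 ) -> dict[str, list[GenomicInterval]]:
    """Native reference calls plus other species' calls lifted over."""
    translated = {}
    for sp, (_, _, _, call_set) in calls.items():
        if sp == reference:
            translated[sp] = list(call_set)
            continue
        entries = crossmap.translate_intervals(
            list(call_set), dataset.chains[(sp, reference)], min_match)
        translated[sp] = [e.target for e in entries
                          if e.status == crossmap.STATUS_MAPPED]
    return translated


# ---------------------------------------------------------------------------
# truth-based evaluation
# ---------------------------------------------------------------------------

def _site_windows(dataset: SimulatedDataset, factor: str, species: str,
                  spread: int) -> list[GenomicInterval]:
    """Expected enriched windows (site span +- spread) for one species."""
    windows = []
    for site in dataset.truth.sites:
        if site.factor_class not in (factor, "common"):
            continue
        pos = site.presence[species]
        if pos is None:
            continue
        windows.append(GenomicInterval(
            CHROM, max(0, pos[0] - spread),
            min(len(dataset.genomes[species][CHROM]), pos[1] + spread),
            name=site.site_id))
    return windows


def evaluate_recovery(dataset: SimulatedDataset, factor: str, species: str,
                      call_set, spread: int | None = None) -> dict:
    """Planted-site recovery and empirical FDR of one species' calls."""
    if spread is None:
        spread = dataset.read_params[factor]["spread"]
    windows = _site_windows(dataset, factor, species, spread)
    calls = list(call_set)
    recovered = cons.overlaps_any(windows, calls)
    false_call = ~cons.overlaps_any(calls, windows)
    return {
        "n_sites": len(windows),
        "n_recovered": int(recovered.sum()),
        "recovery": float(recovered.mean()) if len(windows) else np.nan,
        "n_calls": len(calls),
        "n_false": int(false_call.sum()),
        "fdr": float(false_call.mean()) if calls else 0.0,
        "recovered_ids": {w.name for w, r in zip(windows, recovered) if r},
    }


def site_reference_window(dataset: SimulatedDataset, site,
                          reference: str) -> GenomicInterval | None:
    """A planted site's locus projected onto the reference genome."""
    from .simulate import _interval_to_leaf
    r2l = dataset.root_to_leaf(reference)
    valid = np.flatnonzero(r2l >= 0)
    leaf_of = r2l[valid]
    span = _interval_to_leaf(valid, leaf_of, site.root_start, site.root_end)
    if span is None:
        return None
    return GenomicInterval(CHROM, span[0], span[1], name=site.site_id)


def evaluate_conservation_accuracy(dataset: SimulatedDataset, factor: str,
                                   translated: dict[str, list[GenomicInterval]],
                                   recovered_ids: dict[str, set[str]],
                                   reference: str) -> dict:
    """Category accuracy of union-accounted conservation classification.

    Scored on planted sites recovered in every species where they are
    present.  For turnover sites each presence window is scored separately
    (each is bound in exactly one species).
    """
    records = cons.classify_conservation(translated)
    scored = correct = 0
    details = []
    for site in dataset.truth.sites:
        if site.factor_class not in (factor, "common"):
            continue
        present = site.species_present()
        if not present:
            continue
        if any(site.site_id not in recovered_ids.get(sp, set())
               for sp in present):
            continue
        if site.conservation_class == "turnover":
            expected = 1  # each window bound in one species
        else:
            expected = len(present)
        window = site_reference_window(dataset, site, reference)
        if window is None:
            continue
        overlapping = [rec for rec in records
                       if rec.interval.overlaps(window)]
        if not overlapping:
            continue
        if site.conservation_class == "turnover":
            ok = all(rec.category == 1 for rec in overlapping)
        else:
            ok = any(rec.category == expected for rec in overlapping)
        scored += 1
        correct += ok
        details.append((site.site_id, site.conservation_class, ok))
    return {
        "n_scored": scored,
        "accuracy": correct / scored if scored else np.nan,
        "records": records,
        "details": details,
    }


def evaluate_turnover(dataset: SimulatedDataset, factor: str,
                      translated: dict[str, list[GenomicInterval]],
                      recovered_ids: dict[str, set[str]],
                      reference: str) -> dict:
    """Detection rate of planted turnover genes across all species pairs."""
    genes_ref = dataset.genes[reference]
    annotations = {sp: cons.annotate_nearest_gene(ivs, genes_ref)
                   for sp, ivs in translated.items()}
    species = dataset.phylogeny.species
    detected = {}
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            events = cons.detect_turnover(annotations[a], annotations[b],
                                          species_a=a, species_b=b)
            detected[(a, b)] = {e.gene_id for e in events}
    eligible = hit = 0
    for site in dataset.truth.sites:
        if site.conservation_class != "turnover":
            continue
        if site.factor_class not in (factor, "common"):
            continue
        present = sorted(site.species_present())
        if len(present) != 2:
            continue
        if site.site_id not in recovered_ids.get(present[0], set()) or \
                site.site_id not in recovered_ids.get(present[1], set()):
            continue
        eligible += 1
        pair = tuple(present) if tuple(present) in detected \
            else (present[1], present[0])
        if site.gene_id in detected.get(pair, set()):
            hit += 1
    return {
        "n_eligible": eligible,
        "n_detected": hit,
        "detection_rate": hit / eligible if eligible else np.nan,
        "events_per_pair": {k: len(v) for k, v in detected.items()},
    }


# ---------------------------------------------------------------------------
# joint quantitative comparison
# ---------------------------------------------------------------------------

def joint_quantitative_analysis(dataset: SimulatedDataset, factor: str,
                                reference: str,
                                translated_calls: dict[str, list],
                                min_match: float = 0.7,
                                fdr_level: float = 0.05) -> dict:
    """Translate fusion reads to the reference and compare quantitatively.

    Produces the jointly normalized affinity matrix over consensus
    intervals, sample correlations, a PCA and pairwise differential-binding
    counts against the reference species.
    """
    fusion = [s for s in dataset.samples[factor] if s.condition == "fusion"]
    ref_len = dataset.genomes[reference].lengths
    translated_samples = []
    for sample in fusion:
        if sample.species == reference:
            translated_samples.append(sample)
        else:
            tr, _ = crossmap.translate_reads(
                sample, dataset.chains[(sample.species, reference)],
                min_match)
            translated_samples.append(tr)
    consensus = quantcompare.build_consensus(
        [list(v) for v in translated_calls.values()], min_occupancy=2)
    matrix = quantcompare.build_affinity_matrix(
        consensus, translated_samples, ref_len)
    corr, leaf_order, _ = quantcompare.correlation_and_cluster(matrix)
    coords, explained = quantcompare.pca_samples(matrix)

    species_of = matrix.metadata["species"].to_numpy()
    same = corr[np.equal.outer(species_of, species_of)
                & ~np.eye(len(species_of), dtype=bool)]
    diff = corr[~np.equal.outer(species_of, species_of)]

    diffbind = {}
    for other in dataset.phylogeny.species:
        if other == reference:
            continue
        res = quantcompare.differential_binding(
            matrix, species_of, reference, other, fdr_level=fdr_level,
            native_calls={reference: translated_calls[reference],
                          other: translated_calls[other]})
        diffbind[other] = {
            "n_significant": int(res.significant.sum()),
            "n_quantitative": int((res.divergence_class
                                   == "quantitative").sum()),
            "n_qualitative": int((res.divergence_class
                                  == "qualitative").sum()),
            "distance": dataset.phylogeny.pairwise_distance(reference, other),
        }
    return {
        "matrix": matrix,
        "correlations": corr,
        "leaf_order": leaf_order,
        "mean_within_species_r": float(same.mean()),
        "mean_cross_species_r": float(diff.mean()),
        "pca_coords": coords,
        "pca_explained": explained,
        "diffbind": diffbind,
    }


def pc1_separates_most_divergent(dataset: SimulatedDataset,
                                 quant: dict, reference: str) -> bool:
    """Does PC1 split the most divergent species from the rest?"""
    species = dataset.phylogeny.species
    dists = {sp: dataset.phylogeny.pairwise_distance(reference, sp)
             for sp in species if sp != reference}
    far = max(dists, key=dists.get)
    labels = quant["matrix"].metadata["species"].to_numpy()
    pc1 = quant["pca_coords"][:, 0]
    far_vals = pc1[labels == far]
    near_vals = pc1[labels != far]
    return far_vals.min() > near_vals.max() or far_vals.max() < near_vals.min()


# ---------------------------------------------------------------------------
# calibration and benchmark scenarios
# ---------------------------------------------------------------------------

def _synthetic_fragment_map(n_fragments: int, fragment_len: int = 200
                            ) -> GatcFragmentMap:
    bounds = np.arange(1, n_fragments) * fragment_len
    return GatcFragmentMap({CHROM: bounds},
                           {CHROM: n_fragments * fragment_len})


def null_calibration(seed: int, n_fragments: int = 5000,
                     replicates: int = 3, mean: float = 50.0,
                     alpha: float = 0.1) -> dict:
    """Fusion == control NB null: raw-p level and BH call count."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = 2 * replicates
    lam = rng.gamma(1.0 / alpha, alpha * mean, size=(n_fragments, n))
    counts = rng.poisson(lam)
    frag_map = _synthetic_fragment_map(n_fragments)
    metadata = pd.DataFrame({
        "label": [f"s{i}" for i in range(n)],
        "condition": ["control"] * replicates + ["fusion"] * replicates,
        "factor": ["none"] * replicates + ["Dichaete"] * replicates,
        "species": ["mel"] * n,
        "replicate": list(range(1, replicates + 1)) * 2,
    })
    table = FragmentCountTable(counts.astype(np.int64), frag_map, metadata)
    result = enrichment.test_enrichment(table)
    tested = result.tested
    frac = float((result.pvalue[tested] < 0.05).mean())
    n_bh = int((result.padj[tested] < 0.05).sum())
    return {"raw_p05_fraction": frac, "n_bh_calls": n_bh,
            "n_tested": int(tested.sum())}


def single_species_phylogeny(name: str = "mel") -> PhylogenySpec:
    return PhylogenySpec(root=TreeNode(0.0, children=[TreeNode(0.0, name)]))


def recovery_benchmark(seed: int, length: int = 1_000_000,
                       n_sites: int = 200, depth: int = 200_000,
                       n_genes: int | None = None) -> dict:
    """Single-genome planted-site recovery and empirical FDR at padj<0.05."""
    pwm = sox_consensus_pwm()
    if n_genes is None:
        n_genes = max(10, int(length / 9000))
    dataset = simulate_genomes(single_species_phylogeny(), length=length,
                               n_genes=n_genes, seed=seed)
    plant_sites(dataset, pwm, n_sites=n_sites,
                class_mix={"conserved": 1.0},
                factor_mix={"common": 1.0}, seed=seed + 1)
    simulate_damid_reads(dataset, factor="Dichaete", depth=depth,
                         seed=seed + 2)
    calls = call_species_binding(dataset, "Dichaete", threshold=0.05)
    _, _, _, call_set = calls["mel"]
    return evaluate_recovery(dataset, "Dichaete", "mel", call_set)


def sox_consensus_pwm(name: str = "sox_core") -> "motifs.PWM":
    """A sharp CAAAG-core HMG-box-like matrix used throughout the
    simulations (the fourth core position carries the A/T wobble)."""
    probs = np.array([
        [0.03, 0.91, 0.03, 0.03],   # C
        [0.91, 0.03, 0.03, 0.03],   # A
        [0.91, 0.03, 0.03, 0.03],   # A
        [0.76, 0.03, 0.03, 0.18],   # A/T wobble position
        [0.03, 0.03, 0.91, 0.03],   # G
        [0.03, 0.03, 0.03, 0.91],   # T
        [0.03, 0.91, 0.03, 0.03],   # C
    ])
    return motifs.PWM(name=name, probs=probs)


def run_three_species_scenario(seed: int, length: int = 1_000_000,
                               n_sites: int = 300, depth: int = 200_000,
                               n_genes: int | None = None,
                               reference: str = "mel",
                               threshold: float = 0.05) -> dict:
    """The default comparative scenario, end to end.

    Simulates three species at branch-length ratios 1:1:4, plants sites of
    all conservation classes, draws 3+3 replicate read sets per species,
    calls binding, lifts everything onto the reference and scores recovery,
    conservation classification, turnover detection and the joint
    quantitative comparison against the truth.
    """
    pwm = sox_consensus_pwm()
    phylo = default_three_species()
    if n_genes is None:
        n_genes = max(20, int(length / 9000))
    dataset = simulate_genomes(phylo, length=length, n_genes=n_genes,
                               seed=seed)
    plant_sites(dataset, pwm, n_sites=n_sites, seed=seed + 1,
                factor_mix={"common": 1.0})
    simulate_damid_reads(dataset, factor="Dichaete", depth=depth,
                         seed=seed + 2)
    calls = call_species_binding(dataset, "Dichaete", threshold=threshold)
    recovery = {}
    recovered_ids = {}
    for sp, (_, _, _, call_set) in calls.items():
        recovery[sp] = evaluate_recovery(dataset, "Dichaete", sp, call_set)
        recovered_ids[sp] = recovery[sp]["recovered_ids"]
    translated = translate_calls_to_reference(dataset, calls, reference)
    conservation = evaluate_conservation_accuracy(
        dataset, "Dichaete", translated, recovered_ids, reference)
    turnover = evaluate_turnover(dataset, "Dichaete", translated,
                                 recovered_ids, reference)
    quant = joint_quantitative_analysis(dataset, "Dichaete", reference,
                                        translated)
    return {
        "dataset": dataset,
        "calls": calls,
        "translated": translated,
        "recovery": recovery,
        "conservation": conservation,
        "turnover": turnover,
        "quant": quant,
        "pc1_separates": pc1_separates_most_divergent(
            dataset, quant, reference),
    }


# ---------------------------------------------------------------------------
# motif conservation study
# ---------------------------------------------------------------------------

def motif_conservation_study(seed: int, n_loci: int = 600,
                             locus_length: int = 260,
                             phylogeny: PhylogenySpec | None = None,
                             pwm=None) -> dict:
    """Constrained planted motifs vs neutrally evolving shuffled controls.

    Each locus carries one PWM-sampled instance evolving at the constraint
    factor and one shuffled-control instance evolving neutrally; true
    alignments are scanned with the respective matrix and per-motif
    nucleotide conservation rates are compared by rank-sum test.
    """
    rng = np.random.default_rng(seed)
    phylo = phylogeny or default_four_species()
    pwm = pwm or sox_consensus_pwm()
    control_pwm = motifs.shuffle_pwm_columns(pwm, seed=seed + 7)
    while control_pwm.consensus == pwm.consensus:
        control_pwm = motifs.shuffle_pwm_columns(
            control_pwm, seed=int(rng.integers(2 ** 31)))
    from .simulate import _sample_motif

    dist = motifs.ScoreDistribution(motifs.log_odds(pwm), pwm.background)
    dist_ctl = motifs.ScoreDistribution(motifs.log_odds(control_pwm),
                                        control_pwm.background)
    rates_real, rates_ctl = [], []
    w = pwm.width
    for _ in range(n_loci):
        ancestor = rng.integers(0, 4, size=locus_length, dtype=np.int8)
        pos_real = int(rng.integers(20, locus_length // 2 - w - 10))
        pos_ctl = int(rng.integers(locus_length // 2 + 10,
                                   locus_length - w - 20))
        ancestor[pos_real:pos_real + w] = _sample_motif(pwm, rng)
        ancestor[pos_ctl:pos_ctl + w] = _sample_motif(control_pwm, rng)
        factor_root = np.ones(locus_length)
        factor_root[pos_real:pos_real + w] = phylo.constraint_factor
        protected = np.zeros(locus_length, dtype=bool)
        protected[pos_real:pos_real + w] = True
        protected[pos_ctl:pos_ctl + w] = True
        leaves: dict[str, tuple[np.ndarray, np.ndarray]] = {}

        def walk(node, seq, rp):
            seq, rp = _evolve_branch(seq, rp, node.length, rng,
                                     factor_root, protected)
            if node.is_leaf:
                leaves[node.name] = (seq, rp)
            for ch in node.children:
                walk(ch, seq, rp)
        walk(phylo.root, ancestor, np.arange(locus_length, dtype=np.int64))
        aln = _alignment_from_leaves(leaves, locus_length)
        for matrix, d, store in ((pwm, dist, rates_real),
                                 (control_pwm, dist_ctl, rates_ctl)):
            matches = motifs.scan_alignment(aln, matrix, distribution=d)
            for rec in motifs.positional_conservation(aln, matches):
                store.append(rec.conservation_rate)
    if not rates_real or not rates_ctl:
        raise RuntimeError("no motif matches found in the simulation")
    w_stat, p = motifs.wilcoxon_rank_sum(rates_real, rates_ctl)
    return {
        "n_real": len(rates_real),
        "n_control": len(rates_ctl),
        "mean_rate_real": float(np.mean(rates_real)),
        "mean_rate_control": float(np.mean(rates_ctl)),
        "rank_sum_p": p,
    }


def _alignment_from_leaves(leaves: dict[str, tuple[np.ndarray, np.ndarray]],
                           root_length: int) -> MultipleAlignment:
    """Build the exact alignment of small leaf sequences from leaf maps."""
    from .simulate import _codes_to_string

    species = list(leaves)
    seqs = {sp: _codes_to_string(seq) for sp, (seq, _) in leaves.items()}
    r2l = {}
    inserts: dict[str, dict[int, list[int]]] = {sp: {} for sp in species}
    for sp, (seq, rp) in leaves.items():
        inv = np.full(root_length, -1, dtype=np.int64)
        valid = rp >= 0
        inv[rp[valid]] = np.flatnonzero(valid)
        r2l[sp] = inv
        anchor = -1
        for i, r in enumerate(rp):
            if r >= 0:
                anchor = int(r)
            else:
                inserts[sp].setdefault(anchor, []).append(i)
    rows = {sp: [] for sp in species}
    for r in range(root_length):
        for sp in species:
            leaf = r2l[sp][r]
            rows[sp].append(seqs[sp][leaf] if leaf >= 0 else "-")
        for sp in species:
            ins = inserts[sp].get(r)
            if ins:
                for other in species:
                    if other == sp:
                        rows[other].extend(seqs[sp][i] for i in ins)
                    else:
                        rows[other].extend("-" * len(ins))
    return MultipleAlignment({sp: "".join(chars) for sp, chars in rows.items()})
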