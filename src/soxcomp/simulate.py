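"""Synthetic multi-species DamID datasets with full ground truth.

An ancestral i.i.d. uniform-composition sequence carrying gene models, CRMs
and planted motif clusters is evolved along a rooted phylogeny under
Jukes-Cantor substitutions plus short indels (geometric lengths, rate 10% of
the substitution rate) outside exons and planted site windows.  Because the
complete homology map is recorded during evolution, pairwise chains and
per-locus multiple alignments are emitted exactly, with no inference.

Planted binding sites come in conservation classes (conserved in all
species / unique to one / turned over within a gene locus) and factor
classes (Dichaete-only / SoxN-only / common); only conserved-class motifs
evolve under the constraint factor.  Replicate DamID read sets are drawn per
GATC fragment from a negative binomial whose fusion-sample mean is raised
around each planted site by a triangular kernel of finite half-width
("spread") over a uniform Dam-only background.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .gatc_quant import SampleReads, build_gatc_fragment_map
from .io_core import (Chain, ChainMap, GeneModel, GenomeSequence,
                      GenomicInterval, MultipleAlignment, write_alignment,
                      write_chain, write_fasta, write_gff_genes,
                      write_intervals)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
CHROM = "chr1"


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    length: float
    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhylogenySpec:
    """Rooted tree with branch lengths in expected substitutions per
    neutral site, plus the relative substitution rate inside constrained
    motifs."""

    root: TreeNode
    constraint_factor: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.constraint_factor <= 1:
            raise ValueError("constraint factor must lie in [0, 1]")

        def check(node: TreeNode) -> None:
            if node.length < 0:
                raise ValueError("negative branch length")
            for ch in node.children:
                check(ch)
        check(self.root)

    @property
    def species(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node.name)
            for ch in node.children:
                walk(ch)
        walk(self.root)
        return out

    def pairwise_distance(self, a: str, b: str) -> float:
        path: dict[str, list[TreeNode]] = {}

        def walk(node: TreeNode, trail: list[TreeNode]) -> None:
            trail = trail + [node]
            if node.is_leaf:
                path[node.name] = trail
            for ch in node.children:
                walk(ch, trail)
        walk(self.root, [])
        pa, pb = path[a], path[b]
        shared = 0
        for na, nb in zip(pa, pb):
            if na is nb:
                shared += 1
            else:
                break
        return sum(n.length for n in pa[shared:]) + \
            sum(n.length for n in pb[shared:])

    @classmethod
    def from_newick(cls, newick: str, constraint_factor: float = 0.1
                    ) -> "PhylogenySpec":
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")

        def convert(node) -> TreeNode:
            return TreeNode(
                length=node.edge.length or 0.0,
                name=node.taxon.label if node.taxon else None,
                children=[convert(ch) for ch in node.child_nodes()])
        return cls(root=convert(tree.seed_node),
                   constraint_factor=constraint_factor)


def default_three_species(constraint_factor: float = 0.1) -> PhylogenySpec:
    """mel/sim close, yak distant: pairwise ratios roughly 1:1:4."""
    return PhylogenySpec.from_newick(
        "((mel:0.025,sim:0.025):0.075,yak:0.1);",
        constraint_factor=constraint_factor)


def default_four_species(constraint_factor: float = 0.1) -> PhylogenySpec:
    return PhylogenySpec.from_newick(
        "(((mel:0.02,sim:0.02):0.04,yak:0.06):0.06,pse:0.12);",
        constraint_factor=constraint_factor)


# ---------------------------------------------------------------------------
# truth registry
# ---------------------------------------------------------------------------

@dataclass
class PlantedSite:
    site_id: str
    root_start: int                 # ancestral window (species-1 position
    root_end: int                   # for turnover; see positions)
    conservation_class: str         # conserved / unique / turnover
    factor_class: str               # common / Dichaete / SoxN
    fold: float                     # ancestral enrichment fold
    gene_id: str
    crm: bool
    motif_offsets: tuple[int, ...]  # root coords of planted instances
    presence: dict[str, tuple[int, int] | None] = field(default_factory=dict)
    fold_by_species: dict[str, float] = field(default_factory=dict)

    def species_fold(self, species: str) -> float:
        return self.fold_by_species.get(species, self.fold)

    def species_present(self) -> list[str]:
        return [sp for sp, pos in self.presence.items() if pos is not None]


@dataclass
class SimulationTruth:
    sites: list[PlantedSite]
    seed: int

    def by_class(self, conservation_class: str) -> list[PlantedSite]:
        return [s for s in self.sites
                if s.conservation_class == conservation_class]


@dataclass
class SimulatedDataset:
    phylogeny: PhylogenySpec
    length: int
    seed: int
    ancestor: np.ndarray                      # int8 codes 0..3
    genes_root: list[GeneModel]
    crms_root: list[GenomicInterval]
    genomes: dict[str, GenomeSequence] = field(default_factory=dict)
    leaf_root_pos: dict[str, np.ndarray] = field(default_factory=dict)
    genes: dict[str, list[GeneModel]] = field(default_factory=dict)
    crms: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    chains: dict[tuple[str, str], ChainMap] = field(default_factory=dict)
    alignments: dict[str, MultipleAlignment] = field(default_factory=dict)
    truth: SimulationTruth | None = None
    samples: dict[str, list[SampleReads]] = field(default_factory=dict)
    read_params: dict = field(default_factory=dict)

    def root_to_leaf(self, species: str) -> np.ndarray:
        rp = self.leaf_root_pos[species]
        out = np.full(self.length, -1, dtype=np.int64)
        valid = rp >= 0
        out[rp[valid]] = np.flatnonzero(valid)
        return out


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _evolve_branch(seq: np.ndarray, root_pos: np.ndarray, t: float,
                   rng: np.random.Generator, factor_root: np.ndarray,
                   protected_root: np.ndarray, indel_ratio: float = 0.1,
                   mean_indel: float = 3.0):
    """One branch: JC substitutions then indels, honoring constraints."""
    n = len(seq)
    if t <= 0:
        return seq.copy(), root_pos.copy()
    safe = np.maximum(root_pos, 0)
    factor = np.where(root_pos >= 0, factor_root[safe], 1.0)
    p_sub = 0.75 * (1.0 - np.exp(-4.0 * t * factor / 3.0))
    seq = seq.copy()
    mask = rng.random(n) < p_sub
    seq[mask] = (seq[mask] + rng.integers(1, 4, size=int(mask.sum()),
                                          dtype=np.int8)) % 4

    n_events = rng.poisson(indel_ratio * t * n)
    if n_events == 0:
        return seq, root_pos.copy()
    prot = np.where(root_pos >= 0, protected_root[safe], False)
    pos = np.sort(rng.integers(0, n, size=n_events))
    is_ins = rng.random(n_events) < 0.5
    lens = rng.geometric(1.0 / mean_indel, size=n_events)
    seq_parts, map_parts = [], []
    cursor = 0
    for p, ins, ln in zip(pos, is_ins, lens):
        if p < cursor:
            continue
        if ins:
            if 0 < p < n and prot[p - 1] and prot[p]:
                continue  # would split a protected run
            seq_parts.append(seq[cursor:p])
            map_parts.append(root_pos[cursor:p])
            seq_parts.append(rng.integers(0, 4, size=ln, dtype=np.int8))
            map_parts.append(np.full(ln, -1, dtype=np.int64))
            cursor = p
        else:
            end = min(p + ln, n)
            if prot[p:end].any():
                continue
            seq_parts.append(seq[cursor:p])
            map_parts.append(root_pos[cursor:p])
            cursor = end
    seq_parts.append(seq[cursor:])
    map_parts.append(root_pos[cursor:])
    return np.concatenate(seq_parts), np.concatenate(map_parts)


def _codes_to_string(seq: np.ndarray) -> str:
    return _BASE_BYTES[seq].tobytes().decode()


def _evolve_tree(dataset: SimulatedDataset, factor_root: np.ndarray,
                 protected_root: np.ndarray, seed: int) -> None:
    """(Re)run evolution from the ancestor; fills genomes and leaf maps."""
    rng = np.random.default_rng(seed)
    results: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def walk(node: TreeNode, seq: np.ndarray, root_pos: np.ndarray) -> None:
        seq, root_pos = _evolve_branch(seq, root_pos, node.length, rng,
                                       factor_root, protected_root)
        if node.is_leaf:
            results[node.name] = (seq, root_pos)
        for ch in node.children:
            walk(ch, seq, root_pos)

    root_map = np.arange(dataset.length, dtype=np.int64)
    walk(dataset.phylogeny.root, dataset.ancestor, root_map)

    dataset.genomes = {sp: GenomeSequence({CHROM: _codes_to_string(seq)})
                       for sp, (seq, _) in results.items()}
    dataset.leaf_root_pos = {sp: rp for sp, (_, rp) in results.items()}
    _project_annotations(dataset)
    _build_chains(dataset)


def _interval_to_leaf(r2l_valid: np.ndarray, leaf_of: np.ndarray,
                      start: int, end: int) -> tuple[int, int] | None:
    """Leaf span covering retained root positions of [start, end)."""
    i0 = np.searchsorted(r2l_valid, start, side="left")
    i1 = np.searchsorted(r2l_valid, end, side="left") - 1
    if i1 < i0:
        return None
    return int(leaf_of[i0]), int(leaf_of[i1]) + 1


def _project_annotations(dataset: SimulatedDataset) -> None:
    dataset.genes, dataset.crms = {}, {}
    for sp in dataset.phylogeny.species:
        r2l = dataset.root_to_leaf(sp)
        valid = np.flatnonzero(r2l >= 0)
        leaf_of = r2l[valid]
        genes = []
        for g in dataset.genes_root:
            exons = []
            for s, e in g.exons:
                span = _interval_to_leaf(valid, leaf_of, s, e)
                if span is not None:
                    exons.append(span)
            if not exons:
                continue
            genes.append(GeneModel(
                gene_id=g.gene_id, chrom=CHROM, strand=g.strand,
                start=exons[0][0], end=exons[-1][1], exons=tuple(exons)))
        dataset.genes[sp] = genes
        crms = []
        for c in dataset.crms_root:
            span = _interval_to_leaf(valid, leaf_of, c.start, c.end)
            if span is not None:
                crms.append(GenomicInterval(CHROM, span[0], span[1],
                                            name=c.name))
        dataset.crms[sp] = crms


def _build_chains(dataset: SimulatedDataset) -> None:
    species = dataset.phylogeny.species
    r2l = {sp: dataset.root_to_leaf(sp) for sp in species}
    dataset.chains = {}
    for a in species:
        for b in species:
            if a == b:
                continue
            both = (r2l[a] >= 0) & (r2l[b] >= 0)
            pa, pb = r2l[a][both], r2l[b][both]
            if len(pa) == 0:
                dataset.chains[(a, b)] = ChainMap([])
                continue
            breaks = np.flatnonzero((np.diff(pa) != 1) | (np.diff(pb) != 1))
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks + 1, [len(pa)]])
            chain = Chain(
                chain_id=1, score=float(len(pa)),
                src_chrom=CHROM, src_size=len(dataset.genomes[a][CHROM]),
                tgt_chrom=CHROM, tgt_size=len(dataset.genomes[b][CHROM]),
                orientation="+",
                src_starts=pa[starts], tgt_starts=pb[starts],
                sizes=ends - starts)
            dataset.chains[(a, b)] = ChainMap([chain])


# ---------------------------------------------------------------------------
# genome + annotation synthesis
# ---------------------------------------------------------------------------

def simulate_genomes(phylogeny: PhylogenySpec, length: int = 1_000_000,
                     n_genes: int = 110, n_crms: int | None = None,
                     seed: int = 0, gene_length: tuple[int, int] = (4000, 6000),
                     min_gene_gap: int = 2000) -> SimulatedDataset:
    """Ancestral genome with genes and CRMs, evolved along the phylogeny.

    Genes are placed non-overlapping with 2-4 exons; each of the first
    ``n_crms`` genes (default: half of them) receives one 600-bp upstream
    CRM.  Chains and annotations for every species are derived from the
    recorded homology map.
    """
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, size=length, dtype=np.int8)

    gene_lens = rng.integers(gene_length[0], gene_length[1] + 1, size=n_genes)
    need = int(gene_lens.sum()) + (n_genes + 1) * min_gene_gap
    if need > length:
        raise ValueError(
            f"cannot place {n_genes} genes of ~{int(np.mean(gene_length))} bp "
            f"in {length} bp (need >= {need})")
    slack = length - need
    extra = np.sort(rng.integers(0, slack + 1, size=n_genes))
    genes: list[GeneModel] = []
    cursor = min_gene_gap
    prev_extra = 0
    for k in range(n_genes):
        cursor += int(extra[k] - prev_extra)
        prev_extra = int(extra[k])
        start = cursor
        end = start + int(gene_lens[k])
        n_ex = int(rng.integers(2, 5))
        # exon/intron layout: exons of 200-400 bp spread over the span
        bounds = np.sort(rng.choice(
            np.arange(start + 300, end - 300), size=2 * n_ex - 2,
            replace=False))
        edges = [start] + list(map(int, bounds)) + [end]
        exons = tuple((edges[2 * i], edges[2 * i + 1]) for i in range(n_ex)
                      if edges[2 * i] < edges[2 * i + 1])
        if len(exons) < 2:
            exons = ((start, start + 300), (end - 300, end))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gene_id=f"g{k + 1:04d}", chrom=CHROM,
                               strand=strand, start=start, end=end,
                               exons=exons))
        cursor = end + min_gene_gap
    if n_crms is None:
        n_crms = n_genes // 2
    crm_genes = list(rng.permutation(n_genes))[:n_crms]
    crms = [GenomicInterval(CHROM, genes[k].start - 1900,
                            genes[k].start - 1300, name=f"crm_{genes[k].gene_id}")
            for k in sorted(crm_genes) if genes[k].start >= 1900]

    dataset = SimulatedDataset(
        phylogeny=phylogeny, length=length, seed=seed, ancestor=ancestor,
        genes_root=genes, crms_root=crms)
    protected = np.zeros(length, dtype=bool)
    for g in genes:
        for s, e in g.exons:
            protected[s:e] = True
    dataset._evolution_seed = int(rng.integers(2 ** 31))
    dataset._protected_root = protected
    _evolve_tree(dataset, np.ones(length), protected,
                 dataset._evolution_seed)
    return dataset


# ---------------------------------------------------------------------------
# site planting
# ---------------------------------------------------------------------------

def _sample_motif(pwm, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(pwm.probs, axis=1)
    u = rng.random(pwm.width)
    return np.array([np.searchsorted(cum[i], u[i]) for i in range(pwm.width)],
                    dtype=np.int8)


_RC = np.array([3, 2, 1, 0], dtype=np.int8)

SITE_WINDOW = 140      # bp of ancestral sequence holding a site's motifs
ALIGN_FLANK = 80       # bp of flank in emitted per-locus alignments


def plant_sites(dataset: SimulatedDataset, pwm, n_sites: int = 300,
                class_mix: dict[str, float] | None = None,
                factor_mix: dict[str, float] | None = None,
                fold_range: tuple[float, float] = (4.0, 8.0),
                seed: int = 1, crm_probability: float = 0.5,
                binding_drift: float = 1.0) -> SimulationTruth:
    """Write motif clusters into the ancestor and re-evolve the tree.

    Each site is a 140-bp window holding 1-5 motif instances sampled from
    the PWM.  Turnover sites occupy two windows (near the 5' and 3' ends of
    a dedicated gene); per-species binding presence encodes the conservation
    class, and only conserved-class motifs evolve under the constraint
    factor.  Binding strength drifts neutrally along the tree: each branch
    adds an independent N(0, t * binding_drift) increment to every site's
    log enrichment fold, so quantitative binding divergence between two
    species grows with their phylogenetic distance.  Re-planting on a
    dataset replaces earlier truth.
    """
    class_mix = class_mix or {"conserved": 0.5, "unique": 0.3,
                              "turnover": 0.2}
    factor_mix = factor_mix or {"common": 0.4, "Dichaete": 0.3, "SoxN": 0.3}
    for mix in (class_mix, factor_mix):
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("class mix fractions must sum to 1")
    rng = np.random.default_rng(seed)
    species = dataset.phylogeny.species
    length = dataset.length
    ancestor = dataset.ancestor.copy()

    n_by_class = {c: int(round(f * n_sites)) for c, f in class_mix.items()}
    drift = n_sites - sum(n_by_class.values())
    n_by_class["conserved"] += drift
    class_list = [c for c, n in n_by_class.items() for _ in range(n)]
    factor_classes = list(factor_mix)
    factor_list = [factor_classes[int(i)] for i in
                   np.floor(np.linspace(0, len(factor_classes) - 1e-9,
                                        n_sites))]
    rng.shuffle(factor_list)

    gene_order = list(rng.permutation(len(dataset.genes_root)))
    n_turnover = sum(1 for c in class_list if c == "turnover")
    if n_turnover > len(gene_order):
        raise ValueError("not enough genes for turnover sites")
    turnover_genes = gene_order[:n_turnover]
    other_genes = gene_order[n_turnover:]
    crm_by_gene = {c.name.removeprefix("crm_"): c for c in dataset.crms_root}

    occupied: list[tuple[int, int]] = []     # root windows already used

    def free(start: int) -> bool:
        end = start + SITE_WINDOW
        if start < ALIGN_FLANK or end > length - ALIGN_FLANK:
            return False
        return all(end + 1200 <= s or start >= e + 1200
                   for s, e in occupied)

    def place_near(gene: GeneModel) -> int | None:
        crm = crm_by_gene.get(gene.gene_id)
        for _ in range(200):
            if crm is not None and rng.random() < crm_probability:
                lo, hi = crm.start, crm.end - SITE_WINDOW
            else:
                lo, hi = gene.start - 1500, gene.end + 1500 - SITE_WINDOW
            start = int(rng.integers(lo, hi))
            if free(start):
                return start
        return None

    def write_motifs(start: int) -> tuple[tuple[int, ...], list[np.ndarray]]:
        n_inst = int(rng.integers(1, 6))
        offs: list[int] = []
        for _ in range(100):
            if len(offs) >= n_inst:
                break
            o = int(rng.integers(0, SITE_WINDOW - pwm.width))
            if all(abs(o - p) >= pwm.width + 2 for p in offs):
                offs.append(o)
        instances = []
        for o in sorted(offs):
            inst = _sample_motif(pwm, rng)
            if rng.random() < 0.5:
                inst = _RC[inst][::-1]
            ancestor[start + o:start + o + pwm.width] = inst
            instances.append(inst)
        return tuple(start + o for o in sorted(offs)), instances

    sites: list[PlantedSite] = []
    constrained: list[tuple[int, int]] = []
    unique_cycle = 0
    pairs = [(a, b) for i, a in enumerate(species)
             for b in species[i + 1:]]
    pair_cycle = 0
    gene_cycle = 0
    turnover_cursor = 0

    for idx, (cls, fac) in enumerate(zip(class_list, factor_list)):
        fold = float(rng.uniform(*fold_range))
        site_id = f"site{idx + 1:04d}"
        if cls == "turnover":
            gene = dataset.genes_root[turnover_genes[turnover_cursor]]
            turnover_cursor += 1
            pos_a = gene.start + 400
            pos_b = gene.end - 400 - SITE_WINDOW
            if not (free(pos_a) and free(pos_b)) or pos_b - pos_a < 2600:
                continue
            offs_a, _ = write_motifs(pos_a)
            offs_b, _ = write_motifs(pos_b)
            occupied.extend([(pos_a, pos_a + SITE_WINDOW),
                             (pos_b, pos_b + SITE_WINDOW)])
            sp_a, sp_b = pairs[pair_cycle % len(pairs)]
            pair_cycle += 1
            presence = {sp: None for sp in species}
            presence[sp_a] = (pos_a, pos_a + SITE_WINDOW)
            presence[sp_b] = (pos_b, pos_b + SITE_WINDOW)
            sites.append(PlantedSite(
                site_id=site_id, root_start=pos_a,
                root_end=pos_b + SITE_WINDOW, conservation_class=cls,
                factor_class=fac, fold=fold, gene_id=gene.gene_id,
                crm=False, motif_offsets=offs_a + offs_b,
                presence=presence))
            continue
        placed = None
        for attempt in range(len(other_genes)):
            gene = dataset.genes_root[
                other_genes[(gene_cycle + attempt) % len(other_genes)]]
            placed = place_near(gene)
            if placed is not None:
                gene_cycle += attempt + 1
                break
        if placed is None:
            continue
        offs, _ = write_motifs(placed)
        occupied.append((placed, placed + SITE_WINDOW))
        window = (placed, placed + SITE_WINDOW)
        if cls == "conserved":
            presence = {sp: window for sp in species}
            for o in offs:
                constrained.append((o, o + pwm.width))
        else:  # unique
            target = species[unique_cycle % len(species)]
            unique_cycle += 1
            presence = {sp: (window if sp == target else None)
                        for sp in species}
        crm_flag = any(c.start < window[1] and window[0] < c.end
                       for c in dataset.crms_root)
        sites.append(PlantedSite(
            site_id=site_id, root_start=window[0], root_end=window[1],
            conservation_class=cls, factor_class=fac, fold=fold,
            gene_id=gene.gene_id, crm=crm_flag, motif_offsets=offs,
            presence=presence))

    dataset.ancestor = ancestor
    factor_root = np.ones(length)
    for s, e in constrained:
        factor_root[s:e] = dataset.phylogeny.constraint_factor
    protected = dataset._protected_root.copy()
    for site in sites:
        for sp, window in site.presence.items():
            if window is not None:
                protected[window[0]:window[1]] = True
    _evolve_tree(dataset, factor_root, protected, dataset._evolution_seed)

    # per-species coordinates of each presence window
    for sp in species:
        r2l = dataset.root_to_leaf(sp)
        valid = np.flatnonzero(r2l >= 0)
        leaf_of = r2l[valid]
        for site in sites:
            window = site.presence[sp]
            if window is not None:
                site.presence[sp] = _interval_to_leaf(valid, leaf_of,
                                                      window[0], window[1])

    # Brownian drift of log binding strength along the tree
    base_fold = np.array([s.fold for s in sites])

    def drift(node: TreeNode, acc: np.ndarray) -> None:
        if node.length > 0 and binding_drift > 0:
            acc = acc + rng.normal(
                0.0, np.sqrt(node.length * binding_drift), size=len(sites))
        if node.is_leaf:
            folds = np.maximum(1.0, base_fold * np.exp(acc))
            for site, f in zip(sites, folds):
                site.fold_by_species[node.name] = float(f)
        for ch in node.children:
            drift(ch, acc)

    drift(dataset.phylogeny.root, np.zeros(len(sites)))

    truth = SimulationTruth(sites=sites, seed=seed)
    dataset.truth = truth
    _build_alignments(dataset)
    return truth


def _build_alignments(dataset: SimulatedDataset) -> None:
    """True per-site-locus alignments from the recorded homology maps.

    Columns cover every root position of the locus; bases inserted on a
    lineage get private columns (gap in all other species), placed after
    their anchoring root position.
    """
    species = dataset.phylogeny.species
    leafs = {sp: dataset.leaf_root_pos[sp] for sp in species}
    genomes = {sp: dataset.genomes[sp][CHROM] for sp in species}
    r2l = {sp: dataset.root_to_leaf(sp) for sp in species}
    # insertion bases keyed by (species, anchor root position)
    inserts: dict[str, dict[int, list[int]]] = {sp: {} for sp in species}
    for sp in species:
        rp = leafs[sp]
        anchor = -1
        for i, r in enumerate(rp):
            if r >= 0:
                anchor = r
            else:
                inserts[sp].setdefault(anchor, []).append(i)
    dataset.alignments = {}
    for site in dataset.truth.sites:
        lo = max(0, site.root_start - ALIGN_FLANK)
        hi = min(dataset.length, site.root_end + ALIGN_FLANK)
        rows = {sp: [] for sp in species}
        for r in range(lo, hi):
            for sp in species:
                leaf = r2l[sp][r]
                rows[sp].append(genomes[sp][leaf] if leaf >= 0 else "-")
            for sp in species:
                ins = inserts[sp].get(r)
                if ins:
                    for other in species:
                        if other == sp:
                            rows[other].extend(genomes[sp][i] for i in ins)
                        else:
                            rows[other].extend("-" * len(ins))
        aligned = {sp: "".join(chars) for sp, chars in rows.items()}
        if all(set(row) == {"-"} for row in aligned.values()):
            continue
        dataset.alignments[site.site_id] = MultipleAlignment(
            aligned, name=site.site_id)


# ---------------------------------------------------------------------------
# DamID read simulation
# ---------------------------------------------------------------------------

READ_LENGTH = 50


def simulate_damid_reads(dataset: SimulatedDataset, factor: str = "Dichaete",
                         depth: int = 200_000, replicates: int = 3,
                         dispersion: float = 0.1,
                         background_rate: float = 1.0,
                         spread: int = 500, seed: int = 2
                         ) -> dict[str, list[SampleReads]]:
    """Draw fusion and Dam-only replicate read sets for every species.

    Fragment intensity: background * (1 + (fold-1) * k(d)) with the
    triangular kernel k(d) = max(0, 1 - d/spread), d the distance from the
    fragment midpoint to the nearest present site of the factor (common
    sites feed both factors).  Per-fragment counts are negative binomial
    with the given dispersion, scaled to the sample depth; reads are placed
    uniformly within their fragment (length 50, random strand).
    """
    if spread <= 0:
        raise ValueError("spread must be positive")
    if depth < 10_000:
        raise ValueError("depth below the supported minimum (10,000)")
    if dataset.truth is None:
        raise ValueError("plant sites before simulating reads")
    rng = np.random.default_rng(seed)
    out: dict[str, list[SampleReads]] = {}
    for sp in dataset.phylogeny.species:
        genome = dataset.genomes[sp]
        frag_map = build_gatc_fragment_map(genome)
        starts = frag_map.starts[CHROM]
        ends = frag_map.ends(CHROM)
        mids = (starts + ends) // 2
        site_pos = []
        folds = []
        for site in dataset.truth.sites:
            if site.factor_class not in (factor, "common"):
                continue
            window = site.presence[sp]
            if window is None:
                continue
            site_pos.append((window[0] + window[1]) // 2)
            folds.append(site.species_fold(sp))
        weight_bg = background_rate * (ends - starts).astype(float)
        enrich = np.ones(len(mids))
        for pos, fold in zip(site_pos, folds):
            d = np.abs(mids - pos)
            k = np.maximum(0.0, 1.0 - d / spread)
            enrich = np.maximum(enrich, 1.0 + (fold - 1.0) * k)
        samples: list[SampleReads] = []
        for condition, weight in (("fusion", weight_bg * enrich),
                                  ("control", weight_bg)):
            mu_base = depth * weight / weight.sum()
            for rep in range(1, replicates + 1):
                if dispersion > 0:
                    lam = rng.gamma(1.0 / dispersion,
                                    dispersion * mu_base)
                else:
                    lam = mu_base
                counts = rng.poisson(lam)
                total = int(counts.sum())
                frag_idx = np.repeat(np.arange(len(counts)), counts)
                span = (ends - starts)[frag_idx]
                pos = starts[frag_idx] + np.floor(
                    rng.random(total) * span).astype(np.int64)
                read_ends = np.minimum(pos + READ_LENGTH,
                                       genome.lengths[CHROM])
                strands = np.where(rng.random(total) < 0.5, "+", "-")
                reads = [GenomicInterval(CHROM, int(s), int(e), str(st))
                         for s, e, st in zip(pos, read_ends, strands)]
                fac = factor if condition == "fusion" else "none"
                samples.append(SampleReads(
                    label=f"{sp}_{factor}_{condition}_r{rep}",
                    condition=condition, factor=fac, replicate=rep,
                    species=sp, reads=reads))
        out[sp] = samples
    key = factor
    dataset.samples.setdefault(key, [])
    dataset.samples[key] = [s for sps in out.values() for s in sps]
    dataset.read_params[key] = {
        "depth": depth, "replicates": replicates, "dispersion": dispersion,
        "background_rate": background_rate, "spread": spread, "seed": seed}
    return out


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------

def emit_dataset(dataset: SimulatedDataset, out_dir: str | os.PathLike
                 ) -> None:
    """Write FASTA/GFF3/chain/BED/alignment files plus truth and manifest."""
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    for sp, genome in dataset.genomes.items():
        write_fasta(genome, os.path.join(out_dir, f"{sp}.fa"))
        write_gff_genes(dataset.genes[sp],
                        os.path.join(out_dir, f"{sp}.gff3"))
        write_intervals(dataset.crms[sp],
                        os.path.join(out_dir, f"{sp}.crms.bed"),
                        dialect="BED6")
    for (a, b), chain_map in dataset.chains.items():
        write_chain(chain_map, os.path.join(out_dir, f"{a}_to_{b}.chain"))
    aln_dir = os.path.join(out_dir, "alignments")
    os.makedirs(aln_dir, exist_ok=True)
    for site_id, aln in dataset.alignments.items():
        write_alignment(aln, os.path.join(aln_dir, f"{site_id}.afa"))
    for factor, samples in dataset.samples.items():
        for sample in samples:
            write_intervals(sample.reads,
                            os.path.join(out_dir, f"{sample.label}.bed"),
                            dialect="BED6")
    if dataset.truth is not None:
        with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
            species = dataset.phylogeny.species
            cols = ["site_id", "conservation_class", "factor_class", "fold",
                    "gene_id", "crm", "root_start", "root_end",
                    "motif_offsets"]
            cols += [f"pos_{sp}" for sp in species]
            fh.write("\t".join(cols) + "\n")
            for s in dataset.truth.sites:
                row = [s.site_id, s.conservation_class, s.factor_class,
                       f"{s.fold:.3f}", s.gene_id, str(int(s.crm)),
                       str(s.root_start), str(s.root_end),
                       ",".join(map(str, s.motif_offsets))]
                for sp in species:
                    pos = s.presence[sp]
                    row.append("." if pos is None else f"{pos[0]}-{pos[1]}")
                fh.write("\t".join(row) + "\n")
    manifest = {
        "seed": dataset.seed,
        "length": dataset.length,
        "species": dataset.phylogeny.species,
        "n_genes": len(dataset.genes_root),
        "n_crms": len(dataset.crms_root),
        "n_sites": 0 if dataset.truth is None else len(dataset.truth.sites),
        "read_params": dataset.read_params,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
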