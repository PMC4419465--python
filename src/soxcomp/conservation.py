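"""Cross-species conservation of binding intervals, gene/feature annotation,
compensatory turnover detection and conservation-by-category contingency tests.

Conservation is single-linkage: an interval counts as shared with another
species when it overlaps that species' translated interval set by >= 1 bp.
Category distributions use union accounting: intervals from different species
that overlap each other are merged into one representative, so percentages are
over "all intervals identified across species".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_core import GeneModel, GenomicInterval, merge_intervals


@dataclass
class ConservationRecord:
    interval: GenomicInterval
    species: frozenset[str]
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def category(self) -> int:
        """Number of species the interval is observed in (1 = unique)."""
        return len(self.species)


@dataclass
class TurnoverEvent:
    gene_id: str
    species_a: str
    species_b: str
    intervals_a: tuple[GenomicInterval, ...]
    intervals_b: tuple[GenomicInterval, ...]


@dataclass
class ContingencyResult:
    table: np.ndarray
    chi2: float
    dof: int
    pvalue: float
    warning: str | None = None


@dataclass
class FeatureAnnotation:
    interval: GenomicInterval
    gene_id: str | None
    distance: int | None            # to gene span; 0 iff overlapping
    tss_distance: int | None
    feature: str                    # promoter / exon / intron / intergenic
    intron_rank: int | None = None
    tie: bool = False


# ---------------------------------------------------------------------------
# interval overlap machinery
# ---------------------------------------------------------------------------

def overlaps_any(queries: list[GenomicInterval],
                 subjects: list[GenomicInterval],
                 min_overlap: int = 1) -> np.ndarray:
    """Per-query flag: does it share >= min_overlap bases with any subject?

    Sweep over sorted subject arrays per chromosome with searchsorted; the
    unit tests pin this against the brute-force double loop.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    subj_sorted: dict[str, list[GenomicInterval]] = {}
    for iv in subjects:
        subj_sorted.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in subj_sorted.items():
        ivs.sort(key=lambda x: x.start)
        starts = np.fromiter((i.start for i in ivs), dtype=np.int64)
        ends = np.fromiter((i.end for i in ivs), dtype=np.int64)
        # running maximum of ends makes the scan correct for nested intervals
        by_chrom[chrom] = (starts, np.maximum.accumulate(ends))
    out = np.zeros(len(queries), dtype=bool)
    for qi, q in enumerate(queries):
        if q.chrom not in by_chrom:
            continue
        starts, max_ends = by_chrom[q.chrom]
        # subjects with start <= q.end - min_overlap
        hi = np.searchsorted(starts, q.end - min_overlap, side="right")
        if hi == 0:
            continue
        # require some subject among [0, hi) with end >= q.start + min_overlap
        if max_ends[hi - 1] >= q.start + min_overlap:
            # cheap prefilter passed; verify against individual ends
            lo_ends = max_ends[:hi]
            out[qi] = bool(np.any(lo_ends >= q.start + min_overlap))
    return out


def overlap_matrix(queries: list[GenomicInterval],
                   subject_sets: dict[str, list[GenomicInterval]]
                   ) -> dict[str, np.ndarray]:
    return {name: overlaps_any(queries, ivs)
            for name, ivs in subject_sets.items()}


# ---------------------------------------------------------------------------
# conservation classification
# ---------------------------------------------------------------------------

def classify_conservation(interval_sets: dict[str, list[GenomicInterval]]
                          ) -> list[ConservationRecord]:
    """Union-accounted conservation categories over all species' intervals.

    ``interval_sets`` maps species label to its intervals, all expressed on a
    common reference coordinate system (the reference species' own calls plus
    translated calls of the others).  Overlapping intervals across species are
    merged into representatives; each representative's species set lists every
    species with an overlapping interval.
    """
    pooled = [iv for ivs in interval_sets.values() for iv in ivs]
    chrom_sets = {sp: {iv.chrom for iv in ivs}
                  for sp, ivs in interval_sets.items()}
    for sp, chroms in chrom_sets.items():
        others = set().union(*(c for s, c in chrom_sets.items() if s != sp))
        if chroms and others and not (chroms & others):
            warnings.warn(f"interval set {sp!r} lies on mismatched "
                          "chromosomes; treated as non-overlapping")
    representatives = merge_intervals(pooled, gap=0)
    records = []
    per_species = {sp: overlaps_any(representatives, ivs)
                   for sp, ivs in interval_sets.items()}
    for i, rep in enumerate(representatives):
        present = frozenset(sp for sp in interval_sets if per_species[sp][i])
        records.append(ConservationRecord(interval=rep, species=present))
    return records


def category_distribution(records: list[ConservationRecord]
                          ) -> dict[int, float]:
    """Fraction of representatives per category; fractions sum to 1."""
    n = len(records)
    counts: dict[int, int] = {}
    for rec in records:
        counts[rec.category] = counts.get(rec.category, 0) + 1
    return {k: v / n for k, v in sorted(counts.items())}


# ---------------------------------------------------------------------------
# gene and feature annotation
# ---------------------------------------------------------------------------

def _gene_distance(iv: GenomicInterval, gene: GeneModel) -> int:
    if iv.chrom != gene.chrom:
        return -1
    if iv.start < gene.end and gene.start < iv.end:
        return 0
    return gene.start - iv.end + 1 if gene.start >= iv.end \
        else iv.start - gene.end + 1


def annotate_nearest_gene(intervals: list[GenomicInterval],
                          genes: list[GeneModel]) -> list[FeatureAnnotation]:
    """Assign each interval to its closest gene (ties: lexicographic id)."""
    if not genes:
        raise ValueError("gene list is empty")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    annotations = []
    for iv in intervals:
        candidates = by_chrom.get(iv.chrom, [])
        if not candidates:
            annotations.append(FeatureAnnotation(
                interval=iv, gene_id=None, distance=None, tss_distance=None,
                feature="unannotated"))
            continue
        dists = [( _gene_distance(iv, g), g.gene_id, g) for g in candidates]
        dists.sort(key=lambda x: (x[0], x[1]))
        best_d, _, best_g = dists[0]
        tie = len(dists) > 1 and dists[1][0] == best_d
        tss = best_g.tss
        tss_dist = 0 if iv.start <= tss < iv.end else \
            min(abs(tss - (iv.end - 1)), abs(tss - iv.start))
        annotations.append(FeatureAnnotation(
            interval=iv, gene_id=best_g.gene_id, distance=best_d,
            tss_distance=tss_dist, feature="", tie=tie))
    return annotations


def annotate_features(intervals: list[GenomicInterval],
                      genes: list[GeneModel],
                      promoter_upstream: int = 2000,
                      promoter_downstream: int = 500
                      ) -> list[FeatureAnnotation]:
    """Assign promoter/exon/intron/intergenic by interval midpoint.

    Precedence promoter > exon > intron > intergenic across all genes; the
    promoter window is [TSS - upstream, TSS + downstream) in transcription
    orientation.  Intronic intervals get the rank of the containing intron.
    """
    annotations = annotate_nearest_gene(intervals, genes)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for ann in annotations:
        iv = ann.interval
        mid = iv.midpoint
        feature, rank = "intergenic", None
        in_exon = False
        intron_hits: list[tuple[str, int]] = []
        for g in by_chrom.get(iv.chrom, []):
            tss = g.tss
            if g.strand == "+":
                prom = (tss - promoter_upstream, tss + promoter_downstream)
            else:
                prom = (tss - promoter_downstream + 1, tss + promoter_upstream + 1)
            if prom[0] <= mid < prom[1]:
                feature = "promoter"
                break
            if any(s <= mid < e for s, e in g.exons):
                in_exon = True
                continue
            for s, e, r in g.introns:
                if s <= mid < e:
                    intron_hits.append((g.gene_id, r))
        if feature != "promoter":
            if in_exon:
                feature = "exon"
            elif intron_hits:
                feature = "intron"
                rank = sorted(intron_hits)[0][1]
        ann.feature = feature
        ann.intron_rank = rank
    return annotations


def intron_rank_enrichment(annotations: list[FeatureAnnotation],
                           genes: list[GeneModel]) -> ContingencyResult:
    """First-intron enrichment of intronic intervals vs a length expectation.

    Expected rank-1 hits are proportional to the total genomic length of
    rank-1 vs higher-rank introns; one-degree chi-squared, with an exact
    binomial when expected counts are small.
    """
    intronic = [a for a in annotations if a.feature == "intron"]
    if not intronic:
        raise ValueError("no intronic intervals; enrichment untestable")
    len_rank1 = sum(e - s for g in genes for s, e, r in g.introns if r == 1)
    len_higher = sum(e - s for g in genes for s, e, r in g.introns if r > 1)
    if len_rank1 == 0 or len_higher == 0:
        raise ValueError("degenerate intron length distribution")
    p1 = len_rank1 / (len_rank1 + len_higher)
    n = len(intronic)
    obs1 = sum(1 for a in intronic if a.intron_rank == 1)
    expected = np.array([n * p1, n * (1 - p1)])
    observed = np.array([obs1, n - obs1])
    if expected.min() < 5:
        p = stats.binomtest(obs1, n, p1).pvalue
        chi2 = np.nan
        warning = "small-sample binomial path"
    else:
        chi2 = float((((observed - expected) ** 2) / expected).sum())
        p = float(stats.chi2.sf(chi2, df=1))
        warning = None
    return ContingencyResult(table=np.vstack([observed, expected]),
                             chi2=chi2, dof=1, pvalue=float(p),
                             warning=warning)


# ---------------------------------------------------------------------------
# turnover and contingency tests
# ---------------------------------------------------------------------------

def detect_turnover(annotations_a: list[FeatureAnnotation],
                    annotations_b: list[FeatureAnnotation],
                    species_a: str = "A", species_b: str = "B"
                    ) -> list[TurnoverEvent]:
    """Compensatory turnover: same gene, zero positional overlap.

    Both annotation lists must be against the same reference gene models,
    with species B's intervals already translated to the reference.  A gene
    with intervals in both species yields an event only when no A interval
    overlaps any B interval there; any overlap cancels the event.
    """
    genes_a: dict[str, list[GenomicInterval]] = {}
    genes_b: dict[str, list[GenomicInterval]] = {}
    for ann in annotations_a:
        if ann.gene_id is not None:
            genes_a.setdefault(ann.gene_id, []).append(ann.interval)
    for ann in annotations_b:
        if ann.gene_id is not None:
            genes_b.setdefault(ann.gene_id, []).append(ann.interval)
    events = []
    for gene_id in sorted(set(genes_a) & set(genes_b)):
        ivs_a, ivs_b = genes_a[gene_id], genes_b[gene_id]
        if not overlaps_any(ivs_a, ivs_b).any():
            events.append(TurnoverEvent(
                gene_id=gene_id, species_a=species_a, species_b=species_b,
                intervals_a=tuple(ivs_a), intervals_b=tuple(ivs_b)))
    return events


def pearson_chi2(table: np.ndarray) -> ContingencyResult:
    """Pearson chi-squared test of independence on an r x c count table."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("negative counts")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("degenerate table: empty row or column")
    expected = row @ col / total
    chi2 = float(((table - expected) ** 2 / expected).sum())
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    warning = ("expected counts < 5" if (expected < 5).any() else None)
    if warning:
        warnings.warn("contingency table has expected counts < 5")
    return ContingencyResult(table=table, chi2=chi2, dof=dof,
                             pvalue=float(stats.chi2.sf(chi2, df=dof)),
                             warning=warning)


def conservation_by_category(records: list[ConservationRecord],
                             flag: str) -> ContingencyResult:
    """Cross-tabulate conservation category against a boolean flag."""
    categories = sorted({rec.category for rec in records})
    if any(flag not in rec.flags for rec in records):
        raise ValueError(f"flag {flag!r} missing on some records")
    table = np.zeros((2, len(categories)), dtype=float)
    for rec in records:
        row = 0 if rec.flags[flag] else 1
        table[row, categories.index(rec.category)] += 1
    return pearson_chi2(table)


def common_unique_analysis(
        factor1_sets: dict[str, list[GenomicInterval]],
        factor2_sets: dict[str, list[GenomicInterval]],
        translated_other: dict[str, dict[str, list[GenomicInterval]]],
        factor1: str = "Dichaete", factor2: str = "SoxN"):
    """Common vs factor-unique binding and per-class conservation rates.

    For each species, representatives are the merged union of both factors'
    intervals; a representative overlapped by both factors is 'common',
    otherwise unique to the overlapping factor.  ``translated_other[sp]``
    carries the *other* species' factor interval sets translated onto
    ``sp``'s coordinates; per-class conservation is the fraction of class
    members overlapping the other species' same-class union.  Returns
    (per-species result dict, chi-squared per species).
    """
    if set(factor1_sets) != set(factor2_sets) or len(factor1_sets) < 2:
        raise ValueError("both factors must be called in >= 2 shared species")
    classes = ("common", f"unique_{factor1}", f"unique_{factor2}")

    def classify(sp, f1, f2):
        reps = merge_intervals(f1 + f2, gap=0)
        has1 = overlaps_any(reps, f1)
        has2 = overlaps_any(reps, f2)
        labels = np.where(has1 & has2, "common",
                          np.where(has1, f"unique_{factor1}",
                                   f"unique_{factor2}"))
        return reps, labels

    partition = {sp: classify(sp, factor1_sets[sp], factor2_sets[sp])
                 for sp in factor1_sets}
    results, tests = {}, {}
    for sp in factor1_sets:
        reps, labels = partition[sp]
        other = translated_other.get(sp)
        if other is None:
            continue
        o_reps, o_labels = classify(sp, other[factor1], other[factor2])
        rates = {}
        table = np.zeros((len(classes), 2))
        for ci, cls in enumerate(classes):
            members = [reps[i] for i in np.flatnonzero(labels == cls)]
            target = [o_reps[i] for i in np.flatnonzero(o_labels == cls)]
            if members:
                conserved = overlaps_any(members, target)
                rates[cls] = float(conserved.mean())
                table[ci] = [conserved.sum(), len(members) - conserved.sum()]
            else:
                rates[cls] = np.nan
        results[sp] = {"classes": dict(zip(classes,
                                           [int((labels == c).sum())
                                            for c in classes])),
                       "conservation_rates": rates}
        keep = table.sum(axis=1) > 0
        try:
            tests[sp] = pearson_chi2(table[keep]) if keep.sum() >= 2 else None
        except ValueError:  # all members of every class conserved (or none)
            tests[sp] = None
    return results, tests


def map_targets_via_orthologs(gene_set: set[str],
                              ortholog_pairs: list[tuple[str, str]],
                              reference_set: set[str] | None = None):
    """Image of a gene set under a (many-to-many) ortholog mapping.

    Returns (mapped set, number of genes without orthologs, overlap with the
    reference set or None).
    """
    mapping: dict[str, set[str]] = {}
    for src, dst in ortholog_pairs:
        mapping.setdefault(src, set()).add(dst)
    if not mapping:
        warnings.warn("empty ortholog mapping; image is empty")
    image: set[str] = set()
    dropped = 0
    for g in gene_set:
        if g in mapping:
            image |= mapping[g]
        else:
            dropped += 1
    overlap = len(image & reference_set) if reference_set is not None else None
    return image, dropped, overlap
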