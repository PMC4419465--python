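"""Jointly normalized quantitative comparison of binding across samples.

All samples' reads are counted in a shared consensus interval set and
normalized together with median-of-ratios size factors, which avoids the
under-estimation of similarity that comes from comparing separately
thresholded per-sample calls.  Affinity = log2(count / size factor + 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .enrichment import (bh_adjust, estimate_size_factors, _irls_two_group,
                         estimate_dispersions)
from .gatc_quant import SampleReads, extend_reads
from .io_core import GenomicInterval, merge_intervals


@dataclass
class AffinityMatrix:
    consensus: list[GenomicInterval]
    counts: np.ndarray              # intervals x samples, raw
    affinities: np.ndarray          # intervals x samples, log2 normalized
    size_factors: np.ndarray
    metadata: pd.DataFrame


@dataclass
class DifferentialBindingResult:
    consensus: list[GenomicInterval]
    log2_fold_change: np.ndarray
    pvalue: np.ndarray
    padj: np.ndarray
    significant: np.ndarray
    preferred_group: np.ndarray     # group label or '' per interval
    divergence_class: np.ndarray    # 'quantitative'/'qualitative'/'' per interval
    fdr_level: float


def build_consensus(interval_sets: list[list[GenomicInterval]],
                    min_occupancy: int = 2) -> list[GenomicInterval]:
    """Merged union of all sets, keeping regions supported by enough sets."""
    if len(interval_sets) < 2:
        raise ValueError("need >= 2 interval sets for a consensus")
    pooled = [iv for ivs in interval_sets for iv in ivs]
    merged = merge_intervals(pooled, gap=0)
    from .conservation import overlaps_any
    support = np.zeros(len(merged), dtype=int)
    for ivs in interval_sets:
        support += overlaps_any(merged, ivs)
    return [m for m, s in zip(merged, support) if s >= min_occupancy]


def count_reads_in_intervals(intervals: list[GenomicInterval],
                             reads: list[GenomicInterval]) -> np.ndarray:
    """Reads overlapping each (disjoint, sorted-per-chromosome) interval."""
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append((i, iv))
    arrays = {}
    for chrom, items in by_chrom.items():
        items.sort(key=lambda x: x[1].start)
        arrays[chrom] = (
            np.fromiter((iv.start for _, iv in items), dtype=np.int64),
            np.fromiter((iv.end for _, iv in items), dtype=np.int64),
            np.fromiter((i for i, _ in items), dtype=np.int64))
    counts = np.zeros(len(intervals), dtype=np.int64)
    reads_by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in reads:
        reads_by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in reads_by_chrom.items():
        if chrom not in arrays:
            continue
        starts, ends, idx = arrays[chrom]
        r_start = np.fromiter((r.start for r in rs), dtype=np.int64)
        r_end = np.fromiter((r.end for r in rs), dtype=np.int64)
        lo = np.searchsorted(ends, r_start, side="right")
        hi = np.searchsorted(starts, r_end, side="left")
        # read overlaps intervals lo..hi-1
        n_int = len(starts)
        diff = np.zeros(n_int + 1, dtype=np.int64)
        valid = hi > lo
        np.add.at(diff, lo[valid], 1)
        np.add.at(diff, hi[valid], -1)
        counts[idx] += np.cumsum(diff[:-1])
    return counts


def build_affinity_matrix(consensus: list[GenomicInterval],
                          samples: list[SampleReads],
                          chrom_lengths: dict[str, int],
                          extension_length: int = 200) -> AffinityMatrix:
    """Count extended reads per consensus interval and normalize jointly."""
    if not consensus:
        raise ValueError("empty consensus")
    if len(samples) < 2:
        raise ValueError("need >= 2 samples")
    cols = []
    for sample in samples:
        extended = extend_reads(sample, extension_length, chrom_lengths)
        cols.append(count_reads_in_intervals(consensus, extended))
    counts = np.column_stack(cols)
    size_factors = estimate_size_factors(counts)
    affinities = np.log2(counts / size_factors[None, :] + 0.5)
    metadata = pd.DataFrame({
        "label": [s.label for s in samples],
        "condition": [s.condition for s in samples],
        "factor": [s.factor for s in samples],
        "species": [s.species for s in samples],
        "replicate": [s.replicate for s in samples],
    })
    return AffinityMatrix(consensus=consensus, counts=counts,
                          affinities=affinities, size_factors=size_factors,
                          metadata=metadata)


def correlation_and_cluster(matrix: AffinityMatrix):
    """Pairwise Pearson correlations and average-linkage leaf order."""
    aff = matrix.affinities
    if aff.shape[0] < 2 or aff.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 intervals")
    sd = aff.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance sample column; correlation undefined")
    corr = np.corrcoef(aff, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    linkage = hierarchy.linkage(squareform(dist, checks=False),
                                method="average")
    order = list(hierarchy.leaves_list(linkage))
    labels = matrix.metadata["label"].tolist()
    return corr, [labels[i] for i in order], linkage


def pca_samples(matrix: AffinityMatrix):
    """Sample coordinates on principal components via SVD.

    Intervals (features) are centered; the sign of each component is fixed so
    the largest-magnitude sample loading is positive.  Returns (coordinates
    samples x components, variance-explained fractions).
    """
    aff = matrix.affinities.T            # samples x intervals
    if aff.shape[0] < 3:
        raise ValueError("need >= 3 samples for a PCA")
    centered = aff - aff.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("constant matrix: no principal components")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    coords = u * s[None, :]
    for k in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    var = s ** 2
    explained = var / var.sum() if var.sum() > 0 else var
    return coords, explained


def differential_binding(matrix: AffinityMatrix, group_labels: np.ndarray,
                         group_a: str, group_b: str,
                         fdr_level: float = 0.01,
                         native_calls: dict[str, list[GenomicInterval]]
                         | None = None) -> DifferentialBindingResult:
    """Two-group NB Wald test on consensus-interval counts.

    ``group_labels`` assigns each sample column to a group; only columns in
    ``group_a``/``group_b`` enter the contrast (log2FC is a minus b).  A
    significant interval is 'quantitative' when it overlaps a native called
    interval in both groups' species and 'qualitative' when in exactly one
    (requires ``native_calls`` keyed by group label).
    """
    group_labels = np.asarray(group_labels)
    sel = np.isin(group_labels, [group_a, group_b])
    counts = matrix.counts[:, sel]
    labels = group_labels[sel]
    for g in (group_a, group_b):
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} is unreplicated")
    x = (labels == group_a).astype(float)
    size_factors = matrix.size_factors[sel]
    conditions = np.where(labels == group_a, "fusion", "control")
    dispersions = estimate_dispersions(counts, size_factors, conditions)
    b0, b1, se_b1, converged = _irls_two_group(
        counts.astype(float), np.log(size_factors), x, dispersions)
    from scipy import stats
    log2fc = b1 / np.log(2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pvalue = 2.0 * stats.norm.sf(np.abs(b1 / se_b1))
    pvalue[~converged] = 1.0
    tested = counts.sum(axis=1) > 0
    pvalue[~tested] = np.nan
    padj = np.full_like(pvalue, np.nan)
    padj[tested] = bh_adjust(pvalue[tested])
    with np.errstate(invalid="ignore"):
        significant = tested & (padj < fdr_level)
    preferred = np.where(significant,
                         np.where(log2fc > 0, group_a, group_b), "")

    divergence = np.array([""] * len(padj), dtype=object)
    if native_calls is not None:
        from .conservation import overlaps_any
        in_a = overlaps_any(matrix.consensus, native_calls[group_a])
        in_b = overlaps_any(matrix.consensus, native_calls[group_b])
        divergence[significant & in_a & in_b] = "quantitative"
        divergence[significant & (in_a ^ in_b)] = "qualitative"
    return DifferentialBindingResult(
        consensus=matrix.consensus, log2_fold_change=log2fc,
        pvalue=pvalue, padj=padj, significant=significant,
        preferred_group=preferred, divergence_class=divergence,
        fdr_level=fdr_level)
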