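"""Interval and read translation between genomes through alignment chains.

The mapped fraction of an interval is the share of its bases lying inside a
chain's ungapped blocks.  A translation is accepted only when exactly one
chain reaches the minMatch fraction; two or more qualifying chains mean the
record is ambiguous and is rejected ("multiple outputs not permitted"), and
none means below_minMatch (or no_chain if no chain even overlaps).  The
mapped target is the enclosing span of the mapped pieces, as standard
region-level liftover reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gatc_quant import SampleReads
from .io_core import Chain, ChainMap, GenomicInterval

STATUS_MAPPED = "mapped"
STATUS_BELOW = "below_minMatch"
STATUS_MULTIPLE = "multiple_chains"
STATUS_NONE = "no_chain"


@dataclass
class MappingReportEntry:
    interval: GenomicInterval
    status: str
    mapped_fraction: float = 0.0
    target: GenomicInterval | None = None
    chain_id: int | None = None


def _mapped_bases(chain: Chain, start: int, end: int) -> int:
    """Bases of [start, end) inside the chain's ungapped source blocks."""
    s, z = chain.src_starts, chain.sizes
    lo = np.maximum(s, start)
    hi = np.minimum(s + z, end)
    return int(np.maximum(hi - lo, 0).sum())


def _map_span(chain: Chain, start: int, end: int
              ) -> tuple[int, int] | None:
    """Forward-strand target span covering all mapped bases of [start, end)."""
    s, t, z = chain.src_starts, chain.tgt_starts, chain.sizes
    lo = np.maximum(s, start)
    hi = np.minimum(s + z, end)
    hit = hi > lo
    if not hit.any():
        return None
    if chain.orientation == "+":
        tgt_lo = t[hit] + (lo[hit] - s[hit])
        tgt_hi = t[hit] + (hi[hit] - s[hit])
    else:
        # source s0+k pairs with forward target t0+size-1-k
        tgt_hi = t[hit] + (s[hit] + z[hit] - lo[hit])
        tgt_lo = t[hit] + (s[hit] + z[hit] - hi[hit])
    return int(tgt_lo.min()), int(tgt_hi.max())


def translate_interval(interval: GenomicInterval, chains: ChainMap,
                       min_match: float = 0.7) -> MappingReportEntry:
    """Translate one interval; see module docstring for the decision rule."""
    if not 0 < min_match <= 1:
        raise ValueError("minMatch must lie in (0, 1]")
    overlapping = []
    for chain in chains.for_source(interval.chrom):
        span_lo, span_hi = int(chain.src_starts[0]), chain.src_end
        if interval.end <= span_lo or interval.start >= span_hi:
            continue
        frac = _mapped_bases(chain, interval.start, interval.end) / len(interval)
        overlapping.append((chain, frac))
    if not overlapping:
        return MappingReportEntry(interval, STATUS_NONE)
    candidates = [(c, f) for c, f in overlapping if f > 0 and f >= min_match]
    if not candidates:
        best = max(f for _, f in overlapping)
        return MappingReportEntry(interval, STATUS_BELOW, mapped_fraction=best)
    if len(candidates) > 1:
        best = max(f for _, f in candidates)
        return MappingReportEntry(interval, STATUS_MULTIPLE,
                                  mapped_fraction=best)
    chain, frac = candidates[0]
    span = _map_span(chain, interval.start, interval.end)
    assert span is not None
    strand = interval.strand
    if strand in "+-" and chain.orientation == "-":
        strand = "-" if strand == "+" else "+"
    target = GenomicInterval(chain.tgt_chrom, span[0], span[1], strand,
                             score=interval.score, name=interval.name)
    return MappingReportEntry(interval, STATUS_MAPPED, mapped_fraction=frac,
                              target=target, chain_id=chain.chain_id)


def translate_intervals(intervals, chains: ChainMap, min_match: float = 0.7
                        ) -> list[MappingReportEntry]:
    return [translate_interval(iv, chains, min_match) for iv in intervals]


def _translate_reads_one_chain(chain: Chain, starts: np.ndarray,
                               ends: np.ndarray):
    """Vectorized per-read mapped fraction and target span for one chain."""
    s, t, z = chain.src_starts, chain.tgt_starts, chain.sizes
    block_ends = s + z
    cum = np.concatenate([[0], np.cumsum(z)])

    def aligned_before(x: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(s, x, side="right") - 1
        base = cum[np.maximum(idx, 0)]
        within = np.clip(x - s[np.maximum(idx, 0)], 0, z[np.maximum(idx, 0)])
        return np.where(idx >= 0, base + within, 0)

    mapped = aligned_before(ends) - aligned_before(starts)

    # first mapped base >= start and last mapped base < end
    i0 = np.searchsorted(block_ends, starts, side="right")
    first = np.maximum(starts, s[np.minimum(i0, len(s) - 1)])
    i1 = np.searchsorted(s, ends, side="left") - 1
    last = np.minimum(ends - 1, block_ends[np.maximum(i1, 0)] - 1)

    def map_pos(x: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(s, x, side="right") - 1, 0, len(s) - 1)
        if chain.orientation == "+":
            return t[idx] + (x - s[idx])
        return t[idx] + (s[idx] + z[idx] - 1 - x)

    p_first, p_last = map_pos(first), map_pos(last)
    tgt_start = np.minimum(p_first, p_last)
    tgt_end = np.maximum(p_first, p_last) + 1
    return mapped, tgt_start, tgt_end


def translate_reads(sample: SampleReads, chains: ChainMap,
                    min_match: float = 0.7
                    ) -> tuple[SampleReads, dict[str, int]]:
    """Translate every read of a sample; unmapped reads are dropped.

    Strand is flipped for reverse-orientation chains.  Returns the translated
    sample plus counts of reads per mapping status.
    """
    summary = {STATUS_MAPPED: 0, STATUS_BELOW: 0, STATUS_MULTIPLE: 0,
               STATUS_NONE: 0}
    out_reads: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for read in sample.reads:
        by_chrom.setdefault(read.chrom, []).append(read)

    for chrom, reads in by_chrom.items():
        chrom_chains = chains.for_source(chrom)
        if not chrom_chains:
            summary[STATUS_NONE] += len(reads)
            continue
        starts = np.fromiter((r.start for r in reads), dtype=np.int64)
        ends = np.fromiter((r.end for r in reads), dtype=np.int64)
        lengths = (ends - starts).astype(float)
        n = len(reads)
        n_candidates = np.zeros(n, dtype=np.int64)
        any_overlap = np.zeros(n, dtype=bool)
        best_tgt = np.zeros((n, 2), dtype=np.int64)
        best_chain = [None] * n
        for chain in chrom_chains:
            mapped, tgt_start, tgt_end = _translate_reads_one_chain(
                chain, starts, ends)
            frac = mapped / lengths
            any_overlap |= (starts < chain.src_end) \
                & (ends > chain.src_starts[0])
            ok = frac >= min_match
            n_candidates += ok
            newly = ok & (n_candidates == 1)
            best_tgt[newly, 0] = tgt_start[newly]
            best_tgt[newly, 1] = tgt_end[newly]
            for i in np.flatnonzero(newly):
                best_chain[i] = chain
        for i, read in enumerate(reads):
            if n_candidates[i] == 1:
                chain = best_chain[i]
                strand = read.strand
                if strand in "+-" and chain.orientation == "-":
                    strand = "-" if strand == "+" else "+"
                out_reads.append(GenomicInterval(
                    chain.tgt_chrom, int(best_tgt[i, 0]), int(best_tgt[i, 1]),
                    strand))
                summary[STATUS_MAPPED] += 1
            elif n_candidates[i] > 1:
                summary[STATUS_MULTIPLE] += 1
            elif any_overlap[i]:
                summary[STATUS_BELOW] += 1
            else:
                summary[STATUS_NONE] += 1
    translated = SampleReads(
        label=sample.label, condition=sample.condition, factor=sample.factor,
        replicate=sample.replicate, species=sample.species, reads=out_reads)
    return translated, summary


def invert_chains(chains: ChainMap) -> ChainMap:
    """Swap source and target roles; invert(invert(c)) == c."""
    inverted = []
    for c in chains:
        if c.orientation == "+":
            order = np.argsort(c.tgt_starts)
            inverted.append(Chain(
                chain_id=c.chain_id, score=c.score,
                src_chrom=c.tgt_chrom, src_size=c.tgt_size,
                tgt_chrom=c.src_chrom, tgt_size=c.src_size,
                orientation="+",
                src_starts=c.tgt_starts[order],
                tgt_starts=c.src_starts[order],
                sizes=c.sizes[order]))
        else:
            # forward-target block [t0, t0+z) pairs reversed with [s0, s0+z)
            order = np.argsort(c.tgt_starts)
            inverted.append(Chain(
                chain_id=c.chain_id, score=c.score,
                src_chrom=c.tgt_chrom, src_size=c.tgt_size,
                tgt_chrom=c.src_chrom, tgt_size=c.src_size,
                orientation="-",
                src_starts=c.tgt_starts[order],
                tgt_starts=c.src_starts[order],
                sizes=c.sizes[order]))
    return ChainMap(inverted)
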