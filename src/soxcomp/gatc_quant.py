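"""GATC fragment partition of a genome and per-fragment read coverage.

The DamID quantification unit is the fragment between consecutive GATC sites.
Boundaries sit at the first base of each exact GATC occurrence on the forward
strand (GATC is its own reverse complement, so one strand suffices); the 4-bp
site belongs to the fragment it starts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import GenomeSequence, GenomicInterval

_GATC = re.compile("GATC")


class GatcFragmentMap:
    """Ordered fragments tiling each chromosome exactly, with stable indices."""

    def __init__(self, boundaries: dict[str, np.ndarray],
                 chrom_lengths: dict[str, int]):
        self.chrom_lengths = dict(chrom_lengths)
        self.starts: dict[str, np.ndarray] = {}
        self.offsets: dict[str, int] = {}   # stable index of first fragment
        offset = 0
        for chrom in chrom_lengths:
            bounds = np.asarray(boundaries.get(chrom, np.empty(0, dtype=np.int64)),
                                dtype=np.int64)
            bounds = bounds[(bounds > 0) & (bounds < chrom_lengths[chrom])]
            starts = np.concatenate([[0], bounds])
            self.starts[chrom] = starts
            self.offsets[chrom] = offset
            offset += len(starts)
        self.n_fragments = offset

    def fragments(self, chrom: str) -> list[GenomicInterval]:
        starts = self.starts[chrom]
        ends = np.concatenate([starts[1:], [self.chrom_lengths[chrom]]])
        return [GenomicInterval(chrom, int(s), int(e))
                for s, e in zip(starts, ends)]

    def all_fragments(self) -> list[GenomicInterval]:
        out: list[GenomicInterval] = []
        for chrom in self.chrom_lengths:
            out.extend(self.fragments(chrom))
        return out

    def ends(self, chrom: str) -> np.ndarray:
        starts = self.starts[chrom]
        return np.concatenate([starts[1:], [self.chrom_lengths[chrom]]])

    def fragment_lengths(self) -> np.ndarray:
        return np.concatenate([self.ends(c) - self.starts[c]
                               for c in self.chrom_lengths])

    def midpoints(self, chrom: str) -> np.ndarray:
        return (self.starts[chrom] + self.ends(chrom)) // 2

    def locate(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Fragment index (chromosome-local) containing each position."""
        return np.searchsorted(self.starts[chrom], positions, side="right") - 1


@dataclass
class SampleReads:
    """Mapped reads of one DamID sample (fusion or Dam-only control)."""

    label: str
    condition: str                      # 'fusion' or 'control'
    factor: str                         # 'Dichaete', 'SoxN' or 'none'
    replicate: int
    species: str
    reads: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.condition not in ("fusion", "control"):
            raise ValueError(f"invalid condition {self.condition!r}")
        if self.condition == "control" and self.factor != "none":
            raise ValueError("Dam-only controls must have factor 'none'")
        if self.condition == "fusion" and self.factor == "none":
            raise ValueError("fusion samples must name a factor")


@dataclass
class FragmentCountTable:
    """Samples x GATC-fragments integer count matrix with sample metadata."""

    counts: np.ndarray                  # fragments x samples
    fragment_map: GatcFragmentMap
    metadata: pd.DataFrame              # one row per sample column

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.fragment_map.n_fragments,
                                 len(self.metadata)):
            raise ValueError("count matrix shape does not match fragment map "
                             "and sample list")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype,
                                                        np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def conditions(self) -> np.ndarray:
        return self.metadata["condition"].to_numpy()


def build_gatc_fragment_map(genome: GenomeSequence) -> GatcFragmentMap:
    """Partition every chromosome at GATC occurrences.

    GATC cannot overlap itself, so a plain regex scan finds every site.
    Chromosomes without a (internal) GATC yield one whole-chromosome
    fragment; zero-length fragments (site at position 0) are suppressed.
    """
    boundaries = {
        chrom: np.fromiter((m.start() for m in _GATC.finditer(seq)),
                           dtype=np.int64)
        for chrom, seq in genome.sequences.items()
    }
    return GatcFragmentMap(boundaries, genome.lengths)


def extend_reads(sample: SampleReads, length: int,
                 chrom_lengths: dict[str, int]) -> list[GenomicInterval]:
    """Extend each read to ``length`` bp from its 5' end in its 3' direction.

    Unstranded reads are treated as plus strand; results are clamped to the
    chromosome.
    """
    extended: list[GenomicInterval] = []
    for read in sample.reads:
        if read.chrom not in chrom_lengths:
            raise KeyError(f"read chromosome {read.chrom!r} absent from genome")
        clen = chrom_lengths[read.chrom]
        if len(read) > length:
            raise ValueError(f"read longer ({len(read)}) than extension "
                             f"length ({length})")
        if read.strand == "-":
            start, end = read.end - length, read.end
        else:
            start, end = read.start, read.start + length
        extended.append(GenomicInterval(read.chrom, max(0, start),
                                        min(clen, end), read.strand))
    return extended


def count_fragment_coverage(fragment_map: GatcFragmentMap,
                            extended: list[GenomicInterval]) -> np.ndarray:
    """Count extended reads overlapping each fragment by >= 1 bp.

    A read spanning k fragments contributes to all k (coverage semantics),
    so the count total is >= the read count.
    """
    counts = np.zeros(fragment_map.n_fragments, dtype=np.int64)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in extended:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        if chrom not in fragment_map.starts:
            raise KeyError(f"chromosome {chrom!r} absent from fragment map")
        starts = np.fromiter((iv.start for iv in ivs), dtype=np.int64)
        ends = np.fromiter((iv.end for iv in ivs), dtype=np.int64)
        first = fragment_map.locate(chrom, starts)
        last = fragment_map.locate(chrom, ends - 1)
        offset = fragment_map.offsets[chrom]
        # range-increment via difference array
        diff = np.zeros(len(fragment_map.starts[chrom]) + 1, dtype=np.int64)
        np.add.at(diff, first, 1)
        np.add.at(diff, last + 1, -1)
        counts[offset:offset + len(fragment_map.starts[chrom])] += \
            np.cumsum(diff[:-1])
    return counts


def assemble_count_table(fragment_map: GatcFragmentMap,
                         samples: list[SampleReads],
                         extension_length: int = 200) -> FragmentCountTable:
    """Collate per-sample fragment coverage into one count table."""
    labels = [s.label for s in samples]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sample labels")
    conditions = {s.condition for s in samples}
    if conditions != {"fusion", "control"}:
        raise ValueError("need at least one fusion and one control sample")
    columns = []
    for sample in samples:
        extended = extend_reads(sample, extension_length,
                                fragment_map.chrom_lengths)
        columns.append(count_fragment_coverage(fragment_map, extended))
    metadata = pd.DataFrame({
        "label": labels,
        "condition": [s.condition for s in samples],
        "factor": [s.factor for s in samples],
        "species": [s.species for s in samples],
        "replicate": [s.replicate for s in samples],
    })
    return FragmentCountTable(np.column_stack(columns), fragment_map, metadata)


def write_count_table(table: FragmentCountTable, path,
                      header: list[str] | None = None) -> None:
    frags = table.fragment_map.all_fragments()
    df = pd.DataFrame({
        "index": np.arange(len(frags)),
        "chrom": [f.chrom for f in frags],
        "start": [f.start for f in frags],
        "end": [f.end for f in frags],
    })
    for j, label in enumerate(table.metadata["label"]):
        df[label] = table.counts[:, j]
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(line + "\n")
        meta = table.metadata.to_csv(sep=";", index=False).strip().split("\n")
        for line in meta:
            fh.write(f"# meta {line}\n")
        df.to_csv(fh, sep="\t", index=False)
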