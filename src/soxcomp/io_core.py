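"""Shared genomic primitives, file formats and run configuration.

Every internal coordinate is 0-based half-open (BED convention).  Formats with
other conventions (GFF3: 1-based inclusive; UCSC chain: strand-relative) are
converted at the read/write boundary, never downstream.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

VALID_BASES = frozenset("ACGTN")
STRANDS = ("+", "-", ".")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_overlap


class GenomeSequence:
    """Per-chromosome nucleotide strings over the {A,C,G,T,N} alphabet."""

    def __init__(self, sequences: dict[str, str]):
        for name, seq in sequences.items():
            if not name:
                raise ValueError("empty chromosome name")
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"invalid characters {sorted(bad)} in chromosome {name!r}"
                )
        self.sequences = dict(sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __iter__(self):
        return iter(self.sequences)

    def fetch(self, interval: GenomicInterval) -> str:
        return self.sequences[interval.chrom][interval.start:interval.end]


@dataclass(frozen=True)
class GeneModel:
    """Gene with ordered exons; introns are derived as inter-exon gaps.

    Intron rank 1 is the 5'-most intron in transcription order, so for minus
    strand genes rank counts down from the genomic right.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        exons = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) outside span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start coordinate (5' end of the span per strand)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> tuple[tuple[int, int, int], ...]:
        """(start, end, rank) triples; rank 1 = first intron transcribed."""
        gaps = [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]
        if self.strand == "-":
            gaps = gaps[::-1]
        return tuple((s, e, i + 1) for i, (s, e) in enumerate(gaps))

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand,
                               name=self.gene_id)


@dataclass(frozen=True)
class Chain:
    """One pairwise-alignment chain.

    Blocks are ungapped; ``src_starts``/``tgt_starts`` are forward-strand
    coordinates on both genomes.  For ``orientation == '-'`` the k-th base of
    a block on the source pairs with the (size-1-k)-th forward-strand base on
    the target (coordinates were flipped on read, see :func:`read_chain`).
    """

    chain_id: int
    score: float
    src_chrom: str
    src_size: int
    tgt_chrom: str
    tgt_size: int
    orientation: str  # '+' or '-'
    src_starts: np.ndarray
    tgt_starts: np.ndarray
    sizes: np.ndarray

    def __post_init__(self) -> None:
        for arr_name in ("src_starts", "tgt_starts", "sizes"):
            object.__setattr__(self, arr_name,
                               np.asarray(getattr(self, arr_name), dtype=np.int64))
        s, t, z = self.src_starts, self.tgt_starts, self.sizes
        if not (len(s) == len(t) == len(z)):
            raise ValueError("chain block arrays must have equal length")
        if len(s) == 0:
            raise ValueError("chain with no blocks")
        if np.any(z <= 0):
            raise ValueError("non-positive block size")
        if np.any(np.diff(s) < z[:-1]):
            raise ValueError("overlapping/unsorted source blocks")
        tf = t if self.orientation == "+" else -t  # forward or anti ordering
        if np.any(np.diff(tf) < (z[:-1] if self.orientation == "+" else z[1:])):
            raise ValueError("overlapping target blocks")
        if s[-1] + z[-1] > self.src_size or np.any(s < 0):
            raise ValueError("source blocks exceed chromosome size")
        if np.any(t < 0) or np.any(t + z > self.tgt_size):
            raise ValueError("target blocks exceed chromosome size")

    @property
    def src_end(self) -> int:
        return int(self.src_starts[-1] + self.sizes[-1])

    @property
    def aligned_bases(self) -> int:
        return int(self.sizes.sum())


class ChainMap:
    """Collection of chains indexed by source chromosome."""

    def __init__(self, chains: list[Chain]):
        self.chains = list(chains)
        self._by_src: dict[str, list[Chain]] = {}
        for c in self.chains:
            self._by_src.setdefault(c.src_chrom, []).append(c)

    def for_source(self, chrom: str) -> list[Chain]:
        return self._by_src.get(chrom, [])

    def __len__(self) -> int:
        return len(self.chains)

    def __iter__(self):
        return iter(self.chains)


class MultipleAlignment:
    """Aligned orthologous sequences, one gapped row per species."""

    GAP = "-"

    def __init__(self, rows: dict[str, str], name: str | None = None):
        if not rows:
            raise ValueError("alignment with no rows")
        lengths = {len(s) for s in rows.values()}
        if len(lengths) != 1:
            raise ValueError("gapped rows have unequal lengths")
        self.rows = dict(rows)
        self.name = name
        self.length = lengths.pop()

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def ungapped(self, species: str) -> str:
        return self.rows[species].replace(self.GAP, "")

    def position_map(self, species: str) -> np.ndarray:
        """Map ungapped position -> alignment column for one row."""
        row = np.frombuffer(self.rows[species].encode(), dtype=np.uint8)
        return np.flatnonzero(row != ord(self.GAP))

    def column(self, col: int) -> dict[str, str]:
        return {sp: row[col] for sp, row in self.rows.items()}


@dataclass
class RunConfig:
    """All numeric settings of the pipeline, with the published defaults."""

    extension_length: int = 200       # bp; reads extended to mean fragment size
    merge_gap: int = 100              # bp between enriched fragments to merge
    padj_thresholds: tuple[float, float] = (0.05, 0.01)
    fdr_levels: dict[str, float] = field(
        default_factory=lambda: {"FDR1": 0.01, "FDR5": 0.05})
    min_match: float = 0.7            # liftover minMatch; close species pairs
    min_match_distant: float = 0.5    # distant species pair
    pwm_score_cutoff: float = 4.0     # log2 weight-score
    pwm_pvalue_cutoff: float = 1e-4
    promoter_upstream: int = 2000     # bp upstream of TSS
    promoter_downstream: int = 500    # bp downstream of TSS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extension_length <= 0 or self.merge_gap < 0:
            raise ValueError("invalid extension/merge settings")
        for p in self.padj_thresholds:
            if not 0 < p < 1:
                raise ValueError("adjusted-p thresholds must lie in (0,1)")
        for p in self.fdr_levels.values():
            if not 0 < p < 1:
                raise ValueError("FDR levels must lie in (0,1)")
        for m in (self.min_match, self.min_match_distant):
            if not 0 < m <= 1:
                raise ValueError("minMatch must lie in (0,1]")
        if not 0 < self.pwm_pvalue_cutoff < 1:
            raise ValueError("PWM p-value cutoff must lie in (0,1)")

    def provenance_header(self, extra: dict | None = None) -> list[str]:
        import soxcomp
        items = {
            "soxcomp_version": soxcomp.__version__,
            "seed": self.seed,
            "extension_length": self.extension_length,
            "merge_gap": self.merge_gap,
            "min_match": self.min_match,
        }
        if extra:
            items.update(extra)
        return [f"# {k}={v}" for k, v in items.items()]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> GenomeSequence:
    """Read a genome FASTA; sequences are upper-cased and validated."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA record name {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path: str | os.PathLike,
                width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_intervals(path: str | os.PathLike, dialect: str = "BED3"
                   ) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into validated intervals, preserving order."""
    if dialect not in ("BED3", "BED6"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    ncols = 3 if dialect == "BED3" else 6
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncols:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {ncols} columns for "
                    f"{dialect}, got {len(fields)}")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative coordinate")
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            if dialect == "BED6":
                name = fields[3] if fields[3] != "." else None
                score = float(fields[4]) if fields[4] != "." else None
                strand = fields[5]
                intervals.append(GenomicInterval(chrom, start, end, strand,
                                                 score=score, name=name))
            else:
                intervals.append(GenomicInterval(chrom, start, end))
    return intervals


def write_intervals(intervals: list[GenomicInterval], path: str | os.PathLike,
                    dialect: str = "BED6", header: list[str] | None = None
                    ) -> None:
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(line + "\n")
        for iv in intervals:
            if dialect == "BED3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = "." if iv.score is None else f"{iv.score:g}"
                name = iv.name or "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t"
                         f"{score}\t{iv.strand}\n")


def read_chain(path: str | os.PathLike) -> ChainMap:
    """Parse a UCSC chain file.

    Header: ``chain score tName tSize tStrand tStart tEnd qName qSize qStrand
    qStart qEnd id`` followed by ``size [dt dq]`` block lines; the final line
    of a chain carries only ``size``.  Translation maps the *t* (source)
    genome onto the *q* (target) genome.  Reverse-strand target blocks are
    flipped to forward-strand coordinates; the chain keeps ``orientation='-'``.
    """
    chains: list[Chain] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i]
        if not line or line.startswith("#"):
            i += 1
            continue
        if not line.startswith("chain"):
            raise ValueError(f"{path}: expected chain header, got {line!r}")
        parts = line.split()
        if len(parts) != 13:
            raise ValueError(f"{path}: malformed chain header {line!r}")
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, chain_id) = parts
        if t_strand != "+":
            raise ValueError(f"{path}: tStrand must be '+'")
        t_size, t_start, t_end = int(t_size), int(t_start), int(t_end)
        q_size, q_start, q_end = int(q_size), int(q_start), int(q_end)
        src_starts, tgt_starts, sizes = [], [], []
        t_cursor, q_cursor = t_start, q_start
        i += 1
        closed = False
        while i < len(lines):
            block = lines[i]
            i += 1
            if not block:
                continue
            nums = block.split()
            size = int(nums[0])
            if size > 0:
                src_starts.append(t_cursor)
                # q coordinates are strand-relative; normalize below
                tgt_starts.append(q_cursor)
                sizes.append(size)
            if len(nums) == 1:
                t_cursor += size
                q_cursor += size
                closed = True
                break
            if len(nums) != 3:
                raise ValueError(f"{path}: malformed block line {block!r}")
            dt, dq = int(nums[1]), int(nums[2])
            t_cursor += size + dt
            q_cursor += size + dq
        if not closed:
            raise ValueError(f"{path}: chain {chain_id} missing terminal "
                             "size-only line")
        if t_cursor > t_end or q_cursor > q_end:
            raise ValueError(
                f"{path}: chain {chain_id} blocks extend past declared span")
        sizes_arr = np.asarray(sizes, dtype=np.int64)
        tgt_arr = np.asarray(tgt_starts, dtype=np.int64)
        if q_strand == "-":
            # strand-relative [s, s+size) -> forward [qSize-s-size, qSize-s)
            tgt_arr = q_size - tgt_arr - sizes_arr
        chains.append(Chain(
            chain_id=int(chain_id), score=float(score),
            src_chrom=t_name, src_size=t_size,
            tgt_chrom=q_name, tgt_size=q_size,
            orientation="+" if q_strand == "+" else "-",
            src_starts=np.asarray(src_starts, dtype=np.int64),
            tgt_starts=tgt_arr, sizes=sizes_arr))
    return ChainMap(chains)


def write_chain(chain_map: ChainMap, path: str | os.PathLike) -> None:
    """Write chains back to UCSC chain format (inverse of :func:`read_chain`)."""
    with open(path, "w") as fh:
        for c in chain_map:
            sizes = c.sizes
            t_start = int(c.src_starts[0])
            t_end = c.src_end
            if c.orientation == "+":
                q_rel = c.tgt_starts
            else:
                q_rel = c.tgt_size - c.tgt_starts - sizes
            q_start, q_end = int(q_rel[0]), int(q_rel[-1] + sizes[-1])
            fh.write(f"chain {c.score:g} {c.src_chrom} {c.src_size} + "
                     f"{t_start} {t_end} {c.tgt_chrom} {c.tgt_size} "
                     f"{c.orientation} {q_start} {q_end} {c.chain_id}\n")
            for k in range(len(sizes)):
                if k + 1 < len(sizes):
                    dt = int(c.src_starts[k + 1] - c.src_starts[k] - sizes[k])
                    dq = int(q_rel[k + 1] - q_rel[k] - sizes[k])
                    fh.write(f"{sizes[k]} {dt} {dq}\n")
                else:
                    fh.write(f"{sizes[k]}\n")
            fh.write("\n")


def read_gff_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GFF3; exons come from the longest transcript.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript")))
        if transcripts:
            canonical = max(transcripts,
                            key=lambda t: (t.end - t.start + 1, t.id))
            exon_parent = canonical
        else:
            exon_parent = gene
        exons = sorted(
            (e.start - 1, e.end)
            for e in db.children(exon_parent, featuretype="exon"))
        if not exons:
            raise ValueError(f"gene {gene.id} has no exons")
        genes.append(GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            start=gene.start - 1, end=gene.end, exons=tuple(exons)))
    return genes


def write_gff_genes(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tsoxcomp\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            mrna_id = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\tsoxcomp\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={mrna_id};Parent={g.gene_id}\n")
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tsoxcomp\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={mrna_id}.e{k};Parent={mrna_id}\n")


def write_bedgraph(intervals: list[GenomicInterval], values,
                   path: str | os.PathLike,
                   header: list[str] | None = None) -> None:
    """Write one value per fragment as sorted bedGraph records."""
    values = np.asarray(values, dtype=float)
    if len(values) != len(intervals):
        raise ValueError("one value per fragment required")
    order = sorted(range(len(intervals)),
                   key=lambda i: (intervals[i].chrom, intervals[i].start))
    prev: GenomicInterval | None = None
    for i in order:
        iv = intervals[i]
        if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
            raise ValueError(f"overlapping fragments near {iv.chrom}:{iv.start}")
        prev = iv
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(line + "\n")
        for i in order:
            iv = intervals[i]
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{values[i]:.6f}\n")


def read_bedgraph(path: str | os.PathLike
                  ) -> tuple[list[GenomicInterval], np.ndarray]:
    intervals: list[GenomicInterval] = []
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")
            intervals.append(GenomicInterval(chrom, int(start), int(end)))
            values.append(float(value))
    return intervals, np.asarray(values)


def read_alignment(path: str | os.PathLike) -> MultipleAlignment:
    """Read one aligned-FASTA multiple alignment."""
    aln = AlignIO.read(str(path), "fasta")
    rows = {rec.id: str(rec.seq).upper() for rec in aln}
    return MultipleAlignment(rows, name=os.path.basename(str(path)))


def write_alignment(alignment: MultipleAlignment,
                    path: str | os.PathLike) -> None:
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(seq), id=sp, description="")
        for sp, seq in alignment.rows.items())
    AlignIO.write(msa, str(path), "fasta")


def merge_intervals(intervals: list[GenomicInterval], gap: int = 0
                    ) -> list[GenomicInterval]:
    """Single-linkage merge of intervals whose gaps are <= ``gap`` bp."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1].chrom == iv.chrom \
                and iv.start - merged[-1].end <= gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = replace(last, end=iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged
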