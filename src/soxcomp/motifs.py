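"""PWM scanning with exact score p-values and alignment-based conservation.

Weight scores are log2 odds with a background-proportional pseudocount.  The
null score distribution is computed exactly by dynamic programming on a
discretized score grid, which for short motifs matches exhaustive enumeration
over all 4^w words.  Matches must clear BOTH the weight-score cutoff and the
match p-value cutoff.  Motif conservation works on multiple alignments of
orthologous intervals: a motif is positionally conserved when independent
matches share the identical alignment start column (and strand) in more than
one species, and a column counts as conserved only when every species carries
the identical base with no gap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_core import GenomicInterval, MultipleAlignment

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position probability matrix over {A,C,G,T}."""

    name: str
    probs: np.ndarray                    # width x 4
    pseudocount: float = 0.01
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 \
                or self.probs.shape[0] < 1:
            raise ValueError("PWM must be width x 4 with width >= 1")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("PWM columns must each sum to 1")
        if np.any(self.background <= 0):
            raise ValueError("background must be strictly positive")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


@dataclass
class MotifMatch:
    source: str                  # interval/alignment row identifier
    offset: int                  # 0-based on the forward ungapped sequence
    strand: str
    score: float
    pvalue: float
    width: int
    alignment_column: int | None = None
    gapped_span: bool = False    # True when the match crosses gap columns


@dataclass
class ConservedMotifRecord:
    alignment: str
    column: int
    strand: str
    species: frozenset[str]
    positionally_conserved: bool
    fully_conserved: bool        # all species share the start column
    perfectly_conserved: bool    # identical bases across all species/columns
    conservation_rate: float


def log_odds(pwm: PWM) -> np.ndarray:
    """log2 weight matrix w[i,b] = log2((p+c*bg) / ((1+c)*bg))."""
    c, bg = pwm.pseudocount, pwm.background
    return np.log2((pwm.probs + c * bg[None, :]) / ((1 + c) * bg[None, :]))


class ScoreDistribution:
    """Exact null distribution of window scores on a discretized grid."""

    def __init__(self, weights: np.ndarray, background: np.ndarray,
                 granularity: float = 1e-3, max_width: int = 20):
        weights = np.asarray(weights, dtype=float)
        if weights.shape[0] > max_width:
            raise ValueError(f"motif width {weights.shape[0]} exceeds the "
                             f"DP limit ({max_width})")
        self.granularity = granularity
        scaled = np.rint(weights / granularity).astype(np.int64)
        lo = int(scaled.min(axis=1).sum())
        hi = int(scaled.max(axis=1).sum())
        pmf = np.zeros(hi - lo + 1)
        pmf[0] = 1.0  # distribution of (partial score - partial minimum)
        offset = 0
        for i in range(scaled.shape[0]):
            row = scaled[i] - scaled[i].min()
            width = row.max() + 1
            nxt = np.zeros(len(pmf))
            for b in range(4):
                nxt[row[b]:row[b] + len(pmf) - width + 1] += \
                    background[b] * pmf[:len(pmf) - width + 1]
            pmf = nxt
            offset += int(scaled[i].min())
        self.scores = (np.arange(lo, hi + 1)) * granularity
        self.pmf = pmf
        # survival: P(score >= s); grid half-step guard against rounding
        self._ccdf = np.cumsum(pmf[::-1])[::-1]

    def pvalue(self, score: float | np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.scores,
                              np.asarray(score) - self.granularity / 2,
                              side="left")
        idx = np.clip(idx, 0, len(self._ccdf))
        ccdf = np.concatenate([self._ccdf, [0.0]])
        return ccdf[idx]


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        out[arr == ord(base)] = i
    return out


def _window_scores(encoded: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Score of every window; NaN where the window contains a non-ACGT base."""
    w = weights.shape[0]
    n = len(encoded) - w + 1
    if n <= 0:
        return np.empty(0)
    padded = np.vstack([weights.T, np.full((1, w), np.nan)])  # row 4 = N
    windows = np.lib.stride_tricks.sliding_window_view(encoded, w)
    return padded[windows, np.arange(w)[None, :]].sum(axis=1)


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def scan_sequence(sequence: str, pwm: PWM,
                  score_cutoff: float = 4.0, p_cutoff: float = 1e-4,
                  distribution: ScoreDistribution | None = None,
                  source: str = "") -> list[MotifMatch]:
    """Scan both strands; report matches clearing both cutoffs.

    Reverse-strand windows are scored as the forward-scored reverse
    complement; offsets always refer to the forward strand.  Windows
    containing N are skipped.
    """
    weights = log_odds(pwm)
    if distribution is None:
        distribution = ScoreDistribution(weights, pwm.background)
    w = pwm.width
    matches: list[MotifMatch] = []
    fwd = _window_scores(_encode(sequence), weights)
    rc_scores = _window_scores(_encode(reverse_complement(sequence)), weights)
    rev = rc_scores[::-1] if len(rc_scores) else rc_scores
    for strand, scores in (("+", fwd), ("-", rev)):
        with np.errstate(invalid="ignore"):
            keep = np.flatnonzero(~np.isnan(scores)
                                  & (scores >= score_cutoff))
        if len(keep) == 0:
            continue
        pvals = distribution.pvalue(scores[keep])
        for off, sc, pv in zip(keep, scores[keep], pvals):
            if pv < p_cutoff:
                matches.append(MotifMatch(
                    source=source, offset=int(off), strand=strand,
                    score=float(sc), pvalue=float(pv), width=w))
    matches.sort(key=lambda m: (m.offset, m.strand))
    return matches


def shuffle_pwm_columns(pwm: PWM, seed: int) -> PWM:
    """Control motif: column order permuted (Fisher-Yates); composition,
    GC content and width are preserved exactly."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pwm.width)
    return PWM(name=f"{pwm.name}_shuffled", probs=pwm.probs[perm],
               pseudocount=pwm.pseudocount, background=pwm.background)


def shuffle_intervals(intervals: list[GenomicInterval],
                      chrom_lengths: dict[str, int], seed: int,
                      excluded: list[GenomicInterval] | None = None
                      ) -> list[GenomicInterval]:
    """Re-place each interval uniformly on its own chromosome, length kept.

    Placement avoids ``excluded`` regions by sampling uniformly over the
    allowed start positions.
    """
    rng = np.random.default_rng(seed)
    excl: dict[str, list[tuple[int, int]]] = {}
    for iv in excluded or []:
        excl.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = []
    for iv in intervals:
        clen = chrom_lengths[iv.chrom]
        length = len(iv)
        if length > clen:
            raise ValueError(f"interval longer than chromosome {iv.chrom!r}")
        # allowed gaps between excluded regions
        blocks = sorted(excl.get(iv.chrom, []))
        gaps, cursor = [], 0
        for s, e in blocks:
            if s > cursor:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < clen:
            gaps.append((cursor, clen))
        slots = [(gs, ge - length + 1 - gs) for gs, ge in gaps
                 if ge - gs >= length]
        if not slots:
            raise ValueError(f"no room to place a {length}-bp interval on "
                             f"{iv.chrom!r}")
        weights = np.array([n for _, n in slots], dtype=float)
        slot = rng.choice(len(slots), p=weights / weights.sum())
        start = slots[slot][0] + int(rng.integers(slots[slot][1]))
        out.append(GenomicInterval(iv.chrom, start, start + length,
                                   iv.strand, name=iv.name))
    return out


def wilcoxon_rank_sum(x, y, continuity: bool = True
                      ) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with midranks.

    Exact p by enumeration when n_x + n_y <= 12 with no ties, otherwise a
    normal approximation with tie-corrected variance and a +/- 0.5 continuity
    correction.  Returns (W = rank sum of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = float(ranks[:nx].sum())
    has_ties = len(np.unique(combined)) < len(combined)

    if nx + ny <= 12 and not has_ties:
        order_ranks = np.arange(1, nx + ny + 1, dtype=float)
        sums = [sum(c) for c in itertools.combinations(order_ranks, nx)]
        sums = np.asarray(sums)
        mean = nx * (nx + ny + 1) / 2.0
        extreme = np.abs(sums - mean) >= abs(w - mean) - 1e-12
        return w, float(extreme.mean())

    mean = nx * (nx + ny + 1) / 2.0
    n = nx + ny
    _, counts = np.unique(combined, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / ((n) * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    z = w - mean
    if continuity:
        z = np.sign(z) * max(abs(z) - 0.5, 0.0)
    z /= np.sqrt(var)
    return w, float(2.0 * stats.norm.sf(abs(z)))


def motif_density_compare(intervals_1: list[GenomicInterval],
                          intervals_2: list[GenomicInterval],
                          genome, pwm: PWM,
                          score_cutoff: float = 4.0,
                          p_cutoff: float = 1e-4):
    """Per-interval motif counts in two groups plus a rank-sum comparison.

    Returns (mean count group 1, mean count group 2, W, two-sided p).
    """
    if not intervals_1 or not intervals_2:
        raise ValueError("both interval groups must be non-empty")
    dist = ScoreDistribution(log_odds(pwm), pwm.background)
    counts = []
    for group in (intervals_1, intervals_2):
        counts.append(np.array([
            len(scan_sequence(genome.fetch(iv), pwm, score_cutoff, p_cutoff,
                              distribution=dist))
            for iv in group], dtype=float))
    w, p = wilcoxon_rank_sum(counts[0], counts[1])
    return float(counts[0].mean()), float(counts[1].mean()), w, p


# ---------------------------------------------------------------------------
# alignment-context scanning and conservation
# ---------------------------------------------------------------------------

def scan_alignment(alignment: MultipleAlignment, pwm: PWM,
                   score_cutoff: float = 4.0, p_cutoff: float = 1e-4,
                   distribution: ScoreDistribution | None = None
                   ) -> dict[str, list[MotifMatch]]:
    """Scan each row's ungapped sequence; map match starts to columns."""
    if distribution is None:
        distribution = ScoreDistribution(log_odds(pwm), pwm.background)
    out: dict[str, list[MotifMatch]] = {}
    for species in alignment.species:
        ungapped = alignment.ungapped(species)
        if not ungapped:
            raise ValueError(f"empty alignment row for {species!r}")
        pos_map = alignment.position_map(species)
        matches = scan_sequence(ungapped, pwm, score_cutoff, p_cutoff,
                                distribution=distribution, source=species)
        for m in matches:
            m.alignment_column = int(pos_map[m.offset])
            last_col = int(pos_map[m.offset + m.width - 1])
            m.gapped_span = (last_col - m.alignment_column + 1) != m.width
        out[species] = matches
    return out


def nucleotide_conservation_rate(alignment: MultipleAlignment,
                                 col_start: int, col_end: int) -> float:
    """Fraction of columns in [col_start, col_end) where every species has
    the identical base and no gaps."""
    if not 0 <= col_start < col_end <= alignment.length:
        raise ValueError("empty or out-of-range column window")
    rows = [row[col_start:col_end] for row in alignment.rows.values()]
    conserved = 0
    for cols in zip(*rows):
        if MultipleAlignment.GAP not in cols and len(set(cols)) == 1:
            conserved += 1
    return conserved / (col_end - col_start)


def positional_conservation(alignment: MultipleAlignment,
                            matches: dict[str, list[MotifMatch]]
                            ) -> list[ConservedMotifRecord]:
    """Group matches by (alignment start column, strand).

    Positionally conserved = shared by >= 2 species; fully conserved = shared
    by every aligned species.  The nucleotide conservation rate is computed
    over the motif's alignment columns (start column + motif width columns,
    clipped to the alignment).
    """
    groups: dict[tuple[int, str], dict[str, MotifMatch]] = {}
    for species, mlist in matches.items():
        for m in mlist:
            key = (m.alignment_column, m.strand)
            groups.setdefault(key, {})[species] = m
    n_species = len(alignment.species)
    records = []
    for (col, strand), members in sorted(groups.items()):
        width = next(iter(members.values())).width
        col_end = min(col + width, alignment.length)
        rate = nucleotide_conservation_rate(alignment, col, col_end)
        fully = len(members) == n_species
        records.append(ConservedMotifRecord(
            alignment=alignment.name or "", column=col, strand=strand,
            species=frozenset(members),
            positionally_conserved=len(members) > 1,
            fully_conserved=fully,
            perfectly_conserved=fully and rate == 1.0,
            conservation_rate=rate))
    return records
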