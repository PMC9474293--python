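"""PWM construction and scanning, exact score p-values, peak-set operations
and the shuffled-interval null used to count motif arrays in binding sites.

The scanner scores every length-L window of a sequence (both strands) against
a log-odds position weight matrix.  Hit significance uses the exact score
distribution under the i.i.d. background model, computed by dynamic
programming on a discretized score grid — the same construction used by
TFM-pvalue-style tools — so a hit threshold can be stated either as a raw
log-odds score or as a maximum p-value (``-log10 p`` minimum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import (BASES, GenomicInterval, PositionFrequencyMatrix,
                 ValidationError)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

UNIFORM_BACKGROUND = np.full(4, 0.25)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


@dataclass
class PWM:
    """Log-odds position weight matrix over {A,C,G,T}."""

    motif_id: str
    log_odds: np.ndarray          # L x 4, log2 odds vs background
    background: np.ndarray        # 4 probabilities
    pseudocount: float

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValidationError("background must sum to 1")
        if not np.all(np.isfinite(self.log_odds)):
            raise ValidationError("log-odds must be finite")

    def __len__(self) -> int:
        return self.log_odds.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        # reversing positions and swapping A<->T, C<->G scores the - strand
        rc = self.log_odds[::-1, [3, 2, 1, 0]]
        return PWM(self.motif_id, rc, self.background, self.pseudocount)


@dataclass(frozen=True)
class MotifHit:
    """One scored motif occurrence on the + coordinate frame."""

    interval: GenomicInterval     # strand records match orientation
    score: float
    minus_log10_p: float | None = None


def build_pwm(pfm: PositionFrequencyMatrix, pseudocount: float = 0.8,
              background: Sequence[float] | None = None) -> PWM:
    """Log-odds matrix from base counts with background-weighted pseudocount.

    log_odds[i, b] = log2( (n[i,b] + pc*bg[b]) / (rowsum + pc) / bg[b] )
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    counts = pfm.counts
    rowsum = counts.sum(axis=1, keepdims=True)
    probs = (counts + pseudocount * bg) / (rowsum + pseudocount)
    return PWM(pfm.motif_id, np.log2(probs / bg), bg, pseudocount)


# ---------------------------------------------------------------------------
# exact score distribution
# ---------------------------------------------------------------------------

@dataclass
class ScoreDistribution:
    """Exact PWM score distribution under the i.i.d. background model.

    Scores are discretized to a grid of width ``delta``; ``pmf[k]`` is the
    probability that a random background word scores in grid cell
    ``offset + k`` (units of delta).
    """

    delta: float
    offset: int                   # grid index of pmf[0], in delta units
    pmf: np.ndarray
    n_positions: int              # motif length, bounds the rounding slack
    _tail: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        # upper-tail p: P(score >= grid point)
        self._tail = np.cumsum(self.pmf[::-1])[::-1]

    @property
    def total_mass(self) -> float:
        return float(self.pmf.sum())

    @property
    def _slack(self) -> int:
        # per-position rounding can misplace a summed score by up to L/2
        # grid cells; the p-value is made conservative (inclusive) by that
        # margin so no mass at or above the query score is ever missed
        return (self.n_positions + 1) // 2 + 1

    def pvalue(self, score: float) -> float:
        """P(background score >= score) on the discretized grid.

        Inclusive under discretization: never smaller than the exact
        upper-tail probability at ``score``, and never larger than the
        exact probability ~L*delta below it.
        """
        k = int(round(score / self.delta)) - self.offset - self._slack
        if k <= 0:
            return 1.0
        if k >= len(self.pmf):
            return 0.0
        return float(self._tail[k])

    def score_for_pvalue(self, p: float) -> float:
        """Smallest grid score s with ``pvalue(s) <= p``."""
        idx = np.nonzero(self._tail <= p)[0]
        base = len(self.pmf) if len(idx) == 0 else int(idx[0])
        return (self.offset + base + self._slack) * self.delta


def score_distribution(pwm: PWM, delta: float = 1e-3,
                       max_cells: int = 50_000_000) -> ScoreDistribution:
    """Position-wise convolution of per-base score masses on a delta grid."""
    if delta <= 0:
        raise ValidationError("delta must be positive")
    span = (pwm.max_score - pwm.min_score) / delta
    if span > max_cells:
        raise ValidationError(
            f"score grid would need ~{span:.0f} cells; increase delta")
    quant = np.round(pwm.log_odds / delta).astype(np.int64)
    offset = int(quant.min(axis=1).sum())
    size = int(quant.max(axis=1).sum()) - offset + 1
    pmf = np.zeros(size)
    pmf[0] = 1.0
    for i in range(len(pwm)):
        nxt = np.zeros(size)
        row_min = int(quant[i].min())
        for b in range(4):
            shift = int(quant[i, b]) - row_min
            if shift == 0:
                nxt += pwm.background[b] * pmf
            else:
                nxt[shift:] += pwm.background[b] * pmf[:size - shift]
        pmf = nxt
    return ScoreDistribution(delta=delta, offset=offset, pmf=pmf,
                             n_positions=len(pwm))


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to indices 0..3, with 4 for N/anything else."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _scan_strand(pwm: PWM, codes: np.ndarray) -> np.ndarray:
    """Vectorized per-window scores on the encoded + strand; NaN at N windows."""
    L = len(pwm)
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    bad = np.zeros(n_win, dtype=bool)
    for i in range(L):
        col = codes[i:i + n_win]
        bad |= col == 4
        scores += pwm.log_odds[i, np.minimum(col, 3)]
    scores[bad] = np.nan
    return scores


def scan_sequence(pwm: PWM, seq: str, chrom: str = "seq",
                  min_score: float | None = None,
                  max_minus_log10_p: float | None = None,
                  both_strands: bool = True,
                  dist: ScoreDistribution | None = None,
                  offset: int = 0) -> list[MotifHit]:
    """Report every window on + (and -) scoring at or above the threshold.

    Exactly one of ``min_score`` / ``max_minus_log10_p`` sets the threshold.
    Windows containing N are skipped.  Coordinates are 0-based on the +
    strand, optionally shifted by ``offset`` (genomic start of ``seq``).
    """
    if (min_score is None) == (max_minus_log10_p is None):
        raise ValueError("set exactly one of min_score / max_minus_log10_p")
    if dist is None and max_minus_log10_p is not None:
        dist = score_distribution(pwm)
    if min_score is None:
        min_score = dist.score_for_pvalue(10.0 ** (-max_minus_log10_p))

    codes = _encode(seq)
    L = len(pwm)
    hits: list[MotifHit] = []
    strands = [("+", pwm)]
    if both_strands:
        strands.append(("-", pwm.reverse_complement()))
    for strand, mat in strands:
        scores = _scan_strand(mat, codes)
        ok = np.nonzero(~np.isnan(scores) & (scores >= min_score - 1e-9))[0]
        for pos in ok:
            score = float(scores[pos])
            mlp = None
            if dist is not None:
                p = dist.pvalue(score)
                mlp = float(-np.log10(p)) if p > 0 else np.inf
            hits.append(MotifHit(
                interval=GenomicInterval(chrom, offset + int(pos),
                                         offset + int(pos) + L, strand=strand,
                                         score=score),
                score=score, minus_log10_p=mlp))
    hits.sort(key=lambda h: (h.interval.start, h.interval.strand))
    return hits


def scan_genome(pwm: PWM, genome: dict[str, str], **kwargs) -> list[MotifHit]:
    """Scan every sequence of a genome dict; chrom names from the keys."""
    dist = kwargs.pop("dist", None)
    if kwargs.get("max_minus_log10_p") is not None and dist is None:
        dist = score_distribution(pwm)
    hits: list[MotifHit] = []
    for chrom, seq in genome.items():
        hits.extend(scan_sequence(pwm, seq, chrom=chrom, dist=dist, **kwargs))
    return hits


# ---------------------------------------------------------------------------
# peak-set operations
# ---------------------------------------------------------------------------

def consensus_peaks(rep_a: Sequence[GenomicInterval],
                    rep_b: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Peaks of rep_a sharing >= 1 bp with any rep_b peak (rep_a as reference)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in rep_b:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    starts_ends = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        starts_ends[chrom] = (np.array([s for s, _ in spans]),
                              np.array([e for _, e in spans]))
    out = []
    for iv in rep_a:
        if iv.chrom not in starts_ends:
            continue
        starts, ends = starts_ends[iv.chrom]
        # any b-peak with start < iv.end and end > iv.start
        i = np.searchsorted(starts, iv.end, side="left")
        if np.any(ends[:i] > iv.start):
            out.append(iv)
    return out


def merge_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping (not merely adjacent) intervals per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_s, cur_e = spans[0].start, spans[0].end
        for iv in spans[1:]:
            if iv.start < cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def summit_regions(peaks: Sequence[GenomicInterval], flank: int = 200,
                   chrom_sizes: dict[str, int] | None = None
                   ) -> list[GenomicInterval]:
    """Fixed-width regions centred at peak summits, clipped and merged.

    Each peak contributes [summit - flank, summit + flank); peaks without a
    recorded summit use their midpoint.  Overlapping regions are merged.
    """
    regions = []
    for p in peaks:
        c = p.center
        start = max(0, c - flank)
        end = c + flank
        if chrom_sizes is not None and p.chrom in chrom_sizes:
            end = min(end, chrom_sizes[p.chrom])
        if end > start:
            regions.append(GenomicInterval(p.chrom, start, end))
    return merge_intervals(regions)


def shuffle_intervals(intervals: Sequence[GenomicInterval],
                      chrom_sizes: dict[str, int],
                      exclude: Sequence[GenomicInterval] = (),
                      seed: int = 0, max_tries: int = 1000
                      ) -> list[GenomicInterval]:
    """Randomly re-place each interval on its own chromosome.

    Placement is uniform, length-preserving, pairwise non-overlapping and
    disjoint from ``exclude`` (the behaviour of ``shuffleBed -chrom
    -noOverlapping -excl``).  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    excl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in exclude:
        excl_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    placed_by_chrom: dict[str, list[tuple[int, int]]] = {
        c: sorted(v) for c, v in excl_by_chrom.items()}

    def collides(chrom: str, s: int, e: int) -> bool:
        return any(s < pe and ps < e
                   for ps, pe in placed_by_chrom.get(chrom, ()))

    out: list[GenomicInterval] = []
    for iv in intervals:
        if iv.chrom not in chrom_sizes:
            raise ValidationError(f"no size for chromosome {iv.chrom}")
        size = chrom_sizes[iv.chrom]
        length = len(iv)
        if length > size:
            raise ValidationError(f"interval longer than {iv.chrom}")
        for _ in range(max_tries):
            s = int(rng.integers(0, size - length + 1))
            if not collides(iv.chrom, s, s + length):
                placed_by_chrom.setdefault(iv.chrom, []).append((s, s + length))
                out.append(GenomicInterval(iv.chrom, s, s + length,
                                           name=iv.name, strand=iv.strand))
                break
        else:
            raise ValidationError(
                f"could not place a {length}-bp interval on {iv.chrom} "
                f"after {max_tries} tries")
    return out


def motif_count_histogram(hits: Sequence[MotifHit],
                          regions: Sequence[GenomicInterval],
                          cap: int = 10):
    """Per-region motif counts, the count histogram and the multi-motif rate.

    A hit is assigned to a region iff its midpoint lies inside the region
    (regions are assumed non-overlapping, e.g. post-merge).  Returns
    ``(counts, histogram, multi_fraction)`` where ``histogram`` maps count
    values 0..cap (the last bin pooling >= cap) to region numbers and
    ``multi_fraction`` is the fraction of regions with >= 2 hits.
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end, idx))
    lookup = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        lookup[chrom] = (np.array([s for s, _, _ in spans]),
                         np.array([e for _, e, _ in spans]),
                         np.array([i for _, _, i in spans]))
    counts = np.zeros(len(regions), dtype=int)
    for h in hits:
        chrom = h.interval.chrom
        if chrom not in lookup:
            continue
        mid = h.interval.midpoint
        starts, ends, idxs = lookup[chrom]
        j = np.searchsorted(starts, mid, side="right") - 1
        if j >= 0 and mid < ends[j]:
            counts[idxs[j]] += 1
    histogram = {k: int(np.sum(counts == k)) for k in range(cap)}
    histogram[cap] = int(np.sum(counts >= cap))
    multi_fraction = float(np.mean(counts >= 2)) if len(regions) else 0.0
    return counts, histogram, multi_fraction
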