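"""Insulation scoring of binned contact data and anchor-group signal summaries.

Two insulation statistics are provided, matching the two conventions used in
boundary analyses of ChIA-PET/Hi-C data:

* a per-bin directionality-style score — the log2 ratio of upstream to
  downstream contact frequency within a fixed genomic window (default
  400 kb) on 40-kb bins (`insulation_profile`); and
* a per-loop ratio of contact mass retained within the loop span to contact
  mass crossing its anchors (`loop_within_across_ratio`).

Anchors can then be ranked into k near-equal groups by insulation strength
and their ChIP signal summarized per group for violin-style comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ContactRecord, GenomicInterval, SignalTrack, ValidationError


@dataclass
class ContactMatrix:
    """Symmetric binned intrachromosomal interaction-count matrix."""

    chrom: str
    bin_size: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError("counts must be a square matrix")
        if not np.allclose(self.counts, self.counts.T):
            raise ValidationError("contact matrix must be symmetric")
        if np.any(self.counts < 0):
            raise ValidationError("contact counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def bin_of(self, pos: int) -> int:
        return pos // self.bin_size


@dataclass
class InsulationProfile:
    """Per-bin insulation scores; NaN where a full window does not fit."""

    chrom: str
    bin_size: int
    window_bp: int
    pseudocount: float
    scores: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.scores)

    def score_at(self, pos: int) -> float:
        b = pos // self.bin_size
        if b < 0 or b >= len(self.scores):
            return np.nan
        return float(self.scores[b])


@dataclass
class AnchorGrouping:
    """Anchors split into k near-equal groups, group 1 = highest insulation."""

    anchors: list[GenomicInterval]
    group: np.ndarray             # int 1..k per retained anchor
    anchor_score: np.ndarray
    n_dropped: int = 0

    @property
    def k(self) -> int:
        return int(self.group.max()) if len(self.group) else 0


def bin_contacts(contacts: list[ContactRecord], bin_size: int,
                 chrom_sizes: dict[str, int]) -> dict[str, ContactMatrix]:
    """Aggregate PETs onto per-chromosome bin matrices.

    Each anchor is assigned to the bin containing its midpoint; the record's
    count is added symmetrically.  Interchromosomal records are excluded.
    """
    if bin_size <= 0:
        raise ValidationError("bin_size must be positive")
    mats = {chrom: np.zeros((int(np.ceil(size / bin_size)),) * 2)
            for chrom, size in chrom_sizes.items()}
    n_inter = 0
    for rec in contacts:
        if not rec.is_intrachromosomal:
            n_inter += 1
            continue
        if rec.chrom_a not in mats:
            raise ValidationError(f"unknown chromosome {rec.chrom_a}")
        size = chrom_sizes[rec.chrom_a]
        mid_a = (rec.start_a + rec.end_a) // 2
        mid_b = (rec.start_b + rec.end_b) // 2
        if mid_a >= size or mid_b >= size:
            raise ValidationError(
                f"anchor beyond {rec.chrom_a} length {size}: {rec}")
        i, j = mid_a // bin_size, mid_b // bin_size
        m = mats[rec.chrom_a]
        m[i, j] += rec.count
        if i != j:
            m[j, i] += rec.count
    if n_inter:
        warnings.warn(f"excluded {n_inter} interchromosomal records")
    return {chrom: ContactMatrix(chrom, bin_size, m)
            for chrom, m in mats.items()}


def insulation_profile(matrix: ContactMatrix, window_bp: int = 400_000,
                       pseudocount: float = 1.0) -> InsulationProfile:
    """log2 of upstream vs downstream contact frequency per bin.

    For bin i with a full window on both sides,
    ``score(i) = log2((up + psi) / (down + psi))`` with
    ``up = sum_{d=1..w} counts[i-d, i]`` and ``down = sum_{d=1..w}
    counts[i, i+d]``, ``w = window_bp / bin_size``.  Distances run strictly
    from 1 to w bins, i.e. contacts below the window span, excluding the
    self-bin.  Edge bins where the window does not fit are NaN.
    """
    if window_bp % matrix.bin_size != 0:
        raise ValidationError("window_bp must be a multiple of bin_size")
    w = window_bp // matrix.bin_size
    if w < 1:
        raise ValidationError("window must cover at least one bin")
    B = matrix.n_bins
    scores = np.full(B, np.nan)
    if B < 2 * w + 1:
        warnings.warn(
            f"matrix has {B} bins < 2w+1 = {2 * w + 1}; all scores undefined")
        return InsulationProfile(matrix.chrom, matrix.bin_size, window_bp,
                                 pseudocount, scores)
    c = matrix.counts
    for i in range(w, B - w):
        up = c[i - w:i, i].sum()
        down = c[i, i + 1:i + w + 1].sum()
        scores[i] = np.log2((up + pseudocount) / (down + pseudocount))
    return InsulationProfile(matrix.chrom, matrix.bin_size, window_bp,
                             pseudocount, scores)


def call_boundary(profile: InsulationProfile) -> int:
    """Strongest boundary bin index implied by the insulation profile.

    The directionality-style score is extreme on both flanks of a boundary:
    positive on the last bin of the upstream block (contacts point up),
    negative on the first bin of the downstream block.  The strongest
    |score| bin i therefore marks the boundary at i+1 when score(i) > 0
    and at i when score(i) < 0, i.e. the first bin of the new block.
    """
    if not profile.defined.any():
        raise ValidationError("profile has no defined bins")
    i = int(np.nanargmax(np.abs(profile.scores)))
    return i + 1 if profile.scores[i] > 0 else i


def loop_within_across_ratio(matrix: ContactMatrix,
                             left: GenomicInterval, right: GenomicInterval,
                             pseudocount: float = 1.0) -> float:
    """Contact mass inside a loop relative to mass crossing its anchors.

    ``(sum of counts with both bins strictly inside the loop span + psi) /
    (sum of counts with exactly one bin inside + psi)``.  Anchor bins
    themselves delimit the span and are not "inside".
    """
    if left.chrom != matrix.chrom or right.chrom != matrix.chrom:
        raise ValidationError("loop anchors must be on the matrix chromosome")
    la = matrix.bin_of(left.midpoint)
    lb = matrix.bin_of(right.midpoint)
    if lb <= la:
        raise ValidationError("right anchor must lie beyond the left anchor")
    if lb - la < 2:
        raise ValidationError("loop spans no interior bins (zero-width)")
    inside = np.arange(la + 1, lb)
    mask = np.zeros(matrix.n_bins, dtype=bool)
    mask[inside] = True
    c = matrix.counts
    within = c[np.ix_(inside, inside)][np.triu_indices(len(inside))].sum()
    across = c[np.ix_(inside, ~mask)].sum()
    return float((within + pseudocount) / (across + pseudocount))


def rank_anchors(anchors: list[GenomicInterval], profile: InsulationProfile,
                 k: int = 5, mode: str = "abs") -> AnchorGrouping:
    """Split anchors into k near-equal groups by insulation strength.

    ``anchor_score`` is the profile score at each anchor's midpoint bin
    (absolute value when ``mode='abs'``); group 1 holds the highest scores.
    Anchors on undefined bins are dropped with a warning.
    """
    if mode not in ("abs", "signed"):
        raise ValueError("mode must be 'abs' or 'signed'")
    kept: list[GenomicInterval] = []
    scores: list[float] = []
    n_dropped = 0
    for a in anchors:
        s = profile.score_at(a.midpoint)
        if np.isnan(s):
            n_dropped += 1
            continue
        kept.append(a)
        scores.append(abs(s) if mode == "abs" else s)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} anchors in undefined bins")
    grouping = group_by_score(kept, np.asarray(scores), k=k)
    grouping.n_dropped = n_dropped
    return grouping


def group_by_score(anchors: list[GenomicInterval], scores: np.ndarray,
                   k: int = 5) -> AnchorGrouping:
    """Quantile-split anchors into k near-equal groups, group 1 = highest.

    Ties keep input order (stable sort), so group sizes always differ by
    at most one.
    """
    score_arr = np.asarray(scores, dtype=float)
    if len(score_arr) != len(anchors):
        raise ValidationError("scores and anchors must align")
    order = np.argsort(-score_arr, kind="stable")
    groups = np.empty(len(anchors), dtype=int)
    for g, chunk in enumerate(np.array_split(order, k), start=1):
        groups[chunk] = g
    return AnchorGrouping(anchors=list(anchors), group=groups,
                          anchor_score=score_arr)


def group_signal_summary(grouping: AnchorGrouping, signal: SignalTrack):
    """Per-group distribution of mean ChIP signal over each anchor interval.

    Returns {group: {"n", "mean", "median", "q1", "q3", "values"}}; empty
    groups map to None.
    """
    values_by_group: dict[int, list[float]] = {g: [] for g in
                                               range(1, grouping.k + 1)}
    for anchor, g in zip(grouping.anchors, grouping.group):
        v = signal.mean_over(anchor.chrom, anchor.start, anchor.end)
        values_by_group[int(g)].append(v)
    out = {}
    for g, vals in values_by_group.items():
        if not vals:
            out[g] = None
            continue
        arr = np.asarray(vals)
        out[g] = {"n": len(arr), "mean": float(arr.mean()),
                  "median": float(np.median(arr)),
                  "q1": float(np.percentile(arr, 25)),
                  "q3": float(np.percentile(arr, 75)),
                  "values": arr}
    return out
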