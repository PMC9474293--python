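"""Depth normalization and metagene (reference-point) signal profiling.

Signal around a cohort of regions is summarized as a regions x bins matrix:
each region is aligned at its center (summit when available) and the track
averaged in fixed-width bins across center +/- flank, then column-averaged
into one profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import GenomicInterval, SignalTrack, ValidationError


@dataclass
class MetageneMatrix:
    """Per-region binned signal around aligned centers plus the mean profile."""

    matrix: np.ndarray            # regions x bins
    mask: np.ndarray              # True where the bin fell off-chromosome
    bin_bp: int
    flank_bp: int
    offsets: np.ndarray           # bin-center offsets from the region center

    @property
    def profile(self) -> np.ndarray:
        """Column means over regions, masked bins excluded."""
        m = np.ma.masked_array(self.matrix, mask=self.mask)
        prof = m.mean(axis=0)
        return np.asarray(prof.filled(np.nan))


def normalize_rpm(track: SignalTrack, bin_bp: int = 50) -> SignalTrack:
    """Divide per-bin read counts by millions of mapped reads (RPM).

    The track is resampled onto fixed ``bin_bp`` bins (coverage-weighted
    means of the raw counts) before scaling, so tracks with irregular
    intervals normalize identically to pre-binned ones.
    """
    if track.mapped_read_count is None:
        raise ValidationError("normalize_rpm requires mapped_read_count")
    factor = 1.0 / (track.mapped_read_count / 1e6)
    rows = []
    for chrom in track.chroms:
        starts, ends, _ = track.chrom_arrays(chrom)
        span_end = int(ends[-1])
        for b0 in range(0, span_end, bin_bp):
            b1 = min(b0 + bin_bp, span_end)
            v = track.mean_over(chrom, b0, b1)
            if v != 0.0:
                rows.append((chrom, b0, b1, v * factor))
    return SignalTrack(rows, mapped_read_count=track.mapped_read_count)


def metagene(track: SignalTrack, regions: Sequence[GenomicInterval],
             flank_bp: int = 5000, bin_bp: int = 50,
             chrom_sizes: dict[str, int] | None = None) -> MetageneMatrix:
    """Average signal in bins across each region center +/- flank.

    Columns are ``2*flank_bp/bin_bp + 1`` bins whose centers run from
    -flank to +flank in steps of ``bin_bp``; each entry is the mean track
    value over ``[center + offset - bin_bp/2, center + offset + bin_bp/2)``.
    Bins falling off the chromosome are masked, and regions on chromosomes
    absent from ``chrom_sizes`` (when given) are dropped with a warning.
    """
    if flank_bp % bin_bp != 0:
        raise ValidationError("flank_bp must be a multiple of bin_bp")
    n_bins = 2 * flank_bp // bin_bp + 1
    offsets = np.arange(-flank_bp, flank_bp + 1, bin_bp)
    half = bin_bp // 2
    kept = []
    for r in regions:
        if chrom_sizes is not None and r.chrom not in chrom_sizes:
            warnings.warn(f"dropping region on unknown chromosome {r.chrom}")
            continue
        kept.append(r)
    matrix = np.zeros((len(kept), n_bins))
    mask = np.zeros((len(kept), n_bins), dtype=bool)
    for i, r in enumerate(kept):
        center = r.center
        limit = chrom_sizes.get(r.chrom) if chrom_sizes else None
        for j, off in enumerate(offsets):
            b0 = center + int(off) - half
            b1 = b0 + bin_bp
            if b0 < 0 or (limit is not None and b1 > limit):
                mask[i, j] = True
                continue
            matrix[i, j] = track.mean_over(r.chrom, b0, b1)
    return MetageneMatrix(matrix=matrix, mask=mask, bin_bp=bin_bp,
                          flank_bp=flank_bp, offsets=offsets)
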