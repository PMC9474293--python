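"""Ground-truth synthetic inputs for every pipeline stage.

Each generator emulates the statistical structure of one real input class —
genomes with planted motif arrays, distance-decaying contact maps with
planted boundaries, anchor cohorts whose ChIP signal tracks a latent
insulation value, variant catalogs with a planted substitution spectrum and
positional hotspots, noisy exponential FRAP recoveries, nuclei with planted
Gaussian foci, and kymographs with a planted compaction slope — and returns
a :class:`TruthBundle` pairing the artifact with the planted parameters.

Every generator derives its own named pseudorandom stream from the single
integer seed, so adding a generator never perturbs the draws of another and
the same (seed, parameters) always reproduce the identical artifact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np

from .io import (BASES, ContactRecord, GenomicInterval, ImageStack,
                 PositionFrequencyMatrix, SignalTrack, ValidationError)

# stable per-generator stream ids (never reorder; append only)
_STREAMS = {
    "genome": 1, "contacts": 2, "anchors": 3, "variants": 4,
    "frap": 5, "nucleus": 6, "kymograph": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class TruthBundle:
    """A generated artifact plus the record of its planted parameters."""

    artifact: Any
    truth: dict[str, Any]
    seed: int


class CapacityError(RuntimeError):
    """Requested objects do not fit in the available space."""


# ---------------------------------------------------------------------------
# genomes with planted motif arrays
# ---------------------------------------------------------------------------

def synth_genome_with_arrays(seed: int, n_chrom: int, chrom_len_bp: int,
                             pfm: PositionFrequencyMatrix,
                             array_sizes: Sequence[int], n_sites: int,
                             gc: float = 0.41, spacing_bp: int = 10,
                             max_tries: int = 200) -> TruthBundle:
    """Random genome with ``n_sites`` planted motif arrays.

    Each site holds k consecutive motif instances (k drawn uniformly from
    ``array_sizes``) separated by ``spacing_bp`` of background, each
    instance sampled from the PFM's per-position base distributions with an
    independent random strand.  Background bases are i.i.d. with the given
    GC content.  Truth is a BED-like list of every planted instance.
    """
    rng = _rng(seed, "genome")
    L = len(pfm)
    probs = pfm.counts / pfm.counts.sum(axis=1, keepdims=True)
    bg_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    genome = {c: rng.choice(list(BASES), size=chrom_len_bp, p=bg_p)
              for c in chrom_names}
    max_k = max(array_sizes)
    site_span = max_k * L + (max_k - 1) * spacing_bp
    if site_span + 2 > chrom_len_bp:
        raise CapacityError("chromosomes too short for the requested arrays")

    hits: list[GenomicInterval] = []
    site_regions: list[GenomicInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for s in range(n_sites):
        k = int(array_sizes[rng.integers(0, len(array_sizes))])
        span = k * L + (k - 1) * spacing_bp
        for attempt in range(max_tries):
            chrom = chrom_names[int(rng.integers(0, n_chrom))]
            start = int(rng.integers(0, chrom_len_bp - span + 1))
            pad = 2 * L  # keep planted sites separated so regions stay distinct
            if all(start - pad >= e or start + span + pad <= b
                   for b, e in occupied[chrom]):
                break
        else:
            raise CapacityError(
                f"could not place site {s} after {max_tries} tries")
        occupied[chrom].append((start, start + span))
        pos = start
        for _ in range(k):
            inst = "".join(BASES[int(rng.choice(4, p=probs[i]))]
                           for i in range(L))
            strand = "+" if rng.random() < 0.5 else "-"
            planted = inst if strand == "+" else \
                "".join(comp[b] for b in reversed(inst))
            genome[chrom][pos:pos + L] = list(planted)
            hits.append(GenomicInterval(chrom, pos, pos + L, strand=strand))
            pos += L + spacing_bp
        site_regions.append(GenomicInterval(chrom, start, start + span,
                                            name=f"site{s}"))
    fasta = {c: "".join(genome[c]) for c in chrom_names}
    return TruthBundle(
        artifact=fasta,
        truth={"hits": hits, "sites": site_regions,
               "chrom_sizes": {c: chrom_len_bp for c in chrom_names}},
        seed=seed)


# ---------------------------------------------------------------------------
# contact maps with planted boundaries
# ---------------------------------------------------------------------------

def synth_contact_map(seed: int, n_bins: int, bin_size: int = 40_000,
                      boundaries: Sequence[int] = (), p_intra: float = 1.0,
                      p_inter: float = 0.25, decay_exponent: float = 1.0,
                      base_count: float = 100.0, chrom: str = "chr1"
                      ) -> TruthBundle:
    """Poisson block-model contact list with distance decay.

    Expected count between bins i != j is
    ``base_count * p * |i-j|**(-decay_exponent)`` where p = ``p_intra`` if
    the bins share a boundary-delimited block, else ``p_inter``.  Counts are
    independent Poisson draws, emitted as one ContactRecord per bin pair
    (symmetry by construction when binned).
    """
    if n_bins < 3:
        raise ValidationError("need at least 3 bins")
    if not (0 < p_inter <= p_intra):
        raise ValidationError("require 0 < p_inter <= p_intra")
    boundaries = sorted(boundaries)
    if any(b < 1 or b > n_bins - 1 for b in boundaries):
        raise ValidationError("boundaries must lie strictly inside the map")
    rng = _rng(seed, "contacts")
    block = np.zeros(n_bins, dtype=int)
    for b in boundaries:
        block[b:] += 1
    records: list[ContactRecord] = []
    expected = np.zeros((n_bins, n_bins))
    for i in range(n_bins):
        for j in range(i + 1, n_bins):
            p = p_intra if block[i] == block[j] else p_inter
            lam = base_count * p * float(j - i) ** (-decay_exponent)
            expected[i, j] = expected[j, i] = lam
            c = int(rng.poisson(lam))
            if c > 0:
                records.append(ContactRecord(
                    chrom, i * bin_size, (i + 1) * bin_size,
                    chrom, j * bin_size, (j + 1) * bin_size, count=c))
    return TruthBundle(
        artifact=records,
        truth={"boundaries": list(boundaries), "expected": expected,
               "bin_size": bin_size, "n_bins": n_bins,
               "chrom_sizes": {chrom: n_bins * bin_size}},
        seed=seed)


# ---------------------------------------------------------------------------
# anchor cohorts with signal coupled to latent insulation
# ---------------------------------------------------------------------------

def synth_anchor_cohort(seed: int, n_anchors: int, coupling_slope: float,
                        noise_sd: float, anchor_bp: int = 400,
                        chrom: str = "chr1") -> TruthBundle:
    """Anchors with latent insulation u ~ U(0,1) and log-linear ChIP signal.

    signal = exp(coupling_slope * u + eps), eps ~ N(0, noise_sd).  The
    anchors tile the chromosome with fixed spacing; the artifact is
    (anchors, SignalTrack constant over each anchor), truth records u.
    """
    if n_anchors < 10:
        raise ValidationError("need at least 10 anchors")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    rng = _rng(seed, "anchors")
    u = rng.uniform(0.0, 1.0, size=n_anchors)
    eps = rng.normal(0.0, noise_sd, size=n_anchors) if noise_sd > 0 else \
        np.zeros(n_anchors)
    signal = np.exp(coupling_slope * u + eps)
    spacing = 4 * anchor_bp
    anchors = [GenomicInterval(chrom, i * spacing, i * spacing + anchor_bp,
                               name=f"anchor{i}")
               for i in range(n_anchors)]
    track = SignalTrack([(a.chrom, a.start, a.end, float(v))
                         for a, v in zip(anchors, signal)])
    return TruthBundle(artifact=(anchors, track),
                       truth={"u": u, "signal": signal}, seed=seed)


# ---------------------------------------------------------------------------
# variant catalogs
# ---------------------------------------------------------------------------

def synth_variant_catalog(seed: int, tf_table: dict[str, int], n_variants: int,
                          spectrum: dict[str, float],
                          hotspot: tuple[str, int, float] | None = None,
                          tissues: Sequence[str] = ("breast", "colon", "lung"),
                          ) -> TruthBundle:
    """Variant TSV rows with a planted substitution spectrum and hotspot.

    ``tf_table`` maps gene -> protein length.  Substitution types are drawn
    multinomially from ``spectrum`` (proportions summing to 1); genes and
    tissues uniformly; positions uniformly within the protein except that a
    ``(gene, pos, weight)`` hotspot up-weights one residue by ``weight``
    relative to each other residue of that gene.  The artifact is a list of
    (gene, hgvs_p, tissue) rows ready to write as a TSV.
    """
    total = sum(spectrum.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError("spectrum proportions must sum to 1")
    if hotspot is not None and hotspot[0] not in tf_table:
        raise ValidationError(f"hotspot gene {hotspot[0]!r} not in tf_table")
    rng = _rng(seed, "variants")
    genes = sorted(tf_table)
    types = sorted(spectrum)
    type_p = np.array([spectrum[t] for t in types])
    type_draws = rng.choice(len(types), size=n_variants, p=type_p)
    gene_draws = rng.choice(len(genes), size=n_variants)
    tissue_draws = rng.choice(len(tissues), size=n_variants)
    rows = []
    for ti, gi, si in zip(type_draws, gene_draws, tissue_draws):
        gene = genes[gi]
        length = tf_table[gene]
        weights = np.ones(length)
        if hotspot is not None and gene == hotspot[0]:
            weights[hotspot[1] - 1] = hotspot[2]
        pos = int(rng.choice(length, p=weights / weights.sum())) + 1
        ref, alt = types[ti].split(">")
        rows.append((gene, f"p.{ref}{pos}{alt}", tissues[si]))
    return TruthBundle(
        artifact=rows,
        truth={"spectrum": dict(spectrum), "hotspot": hotspot,
               "n_variants": n_variants}, seed=seed)


def write_variant_tsv(rows: Sequence[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\thgvs_p\ttissue\n")
        for gene, hgvs, tissue in rows:
            fh.write(f"{gene}\t{hgvs}\t{tissue}\n")


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------

def synth_frap_trace(seed: int, Ipre: float = 1.0, Io: float = 0.2,
                     Mf: float = 0.8, tau_s: float = 5.0, dt_s: float = 1.0,
                     n_points: int = 60, noise_sd: float = 0.0,
                     n_pre: int = 3) -> TruthBundle:
    """Noisy single-exponential FRAP recovery with known parameters.

    Pre-bleach samples sit at ``Ipre``; after the bleach at t = 0,
    I(t) = Io + Mf (Ipre - Io)(1 - exp(-t/tau)) + eps.
    """
    if Io > Ipre:
        raise ValidationError("Io must not exceed Ipre")
    if not (0.0 <= Mf <= 1.0):
        raise ValidationError("Mf must lie in [0, 1]")
    if tau_s <= 0:
        raise ValidationError("tau must be positive")
    rng = _rng(seed, "frap")
    t_pre = -dt_s * np.arange(n_pre, 0, -1)
    t_post = dt_s * np.arange(n_points)
    t = np.concatenate([t_pre, t_post])
    clean = np.where(
        t < 0, Ipre,
        Io + Mf * (Ipre - Io) * (1.0 - np.exp(-np.maximum(t, 0) / tau_s)))
    noisy = clean + (rng.normal(0.0, noise_sd, size=t.shape)
                     if noise_sd > 0 else 0.0)
    return TruthBundle(
        artifact=(t, noisy),
        truth={"Ipre": Ipre, "Io": Io, "Mf": Mf, "tau_s": tau_s,
               "Ie": Io + Mf * (Ipre - Io)}, seed=seed)


# ---------------------------------------------------------------------------
# nuclei with planted foci
# ---------------------------------------------------------------------------

def synth_nucleus_stack(seed: int, shape: tuple[int, int, int] = (16, 64, 64),
                        n_foci: int = 3, focus_sigma_vox: float = 1.5,
                        focus_amplitude: float = 500.0,
                        background: float = 20.0,
                        noise_model: str = "gaussian",
                        noise_sd: float = 5.0, max_tries: int = 500
                        ) -> TruthBundle:
    """Image stack with ``n_foci`` 3D Gaussian bumps over flat background.

    Centroids keep a >= 2 sigma margin from the borders and >= 4 sigma
    pairwise separation.  ``noise_model`` is 'gaussian' (read noise of SD
    ``noise_sd``) or 'poisson' (shot noise on the clean image).
    """
    if noise_model not in ("gaussian", "poisson", "none"):
        raise ValidationError("noise_model must be gaussian, poisson or none")
    rng = _rng(seed, "nucleus")
    sz = np.array(shape, dtype=float)
    margin = 2.0 * focus_sigma_vox
    if np.any(sz - 2 * margin <= 0) and n_foci > 0:
        raise CapacityError("stack too small for the focus margin")
    centers: list[np.ndarray] = []
    for _ in range(n_foci):
        for _ in range(max_tries):
            c = rng.uniform(margin, sz - margin)
            if all(np.linalg.norm(c - o) >= 4.0 * focus_sigma_vox
                   for o in centers):
                centers.append(c)
                break
        else:
            raise CapacityError("could not place foci with the required "
                                "separation")
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    clean = np.full(shape, background, dtype=float)
    for c in centers:
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        clean += focus_amplitude * np.exp(-d2 / (2.0 * focus_sigma_vox ** 2))
    if noise_model == "gaussian":
        img = clean + rng.normal(0.0, noise_sd, size=shape)
    elif noise_model == "poisson":
        img = rng.poisson(clean).astype(float)
    else:
        img = clean
    img = np.clip(img, 0, None)
    return TruthBundle(
        artifact=ImageStack(data=img),
        truth={"centroids": [tuple(c) for c in centers],
               "sigma_vox": focus_sigma_vox, "amplitude": focus_amplitude,
               "background": background}, seed=seed)


# ---------------------------------------------------------------------------
# kymographs with planted compaction
# ---------------------------------------------------------------------------

def synth_kymograph(seed: int, n_frames: int = 50, n_pix: int = 500,
                    rate_nm_s: float = 871.0, pixel_nm: float = 100.0,
                    dt_s: float = 1.0, noise_sd: float = 0.0,
                    dna_intensity: float = 100.0, background: float = 5.0,
                    start_px: float | None = None) -> TruthBundle:
    """Kymograph of a DNA end retreating toward the anchor at a fixed rate.

    DNA occupies pixels [0, end(t)] with end(t) = end(0) - rate*t/pixel_nm;
    intensity is ``dna_intensity`` inside, ``background`` outside, plus
    Gaussian noise of SD ``noise_sd`` (as a fraction of dna_intensity when
    < 1, absolute otherwise — pass the absolute value directly for clarity).
    """
    if start_px is None:
        start_px = n_pix - 5
    end_final = start_px - rate_nm_s * (n_frames - 1) * dt_s / pixel_nm
    if end_final < 1:
        raise ValidationError("rate too high: DNA end leaves the kymograph "
                              "within the frame count")
    rng = _rng(seed, "kymograph")
    img = np.full((n_frames, n_pix), background, dtype=float)
    ends = np.empty(n_frames)
    for f in range(n_frames):
        end = start_px - rate_nm_s * f * dt_s / pixel_nm
        ends[f] = end
        img[f, : int(np.floor(end)) + 1] = dna_intensity
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
        img = np.clip(img, 0, None)
    from .kinetics import Kymograph

    return TruthBundle(
        artifact=Kymograph(intensity=img, pixel_nm=pixel_nm, dt_s=dt_s),
        truth={"rate_nm_s": rate_nm_s, "end_px": ends,
               "start_px": start_px}, seed=seed)
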