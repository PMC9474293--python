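# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators emulate, and the known
limits of both.

## Coordinate and format conventions

All genomic coordinates are 0-based, half-open (BED convention) throughout.
narrowPeak summit columns are offsets from the interval start, with −1
meaning "no summit"; operations needing a region center use the summit when
present and the interval midpoint otherwise. Signal lives in text bedGraph
tracks (step functions; uncovered positions are 0); contacts in BEDPE with
an optional eighth column holding the paired-end-tag (PET) count, defaulting
to 1. Binary track and alignment formats are deliberately out of scope: the
pipeline consumes already-called intervals, contacts and tracks.

## Contact insulation

Contacts are aggregated onto per-chromosome square matrices of `bin_size`
bp (default 40 kb); each anchor maps to the bin containing its midpoint (the
source convention does not resolve anchors spanning bins, so midpoint
assignment is the deterministic choice), and interchromosomal records are
excluded with a warning.

The per-bin score is a directionality-index-style statistic:

    score(i) = log2( (up(i) + ψ) / (down(i) + ψ) ),
    up(i)   = Σ_{d=1..w} counts[i−d, i],
    down(i) = Σ_{d=1..w} counts[i, i+d],   w = window_bp / bin_size.

Distances run strictly from 1 to w bins — the window covers contacts below
the window span, excluding the self-bin. The default window is 400 kb
(w = 10 at 40-kb bins). A pseudocount ψ (default 1) guards against empty
flanks; with ψ = 0 the score is the pure log-ratio and adding a constant to
every cell shrinks all scores toward zero without crossing sign. Bins
without a full window on both sides are undefined (NaN).

Because the statistic is antisymmetric, a sharp boundary produces a
positive extreme on its upstream flank and a negative extreme on its
downstream flank. `call_boundary` therefore reports bin i+1 when the
strongest |score| bin i is positive and bin i itself when negative, i.e.
always the first bin of the downstream block.

A second, loop-level statistic is the within/across ratio: contact mass
with both bins strictly between the anchor bins over mass crossing exactly
one anchor, each plus ψ. Both statistics are provided because both
conventions appear in boundary analyses; anchor ranking accepts either.

Anchors are ranked by |score| at their midpoint bin by default (a boundary
insulates in either orientation; signed mode is retained for audit) and
quantile-split into k = 5 near-equal groups with stable tie-breaking, group
1 highest. Group summaries report n, mean, median, quartiles and the raw
per-anchor mean signal values for violin-style plots.

## Motif arrays

PWMs are log2-odds matrices built from JASPAR count matrices with a
background-weighted pseudocount (default 0.8 split by background
probability; background defaults to uniform 0.25). The bundled MA0139.1
matrix has 19 positions.

Scanning scores every length-L window on both strands (the minus strand via
the reverse-complemented matrix), keeps all hits at or above threshold
(no greedy masking), skips windows containing N, and reports coordinates on
the plus strand. Hit significance uses the exact score distribution under
the i.i.d. background model, computed by position-wise convolution of the
per-base score masses on a δ-discretized grid (δ = 10⁻³ score units by
default). Discretization convention: per-position rounding can displace a
summed score by up to L/2 grid cells, so the p-value is inclusive by that
margin — it never undercounts mass at or above the query score, and
overcounts by at most the mass within ~L·δ score units below it. Thresholds
can be stated as a raw log-odds score or as a maximum p-value
(minimum −log10 p) through the distribution's inversion.

Peak-set operations follow the standard ChIP-seq post-processing recipe:
replicate-consistent peaks are reference peaks sharing ≥ 1 bp with the
other replicate (half-open intervals, so abutting peaks share 0 bp);
binding-site regions are summit ± 200 bp (400 bp total), clipped to the
chromosome and merged when overlapping. Motif counting assigns a hit to a
region iff the hit's midpoint lies inside it, avoiding double counting at
region borders, and reports the count histogram plus the fraction of
regions with ≥ 2 motifs (the "motif array" fraction).

The shuffled null re-places each interval uniformly at random on its own
chromosome, preserving length, forbidding pairwise overlap and overlap with
an exclusion set (the behaviour of `shuffleBed -chrom -noOverlapping
-excl`), by bounded rejection sampling from a seeded generator. Count and
length multiset conservation per chromosome is asserted in tests on every
run.

## Signal profiles

Depth normalization resamples a track onto fixed 50-bp bins
(coverage-weighted means) and divides by millions of mapped reads (RPM).
Metagene profiles use reference-point mode: 2·flank/bin + 1 bins whose
centers run from −flank to +flank (defaults ± 5 kb at 50 bp → 201 columns),
each holding the mean track value over a bin-width window; bins off the
chromosome are masked and excluded from the column means rather than
zero-filled, to avoid edge artefacts. Profiles are linear in the track and
equivariant under joint translation of track and regions, both asserted as
property tests.

## Mutation spectrum

HGVS.p strings are parsed with 1- or 3-letter codes; nonsense, synonymous,
frameshift, indel and unparseable notations are rejected with a category
label and reported in a sidecar table, never silently dropped — the
analyses use strictly missense events. The annotation table must carry one
representative protein per gene (duplicates are an input error); variants
beyond the annotated protein length are flagged inconsistent and excluded
from counts, and the partition dbd/non-dbd/inconsistent/unmatched conserves
the input count.

The substitution spectrum treats each transcription factor (or cancer
type) as one unit: contribution(X>Y | unit) = count/unit total, and the
report is the mean ± SD of contributions across units with the top-k types
by mean (k = 9 by default). Per-unit normalization makes the spectrum
invariant to variant order and to duplicating a whole unit. Rankings sort
by count descending with alphabetical tie-break; tissue stratification
gives the most-mutated tissues (default 10 panels) their own sub-rankings.
Hotspot landscapes are per-residue counts with ties broken by ascending
position.

## Foci imaging

Foci are connected components of the voxel set {I ≥ threshold} (threshold
inclusive), default 26-connectivity in 3D with 6 and 18 available, filtered
to ≥ min_voxels (default 10) — so a 9-voxel blob is always rejected at the
default. Per-focus statistics are voxel count, intensity-weighted centroid,
total and peak intensity. Fold changes of per-cell focus counts use the
equal-variance two-tailed Student t (Welch behind a flag); the
implementation is cross-checked in tests against a hand-computed worked
pair and calibrated for type-I error under the null.

Point enrichment realizes a "0.9 µm² around the focus center" window as the
axis-aligned square of side √0.9 µm rounded to the nearest odd pixel count,
clipped at image borders, divided by the mean over the nuclear mask. The
phase-shifted fraction is supra-threshold area within the nucleus over
nuclear area. Line profiles sample bilinear interpolation at ≤ 1-pixel
spacing on a common distance axis per channel. Nuclear masks are inputs,
with a simple Otsu fallback — nucleus segmentation is intentionally
minimal.

## Kinetics

FRAP traces carry ≥ 3 pre-bleach samples with the bleach at t = 0. Double
normalization divides the background-subtracted bleached-ROI signal by the
background-subtracted reference ROI (cancelling acquisition bleaching
common to both, verified by a linear-decay property test) and scales by the
pre-bleach mean of the same ratio, so pre-bleach maps to ≈ 1. The recovery
is fitted by least squares to

    I(t) = Io + (Ie − Io)(1 − e^(−t/τ)),

with t1/2 = τ·ln 2, Mf = (Ie − Io)/(Ipre − Io) using the fitted plateau Ie
(not the last sample, since recoveries can be incomplete within the
acquisition), and the circular-bleach half-time approximation
D = 0.88·r²/(4·t1/2) — a convention-dependent quantity, flagged as such.
Fits with a plateau within 1% of the floor are flagged degenerate; Mf
outside [0, 1] is clipped and flagged.

Kymograph compaction tracks the DNA end as the farthest supra-threshold
pixel from the anchored end per frame and reports the absolute least-squares
slope of end position (nm) against time (s). The estimate is invariant to
uniform intensity rescaling (threshold scaled alongside). Pixel-quantized
end tracking bounds the noiseless residual error: with a 50-frame fit the
recovered rate sits within ~0.1% of the planted value rather than at exact
float equality.

The nuclear-concentration estimate models the nucleus as a sphere:
C = ((m/n)/MW)/((4/3)π(d/2)³). With 0.352 ng over 80,000 cells, 26.7 kDa
and d = 12 µm it returns 182.1 nM; it is exactly linear in mass and
inverse-cubic in diameter.

## Synthetic data: what it emulates, and what it does not

Each generator derives a named, independent pseudorandom stream from one
integer seed (adding a generator never perturbs another), and identical
(seed, parameters) reproduce identical artifacts.

- *Genomes with motif arrays*: i.i.d. background bases at configurable GC
  (default 0.41, a mammalian-like composition); planted sites hold k
  consecutive instances sampled from the PFM's per-position distributions
  (not the fixed consensus, so detection tests see score variation), each
  with a random strand, spaced 10 bp, placed without overlap.
- *Contact maps*: independent Poisson counts around a block model,
  E[c_ij] = N·p·|i−j|^(−α) with p = p_intra within a boundary-delimited
  block and p_inter across, α = 1 by default. No balancing or normalization
  is simulated, matching pipelines that use raw aggregated PET counts.
- *Anchor cohorts*: latent insulation u ~ U(0,1), signal
  exp(slope·u + ε), ε ~ N(0, σ) — a log-linear coupling with log-normal
  noise.
- *Variant catalogs*: substitution types multinomial from a planted
  spectrum, genes and tissues uniform, positions uniform with one
  up-weighted hotspot residue.
- *FRAP traces*: the single-exponential model above plus Gaussian noise.
- *Nucleus stacks*: 3D Gaussian intensity bumps (σ = 1.5 voxels by
  default) over flat background with Gaussian read noise or Poisson shot
  noise; centroids keep a 2σ border margin and 4σ pairwise separation.
- *Kymographs*: a linear end trajectory with uniform interior intensity
  and additive Gaussian noise.

These emulate the statistical structure the estimators rely on, not the
full phenomenology of real data: no fragment-level ChIA-PET noise, mapping
artefacts or copy-number structure in the contact maps; no read-level
simulation or peak-calling uncertainty; no optical PSF beyond the Gaussian
focus shape; no multi-exponential or binding-dominated FRAP. Passing
recovery tests therefore demonstrates correctness of the estimators under
their stated models, not robustness to every artefact of real experiments.

## Problem sizes and acceptance measurements

The recovery studies run at sizes chosen to make the statistical criteria
meaningful while keeping the whole suite fast: 100 seeded replicates per
study; 40-bin contact maps with one planted boundary, 4× contrast and 200
expected counts at distance 1; 200-anchor cohorts at slope 1.0 and noise
0.2; 2,000-variant catalogs; 16×64×64 nucleus stacks with three planted
foci at 5× background amplitude and 10-unit read noise (called at
threshold = background + 3 SD); FRAP traces sampled every 0.5 s for 120 s
with noise at 1/20 of the recovery amplitude; 50-frame kymographs at
871 nm/s planted rate. `scripts/acceptance.py` re-measures all of these
from a user seed and writes the results as JSON.

## Known limitations

- Two insulation conventions exist in the literature this pipeline serves
  (log2 up/down vs within/across ratio); both are implemented, and group
  analyses default to the per-bin log-ratio with |score| ranking.
- The exact p-value grid is conservative by construction; extremely sharp
  matrices with near-degenerate score gaps below L·δ can see adjacent
  thresholds merge (decrease δ to resolve).
- The shuffled null uses rejection sampling; extremely dense interval sets
  near chromosome capacity can hit the bounded-retry limit and raise a
  capacity error rather than bias placement.
- `normalize_rpm` treats track values as read counts per bin; it does not
  attempt fragment-length extension or strand shifting.
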