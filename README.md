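# insulome

A quantification toolkit for studies of CTCF (CCCTC-binding factor)
clustering and chromatin insulation. It re-implements, as a tested Python
library with a thin CLI, the analysis stages such studies chain together:

- **Contact insulation** — binning ChIA-PET/Hi-C style paired contacts onto
  40-kb matrices, per-bin insulation scores (log2 ratio of upstream to
  downstream contact frequency within 400 kb), per-loop within/across
  contact ratios, quantile ranking of loop anchors into five insulation
  groups and per-group ChIP-signal summaries.
- **Motif arrays** — log-odds PWM construction from JASPAR count matrices
  (the CTCF matrix MA0139.1 is bundled), exhaustive two-strand scanning,
  exact score-distribution p-values by dynamic programming, summit-centred
  400-bp binding-site regions, replicate-consistent peak sets, per-site
  motif-array counting, and a length-preserving shuffled-interval null.
- **Signal profiles** — reads-per-million depth normalization in 50-bp bins
  and metagene averaging across binding-site centers ± 5 kb.
- **Mutation spectrum** — HGVS.p missense parsing, DNA-binding-domain (DBD)
  annotation, positional hotspot landscapes, amino-acid substitution
  spectra (mean ± SD relative contribution per transcription factor or
  cancer type), mutation-count rankings and amino-acid composition.
- **Foci imaging** — 3D connected-component focus calling with voxel-size
  and intensity filters, focus-count fold changes with Student's t,
  point-enrichment ratios, phase-shifted area fractions and line profiles.
- **Kinetics** — FRAP double normalization and single-exponential recovery
  fits (tau, t1/2 = tau·ln2, mobile fraction Mf = (Ie−Io)/(Ipre−Io),
  apparent D = 0.88·r²/(4·t1/2)), DNA-curtain compaction rates from
  kymograph end tracking, and nuclear-concentration estimates.

A first-class synthetic-data module generates every input class with known
ground truth (planted motif arrays, contact-map boundaries, coupled anchor
cohorts, variant spectra and hotspots, FRAP parameters, nuclear foci,
compaction slopes), so the full pipeline is testable end to end without any
external download.

## Worked example

```python
import numpy as np
from insulome import insulation, kinetics, synthetic

# 1. a contact map with a boundary planted at bin 20 of 40
tb = synthetic.synth_contact_map(seed=11, n_bins=40, boundaries=[20],
                                 p_intra=1.0, p_inter=0.2, base_count=200)
mats = insulation.bin_contacts(tb.artifact, 40_000, tb.truth["chrom_sizes"])
prof = insulation.insulation_profile(mats["chr1"])   # 400-kb window
print(insulation.call_boundary(prof))                # -> 20

# 2. a noiseless FRAP recovery with tau = 5 s and Mf = 0.8
t, y = synthetic.synth_frap_trace(seed=0, tau_s=5.0, Mf=0.8,
                                  noise_sd=0.0).artifact
fit = kinetics.fit_frap_recovery(t, y, bleach_radius_um=0.75)
print(round(fit.tau_s, 2), round(fit.mobile_fraction, 2))   # -> 5.0 0.8

# 3. the nuclear-concentration estimate
print(round(kinetics.nuclear_concentration(0.352, 80_000, 26.7, 12.0), 1))
# -> 182.1  (nM)
```

The boundary caller resolves the planted boundary bin; the exponential fit
returns the planted time constant and mobile fraction; and 0.352 ng of a
26.7-kDa protein spread over 80,000 nuclei of 12 µm diameter corresponds to
a 182 nM nuclear concentration.

The same operations are exposed on the command line, e.g.

```bash
insulome conc --mass-ng 0.352 --cells 80000 --mw-kda 26.7 --diameter-um 12
insulome insulation --contacts pets.bedpe --chrom-sizes sizes.tsv --out run1
insulome motifs --fasta genome.fa --pfm MA0139.1.jaspar \
    --peaks peaks.narrowPeak --peaks-dialect narrowPeak \
    --threshold-logp 4 --out run1
```

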