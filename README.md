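# cingfp — cross-species cingulate connectivity fingerprints

`cingfp` is a tested, reusable implementation of a comparative-connectomics
pipeline for the cingulate cortex: data-driven parcellation of tracer-based
structural connectivity, seed-by-target connectivity fingerprints from both
tracer and resting-state fMRI data, scan-level functional-connectivity
quality control, repeated-measures statistics, and a quantitative
cross-species fingerprint comparator. It is aimed at researchers who want to
ask whether two species' cingulate cortices are organized along the same
rostro-caudal connectivity gradient — and at methodologists who want every
stage of such an analysis exercised end-to-end on synthetic brain phantoms
with known ground truth.

## What it computes

**Projection similarity.** Given a collection of anterograde-tracer
experiments *e* = 1…E (3D projection-density volumes on a common grid), the
connectivity signature of a seed voxel *s* is its density profile across
experiments. The projection similarity between seed *s* and any brain voxel
*v* is the Pearson correlation across experiments,

    S[s, v] = corr_e( d_e(s), d_e(v) ),

high when *s* and *v* receive projections from the same injection sites.
Seeds are placed at even rank intervals along the rostro-caudal axis
(normalized position u ∈ [0, 1]) of the cingulate seed strip.

**ICA parcellation.** The seeds × voxels similarity matrix is decomposed by
spatial ICA (fixed-point, logcosh contrast, one-unit deflation) at model
orders 4–9. Each component is a z-scaled spatial map with one mixing weight
per seed; assigning every seed to its largest-|weight| component yields a
data-driven parcellation of the strip, which on phantom data segments it
contiguously into anterior-limbic, mid-motor/striatal, and
posterior-hippocampal zones.

**Connectivity fingerprints.** For a fixed battery of target regions, the
fingerprint is the seeds × targets matrix of connectivity — correlation of
whole-brain similarity profiles for tracer data; for rs-fMRI, the Pearson
correlation of detrended, zero-phase Butterworth band-passed mean ROI time
series, averaged over subjects with ± SEM.

**Quality control.** A scan is kept when the sensory seed correlates
strongly with its homotopic contralateral counterpart (r > 0.1) and weakly
or negatively with a default-mode seed (r < 0.1), the standard
functional-connectivity specificity filter.

**Statistics.** A two-way fully within-subject ANOVA (seed × target) with
Greenhouse–Geisser and Huynh–Feldt sphericity corrections tests whether
targets distinguish the seeds:
F = MS_seed×target / MS_seed×target×subject with df
((a−1)(b−1), (a−1)(b−1)(n−1)); ε̂_HF rescales both df.

**Cross-species comparison.** Two fingerprints with different seed counts
are interpolated onto a common u grid; each homolog target pair is compared
by the Pearson correlation of its two rostro-caudal profiles, plus cosine
and mean-absolute-difference summaries of the whole matrix.

The `synthetic` module generates all inputs with planted ground truth:
bilateral phantom atlases with an elongated midline seed strip, tracer
collections whose projection targets depend on injection position along the
strip, and BOLD scans with planted network covariance (homotopic sensory
coupling, sensory-vs-default-mode anticorrelation, and a configurable
fraction of non-specific scans).

## Worked example

The whole pipeline runs on phantoms in one command (≈ 25 s):

```sh
cingfp demo --out report --seed 7
```

This simulates two phantom "species" — both share the anterior-limbic /
mid-motor / posterior-hippocampal gradient, but the insula is wired to the
anterior network in species A ("mouse") and to the mid-cingulate network in
species B ("human") — then runs tracer mapping, ICA parcellation at orders
4–9, fingerprints for both modalities, QC, the repeated-measures ANOVA, and
the comparator. With seed 7 the report contains:

* `anova.tsv` — the seed-by-target interaction per species:

  ```
  species  F_interaction  df1  df2   p_unadjusted
  mouse        93.24       72  504   4.8e-248
  human        31.97       88  616   1.4e-178
  ```

  df1 = 72 and 88 are the analytically forced values for 10 × 9 and 12 × 9
  designs; large F means the targets separate the seeds, i.e. a genuine
  connectivity gradient.

* `run_log.json` — the seed parcellation is contiguous along u at every ICA
  order (4–9), and the least-similar homolog pair is the insula.

* `qc_human.tsv` — 8 of 10 scans pass; the two rejected scans are exactly
  the two the generator planted as non-specific.

* `compare.tsv` — per-target cross-species profile correlations:

  ```
  amygdala 0.97   nucleus_accumbens 0.96   orbitofrontal 0.97
  insula  -0.50   hypothalamus 0.96        caudoputamen 0.94
  motor_secondary 0.94   parietal_assoc 0.94   hippocampus 0.97
  ```

  Every homolog pair that is wired the same way in both species agrees at
  r ≈ 0.95; the deliberately re-wired insula stands out at r = −0.50 — the
  comparator isolates the one planted species difference.

Each stage is also available as its own subcommand (`simulate`,
`tracer-map`, `parcellate`, `fingerprint`, `qc`, `anova`, `compare`)
operating on NIfTI volumes and TSV manifests, and as plain library calls
(`cingfp.place_seeds`, `cingfp.projection_similarity`, `cingfp.decompose`,
`cingfp.two_way_rm_anova`, …). See `docs/methods.md` for the models,
parameter defaults, and design decisions.

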