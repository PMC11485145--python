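# Methods

This note documents the models implemented in `cingfp`, the phantom
generators that stand in for real data, the numerical choices, and the
design decisions taken where the design was genuinely open. Everything
stated here is computed by the test suite or the demo pipeline; nothing is
quoted from external runs.

## 1. Data model and conventions

All volumes live in a canonical orientation: array axis 1 is the
rostro-caudal (anterior–posterior) axis with anterior at index 0; axis 0 is
left–right, axis 2 ventral–dorsal. NIfTI files are written RAS+ and
reoriented on load, so seed-ordering logic only ever reads one axis. Voxel
indices are 0-based; coordinates refer to voxel centers. Tabular artifacts
are TSV with the literal token `NA` for missing values; integer volumes
round-trip bit-exactly.

A `LabelAtlas` is an integer label volume plus a table
(`label_id, name, hemisphere ∈ {L,R,M}, role ∈ {seed_roi, target, sensory,
dmn, other}`); label 0 is background and every grid label must appear in
the table. 4D scans are held as voxels × timepoints matrices with grid
metadata and a repetition time in seconds.

## 2. Seed placement along the strip

"Even intervals" is operationalized as rank quantiles: ROI voxels are
ranked by rostro-caudal coordinate (ties broken by the left–right then
ventral–dorsal axes, in that fixed order), seed *i* of *n* sits at 0-based
rank ⌈q·N⌉−1 with q = (i+0.5)/n, computed in exact integer arithmetic, and
carries u = (rank+1)/N. On a straight strip this reduces to even arc-length
spacing; on arbitrary ROI shapes it remains well defined. Parcellation
seeds are single voxels; fingerprint seeds default to single voxels with an
optional Chebyshev-radius growth clipped to the ROI.

## 3. The tracer phantom

Each phantom experiment is an injection at a stratified-jittered position
u ∈ [0, 1] along the strip. Deposits, all on top of a uniform background
(0.05 a.u.) inside an ellipsoidal brain mask (outside is air: exactly zero,
hence zero variance, hence dropped from every correlation support):

* **Zones.** Three Gaussian projection zones (centers 0.12 / 0.50 / 0.88,
  width σ_u = 0.10, strength 1) deposit `strength · exp(−(u−c)²/2σ_u²)`
  into their targets: anterior → amygdala, nucleus accumbens,
  orbitofrontal, insula, hypothalamus; mid → caudoputamen, secondary motor,
  parietal association; posterior → hippocampus.
* **Graded specificity (crosstalk 0.3).** Every target also receives 0.3 of
  the other zones' gains. Real cingulate targets connect to the whole
  strip with graded strength; mathematically this keeps the three
  (centered) gain profiles from being strongly anti-correlated, which is
  what makes the three zones separately identifiable (see §5).
* **Termination halos.** A 0.7 fraction of each zone's density spills into
  a 3-voxel shell around its targets — the termination field extending
  beyond the labelled core. These unlabelled halo voxels are what the
  tracer fingerprint correlates over after the seed strip and target cores
  are excluded.
* **Intra-cingulate projections.** Each zone labels the strip segment
  nearest its own center at 2× its gain. This gives strip voxels a
  discrete zone membership, so parcellation boundaries are noise-robust.
* **Injection site.** The needle-track blob fluoresces: a Gaussian bump
  (amplitude 0.5, width 0.12 in u) along the strip and a 2-voxel halo
  around it.
* **Noise.** Additive Gaussian noise (default sd 0.2 = 0.2 × zone
  strength) inside the brain, truncated at zero (fluorescence density is
  non-negative).

Optional mechanisms, off by default: off-strip (non-specific) injections,
per-experiment lognormal expression efficacy, and diffuse background
projection systems (random blobs with their own u-profiles).

`simulate_tracer_experiments(..., return_truth=True)` returns the noiseless
densities and the deposit mask; `planted_zone_maps` converts these into the
population spatial map of each zone — the correlation of the zone's
effective gain profile with the noiseless densities — which is the correct
recovery target for the decomposition (a binary target indicator is not:
the planted pattern is graded and extends over halos and strip segments).

## 4. The BOLD phantom

Voxel signal is a network latent (unit-variance Gaussian white series,
shared by all voxels of a network) scaled by `signal_sd`, plus white noise
of sd `noise_sd`, inside the brain mask. Five default networks mirror the
tracer zones: limbic / motor / posterior target batteries plus the
anterior, mid and posterior thirds of the strip; a homotopic sensory L/R
pair shares one latent; the default-mode pair receives the sensory latent
with negated loading (population r → −1 as noise → 0). Two voxels of one
network have population correlation s²/(s²+σ²) — 0.5 at s = σ, the default
study condition. A `frac_bad` fraction of scans (exact count, random
choice) is pure noise and flagged in the returned manifest; per-subject
seeds are spawned from one `SeedSequence`, so streaming and in-memory
generation are bit-identical.

Latents are white (no autocorrelation) because Pearson r then has known
sampling behaviour; hemodynamic spectra, motion and physiological noise are
out of scope, so passing tests show correctness of the estimators, not
robustness to those artifacts.

## 5. ICA parcellation

The decomposition is spatial ICA of the seeds × voxels similarity matrix:
voxels are samples, seeds are features, sources are spatial maps, mixing
weights are per-seed loadings. Pipeline: drop NA voxels → PCA whitening to
the requested order → fixed-point ICA with logcosh contrast, **one-unit
deflation** with Gram–Schmidt orthogonalization, tolerance 1e-6, at most
500 iterations per component → sign flip so each map has positive skewness
(tie: make the largest-|value| voxel positive) → order by explained
variance (maps are z-scaled, so this is the squared weight norm).

Two numerical findings shaped this design:

* **Deflation, not symmetric decorrelation.** On similarity data whose
  higher whitened dimensions are dominated by the correlated sampling
  noise of Pearson r at n ≈ 60 experiments, the symmetric fixed point
  enters stable limit cycles (the convergence criterion plateaus around
  3×10⁻², for any tolerance and iteration budget). The one-unit deflation
  variant converges at every order, and is equally deterministic under a
  seeded start.
* **No per-voxel centering.** Removing each voxel's mean across seeds
  collapses the three zone gain profiles — whose sum is close to constant
  in u — into a rank-2 contrast space. The decomposition then *must*
  return bipolar anterior-vs-posterior components, and no assignment rule
  can segment the strip into three zones. Only the per-seed (feature)
  centering inherent to whitening is applied.

A component that exhausts its iteration budget yields a warning and the
running estimate (as the field's standard decomposition tools do);
`strict_convergence=True` turns this into a `ConvergenceError` carrying the
iteration count. Seeds are assigned to the component with the largest
absolute weight, ties toward the lower index; a z > 3 thresholding option
exists for display only. `order_sweep` decomposes at several orders and
pairs components of consecutive orders greedily by maximal |spatial
correlation|.

On the default phantom at the documented study conditions (60 experiments,
noise 0.2), every planted zone is matched by a component with spatial
correlation ≥ 0.8 (measured within the deposit-bearing tissue mask against
the `planted_zone_maps` ground truth) and the seed assignment is a
contiguous segmentation of the strip at every order 4–9; the margin
observed across seeds is ≈ 0.90 worst-case.

## 6. Fingerprints

*Tracer*: the whole-brain similarity profile of each of 10 seeds is
correlated with the profile of each target region over brain voxels outside
the seed strip and all target labels (exclusion avoids self-correlation
inflation and makes entries comparable across targets); NA voxels drop
pairwise; SEM is NA (a single measurement).

*rs-fMRI*: per scan, unweighted mean ROI time series are extracted,
linearly detrended, band-pass filtered with a zero-phase 4th-order
Butterworth (applied forward–backward; default bands 0.01–0.25 Hz for the
mouse-like cohort, 0.01–0.1 Hz for the human-like cohort, TR 1 s), and
correlated per subject between every seed and target. Point seeds given as
millimetre coordinates (the usual way human seeds are reported) are
snapped to the nearest voxel and optionally grown to a radius
(`seed_spec_from_mm`). Group fingerprints
average raw r across subjects (no Fisher transform by default, matching
how such fingerprints are usually reported; a Fisher-z option exists) with
SEM = sample sd/√n and per-cell n under pairwise NA dropping.

## 7. Quality control

`specificity_filter` computes r_homotopic (sensory seed vs its
contralateral twin) and r_specificity (sensory vs default-mode seed) on the
extracted mean series and passes a scan iff r_homotopic > 0.1 **and**
r_specificity < 0.1, both strict; constant series mark the scan failed with
reason "degenerate". QC runs on unfiltered series by default — in the
workflow this filter models, scan selection precedes the analysis band-pass
— and narrow-band filtering before QC would also inflate the sampling
variance of r on pure-noise scans (effective dof ≈ 2·bandwidth·T·TR) enough
to blunt the filter. An optional band argument exists for pipelines that
want it. At the phantom study conditions (T = 900, signal sd 2, noise sd 1,
30% bad scans) sensitivity and specificity against generator truth both
exceed 0.95.

## 8. Repeated-measures ANOVA

Classical two-way fully within-subject decomposition on a complete
subjects × a × b table; the statistic of interest is
F = MS_AB / MS_AB×S with df ((a−1)(b−1), (a−1)(b−1)(n−1)). Sphericity:
ε̂_GG = tr(S)²/(d·tr(S²)) from the covariance S of the d = (a−1)(b−1)
orthonormalized (Helmert) interaction contrasts;
ε̂_HF = (n·d·ε̂_GG − 2)/(d·(n−1−d·ε̂_GG)), floored at ε̂_GG and capped at 1.
Both adjusted and unadjusted p-values are always reported, with a flag when
ε̂_HF < 0.75 ("adjustment necessary"). When n ≤ d the contrast covariance
is singular; the epsilons are NaN with a warning and the unadjusted p is
reported as the adjusted one. Subjects with any NA cell are dropped
listwise (classical RM-ANOVA requires complete tables); zero interaction
error mean square raises a degenerate-data error. The implementation is
verified against an independent Kronecker-projection sum-of-squares oracle
and against `statsmodels` `AnovaRM`, and its null p-values are uniform by
KS test under iid Gaussian cells.

## 9. Cross-species comparison

Each homolog target's profile over seeds is linearly interpolated onto m
(default 50) evenly spaced u values within the overlap of the two seed
ranges — no warping; the premise is positional correspondence of the
rostro-caudal gradient. Per-target similarity is the Pearson correlation of
the two profiles; overall similarity is the cosine of the flattened
matrices or the mean absolute difference (which, unlike the correlation
measures, is scale-sensitive). Constant profiles yield NA with a warning.

## 10. Pipeline, determinism and problem sizes

`run_demo` chains simulate → tracer-map → parcellate → fingerprint (tracer
and rs-fMRI) → qc → anova → compare with one JSON config whose defaults are
the documented study parameters (ICA orders 4–9, 10 and 12 fingerprint
seeds, bands 0.01–0.25 / 0.01–0.1 Hz, QC thresholds 0.1/0.1, parcellation
seeds min(2000, ROI size) — 216 on the default 40 × 60 × 30 phantom). All
randomness flows from a single seed; reruns are byte-identical. The demo
uses 8 + 10 subjects at 200 timepoints so a full run takes ~25 s on one
core; the statistical-guarantee tests use the larger cohorts stated above
(20 × 500 for fingerprint recovery, 100 × 900 for QC), sizes chosen so each
check has a comfortable margin while the whole suite stays fast.

## Known limitations

* The phantoms plant block covariance and Gaussian projection zones;
  passing tests demonstrate estimator correctness and recovery under those
  assumptions, not performance on real registration/motion/physiology
  artifacts, which are explicitly out of scope.
* ICA model order is a user parameter; no automatic order selection is
  attempted.
* The comparator assumes homolog target pairs are given; it quantifies
  profile similarity and does not assign area-by-area homology.
* CLI subcommands exchange the similarity matrix as a compressed `.npz`
  rather than one NIfTI per seed; per-component maps are written as NIfTI.
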