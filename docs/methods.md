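# Methods

This note documents the models, operational definitions and numerical
choices behind flpet, and what the synthetic-data tests do and do not show
about real PET data.

## Segmentation model

A lesion is the connected set of voxels whose SUV is at least a fraction
`threshold_fraction` (default 0.41) of the lesion's own maximum SUV. Since
the lesion maximum is only known after delineation, growth is a fixed
point: from a seed voxel, threshold at 41% of the current maximum, take the
connected component containing the seed, update the maximum to the hottest
voxel inside, and repeat until stable. The iteration terminates because the
in-region maximum is non-decreasing and bounded by the volume maximum; in
practice it converges in one or two rounds. A `global_threshold` mode
(fraction of the volume-wide SUVmax) is provided for comparison with
single-threshold studies; per-lesion is the default because multi-site
lymphoma lesions differ widely in peak uptake.

Seeds are 26-neighborhood local maxima with SUV ≥ `seed_min_suv`
(default 2.5, a conservative floor above typical mediastinal background);
a user-supplied seed list or exclusion mask replaces the visual check a
physician would perform on clinical images. Components smaller than
`min_lesion_voxels` (default 2) are discarded as noise specks. Voxel
connectivity (6/18/26, default 26) is configurable because lesion counting
and dispersion distances depend on it. A diffusely hot spleen is included
wholesale iff its ROI mean SUV strictly exceeds 1.5 × the liver ROI mean
(the statistic is configurable to the median; the mean is the default
reading of "background").

## Feature definitions

Distances are between voxel centers in mm, with the physical position of
voxel index *i* being `origin + i·spacing`. Units: TMTV and TumBB in cm³,
TMTS in cm², TVSR in mm (= 10 × cm³/cm²), all distances in mm.

Several parameters have no single published operational definition; the
committed defaults, all pinned in `FeatureConfig` and echoed into run
manifests, are:

- **Surface (TMTS):** marching cubes on the binary lesion mask at the 0.5
  iso-level after a 1-voxel Gaussian pre-smoothing. The smoothing removes
  the voxelization staircase, which otherwise inflates curved surfaces by
  ~9%; with it, digitized spheres of radius ≥ 10 voxels are within ~2% of
  4πr². Lesions too small to survive smoothing fall back to the raw binary
  iso-surface. A `voxel_faces` variant (exposed-face counting) is kept for
  exact axis-aligned geometry and oracle tests; it over-estimates curved
  surfaces by up to ~50% and therefore materially lowers TVSR — the two
  variants must never be mixed within a study.
- **Surface voxels:** lesion voxels with at least one 6-neighbor outside
  the lesion.
- **Dmax:** default `voxel_pair` — the largest distance between centers of
  any two tumor voxels, pooled across lesions (convex-hull accelerated; the
  extremal pair always lies on surface voxels). A single-lesion patient
  then has Dmax equal to its own maximal extent, which keeps Dmax defined
  for nROI = 1. `centroid_pair` (max distance between lesion centroids,
  0 for one lesion) is available for cross-study comparability.
- **medPCD:** distances from each lesion's centroid to each of its
  surface-voxel centers, pooled across lesions, median. A
  per-lesion-median-then-median variant is available. Per-lesion centroids
  (not the whole-tumor centroid) are used: a whole-tumor centroid would
  measure dispersion, not massiveness.
- **medEDGE:** per lesion, the maximal pairwise distance between its
  surface voxels (its maximal diameter); median across lesions. This is a
  committed interpretation of "median edge distance" — it makes medEDGE a
  massiveness-family statistic and reduces to the lesion diameter for a
  single sphere.
- **itErosion:** per lesion, the number of successive binary erosions
  (full 3×3×3 structuring element by default, 6-neighborhood optional)
  until the lesion is empty; aggregated by volume-weighted mean, so the
  patient-level value can be fractional (consistent with non-integer
  cohort summaries). Erosion operates in voxel units, so strongly
  anisotropic voxels bias the count toward the thinnest axis.

Internal identities asserted on every panel: TLG = TMTV × SUVmean
(to 1e-6 relative), TumBB ≥ TMTV.

## Statistical chain

- **POD24:** 1 iff a progression/relapse event occurred at ≤ 24.0 months.
  Patients censored before 24 months count as POD24−; this optimistic-label
  convention keeps every patient classifiable and is flagged here as a
  known caveat. Months are converted from days, when needed, at 30.44
  days/month.
- **Correlogram:** pairwise Spearman ρ (tie-corrected) with two-sided
  p-values; feature clusters from average-linkage hierarchical clustering
  on the distance 1 − |ρ| cut at k = 4 (k exposed as a parameter).
  Constant features yield undefined correlations, reported as missing.
- **ROC cut-off:** AUC as the Mann–Whitney rank statistic with ties given
  half credit; 95% CI by the asymptotic structural-component
  (DeLong-style) variance. The cut-off maximizes sensitivity × specificity
  over midpoints between consecutive sorted unique values, with "high"
  meaning value ≥ cut-off; product ties break toward the lower (more
  sensitive) cut-off.
- **Survival:** Kaplan–Meier product-limit curves; two-group (or
  multivariate) log-rank tests; univariate Cox proportional-hazards fits
  with Efron tie handling and Wald 95% CIs, via lifelines. PFS24 analyses
  administratively censor follow-up at 24 months. Non-identifiable fits
  (no events in a level) raise rather than silently dropping; the pipeline
  records them as missing rows with the error text.
- **Combined score:** count of high indicators among TMTV, TVSR and
  medPCD; sensitivity/specificity reported for the score ≥ 2 rule against
  POD24; each score group contrasted against group 0 in a Cox fit.
- No multiple-testing correction is applied across the twelve features
  (two-tailed α = 0.05) — deliberate, matching standard practice in this
  literature, and a caveat for interpretation.

## Synthetic data

**Phantoms** place plateau- or Gaussian-profile lesions (spheres,
ellipsoids, fused pairs, fragmented clusters) on a constant background with
additive Gaussian noise (clipped at 0). Ground-truth masks are the analytic
shape interiors (for Gaussian profiles, the 41%-of-peak region), and
closed-form feature expectations are returned where they exist. Phantoms
emulate only the geometry of PET lesions: there is no scanner PSF, scatter,
reconstruction artifact or partial-volume effect, so passing phantom tests
validates the geometry pipeline, not robustness to PET physics.

**Cohorts** draw a 12-dimensional latent Gaussian with a four-block
correlation structure (activity {SUVmax, SUVmean}; burden {TMTV, TLG,
TMTS}; massiveness-fragmentation {TVSR, medPCD, medEDGE, itErosion};
dispersion {Dmax, TumBB, nROI}; within-block ρ 0.8, between-block 0.2 by
default) and map each coordinate through a log-normal marginal
moment-matched to a high-burden FL cohort (e.g. TMTV mean 867.8, SD
731.0 cm³). TLG sits in the burden block because it is TMTV × SUVmean and
empirically correlates ~0.9 with TMTV; in real cohorts TLG correlates with
everything, which the block model deliberately simplifies. The latent
Gaussian copula preserves ranks, the quantity the downstream Spearman
stage sees. Time-to-progression is exponential (Weibull optional) with
log-hazard additive in the three dichotomized score indicators (default
true HRs 4.341 / 3.204 / 4.507 at cut-offs 1195.248 cm³ / 4.854 mm /
36.932 mm); the baseline hazard is calibrated by root-finding so the
expected 24-month event fraction equals the target POD24 prevalence
(default 0.222), and censoring is independent exponential with its rate
calibrated the same way to the target censoring fraction (default 0.25).
Simulated cohorts share the real data's correlation skeleton and hazard
structure but not its tails, measurement error or covariate confounding —
parameter-recovery results are evidence of estimator correctness, not of
clinical effect sizes.

## Problem sizes and tolerances

Phantom validation uses a radius-20 mm sphere at 1 mm spacing (~33,400
lesion voxels): TMTV within 1% of 33.51 cm³, TMTS within 3% of 50.27 cm²,
TVSR within 3% of 6.67 mm, medPCD within 0.5 mm, medEDGE/Dmax within one
voxel. Brute-force oracle equivalence is checked on random masks of ≤ 500
voxels, where all-pairs and set-based loops are tractable. Parameter
recovery runs 200 replicates of n = 126 cohorts (median estimated HR for
high TMTV expected in [3.4, 5.4] when the true HR is 4.3); cluster recovery
runs 100 replicates. These sizes keep the full validation sweep fast while
leaving the estimators in their intended operating range.

## Known limitations

- No DICOM ingestion or SUV computation from raw activity; inputs are
  already-scaled SUV NIfTI volumes.
- Automatic seeds stand in for physician review; on real data the
  exclusion of physiological uptake requires a supplied mask.
- The marching-cubes smoothing constant (σ = 1 voxel) is tuned for lesions
  ≥ a few voxels across; sub-voxel structures fall back to the blocky
  surface.
- The medEDGE and itErosion aggregation defaults are committed
  interpretations of under-specified definitions; variant selectors exist
  precisely so studies can state and vary them.
- OS modeling is intentionally minimal; the package's focus is POD24/PFS24.
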