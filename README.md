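# flpet

Quantitative baseline ¹⁸F-FDG-PET analysis for high-tumor-burden follicular
lymphoma: lesion segmentation, twelve 3-D burden / massiveness /
fragmentation / dispersion parameters, and the prognostic statistics that
link them to early progression (POD24, progression within 24 months of
first-line immuno-chemotherapy).

The package is aimed at nuclear-medicine and hemato-oncology researchers
who want a tested, scriptable re-implementation of this feature-extraction
and survival-analysis chain — for phantom validation, for method studies on
synthetic cohorts, or for running the pipeline on their own NIfTI SUV
volumes.

## What it computes

**Segmentation.** Lesions are delineated at 41% of their own SUVmax
(the EANM-recommended relative threshold for lymphoma), found by fixed-point
region growing from automatically detected or user-supplied seeds, with
optional physiological-uptake exclusion masks and the diffuse-spleen rule
(include the whole spleen when its uptake exceeds 150% of the liver
background).

**The twelve parameters** (per patient, over all segmented lesions):

| family | parameters |
|---|---|
| activity | SUVmax, SUVmean |
| burden | TMTV (cm³), TLG = TMTV·SUVmean, TMTS (cm²) |
| massiveness / fragmentation | TVSR = TMTV/TMTS (mm), medPCD (mm), medEDGE (mm), itErosion |
| dispersion | Dmax (mm), TumBB (cm³), nROI |

TVSR is the volume-to-surface ratio (for a sphere, r/3): low values mean a
fragmented tumor, high values a massive one. medPCD is the median distance
from each lesion's centroid to its surface (for a sphere, r). itErosion is
the number of binary erosions needed to make the tumor disappear.

**Prognostic chain.** Spearman correlogram with average-linkage clustering
of the features (the four families above emerge as correlation blocks);
per-feature ROC dichotomization for POD24 at the cut-off maximizing
sensitivity × specificity; Kaplan–Meier / log-rank and univariate Cox fits
(Efron ties) of each dichotomized feature; and the combined 0–3 score —
the count of "high" parameters among TMTV, TVSR and medPCD — whose groups
show a synergistic hazard gradient.

**Synthetic data.** `make_phantom` builds PET-like volumes with lesions of
known geometry (spheres, ellipsoids, fused pairs, fragmented clusters) and
returns closed-form expected feature values; `make_cohort` simulates
feature tables with the four-block correlation structure and exponential
survival whose hazard depends on the dichotomized score features.

## Worked example

```bash
python examples/01_phantom_features.py
```

segments a digitized sphere of radius 20 mm (1 mm voxels, plateau SUV 10)
and prints the panel next to the closed-form sphere values:

```
parameter       computed  analytic
tmtv_cm3           33.40     33.51
tmts_cm2           50.01     50.27
tvsr_mm             6.68      6.67
med_pcd_mm         19.54     20.00
med_edge_mm        40.00     40.00
n_roi               1.00         1
```

The residual differences are voxelization error and shrink with grid
refinement. `examples/03_combined_score.py` evaluates the combined score on
the published per-group counts of a 126-patient cohort (POD24− 51/16/18/13,
POD24+ 2/5/9/12 across scores 0–3) and prints

```
score >= 2 for POD24: sensitivity 75% (21/28), specificity 68% (67/98)
```

then repeats the computation end-to-end on a simulated cohort, where the
Cox hazard ratio rises monotonically with the score (the synergy pattern).
`examples/02_cohort_analysis.py` runs the correlogram + ROC + Cox chain;
`examples/04_full_pipeline.py` drives the whole pipeline on 20 simulated
phantom patients.

## Command line

```bash
flpet segment  --in vol.nii.gz --out mask.nii.gz --threshold-fraction 0.41
flpet features --vol vol.nii.gz --mask mask.nii.gz --out features.csv
flpet analyze  --cohort cohort.csv --out results/
flpet simulate cohort --out cohort.csv --n 126 --seed 1
flpet run      --config pipeline.yml
```

Every run writes a `manifest.json` pinning the seed and all analysis
variants (surface method, Dmax mode, aggregation choices) so results stay
interpretable.

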