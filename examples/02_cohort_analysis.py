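"""Prognostic analysis of a synthetic 126-patient cohort.

Generates a cohort whose features carry the four-block correlation
structure (activity / burden / massiveness-fragmentation / dispersion)
and whose progression hazard rises with high TMTV, TVSR and medPCD, then
runs the full statistical chain: correlogram clustering, ROC cut-off
search for POD24, and univariate Cox fits of the dichotomized features.
"""

import pandas as pd

from flpet import CohortSpec, cox_univariate, make_cohort, roc_table, spearman_correlogram

cohort, truth = make_cohort(CohortSpec(n=126, seed=42))
print(f"cohort: {len(cohort)} patients, POD24 prevalence {cohort['pod24'].mean():.1%}\n")

corr = spearman_correlogram(cohort)
clusters = pd.Series(corr.clusters).groupby(pd.Series(corr.clusters)).groups
print("feature clusters found (average linkage on 1-|rho|, k=4):")
for cid in sorted(set(corr.clusters.values())):
    members = [f for f, c in corr.clusters.items() if c == cid]
    print(f"  cluster {cid}: {', '.join(members)}")

roc = roc_table(cohort)
print("\nROC cut-off search for POD24 (high = value >= cut-off):")
print(roc[["feature", "auc", "cutoff", "sensitivity", "specificity"]].round(3).to_string(index=False))

print("\nunivariate Cox (PFS censored at 24 months), dichotomized at the ROC cut-off:")
for feat in ("tmtv_cm3", "tvsr_mm", "med_pcd_mm"):
    cut = roc.loc[roc.feature == feat, "cutoff"].iloc[0]
    ind = (cohort[feat] >= cut).astype(int)
    ind.name = feat
    fit = cox_univariate(cohort, ind)[0]
    print(f"  {feat:<12} HR {fit.hazard_ratio:5.2f}  [{fit.ci_low:.2f}, {fit.ci_high:.2f}]  p = {fit.p_value:.2g}")
print("\nHRs well above 1 for the three score features reflect the generative "
      "hazard ratios (4.3 / 3.2 / 4.5) the cohort was simulated with.")
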