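"""Prognostic analysis: correlogram clustering, ROC dichotomization,
Kaplan–Meier / log-rank, univariate Cox fits, and the combined 0-3 score.

The analysis chain dichotomizes each PET parameter at the cut-off that
maximizes sensitivity × specificity for the 24-month progression endpoint
(POD24), then quantifies the prognostic value of each "high" indicator by
Kaplan–Meier curves, log-rank tests and univariate proportional-hazards
fits, and finally combines the three least-redundant indicators (TMTV,
TVSR, medPCD) into a 0-3 score.

Conventions: "high" means value ≥ cut-off; no multiple-testing correction
is applied across the twelve features (two-tailed α = 0.05) — a deliberate
caveat documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import FEATURE_COLUMNS

#: The three combined-score features and their canonical cluster labels.
SCORE_FEATURES = ("tmtv_cm3", "tvsr_mm", "med_pcd_mm")

FEATURE_CLUSTERS = {
    "activity": ("suv_max", "suv_mean"),
    "burden": ("tmtv_cm3", "tlg", "tmts_cm2"),
    "massiveness_fragmentation": ("tvsr_mm", "med_pcd_mm", "med_edge_mm", "it_erosion"),
    "dispersion": ("dmax_mm", "tumbb_cm3", "n_roi"),
}


@dataclass
class CutoffResult:
    feature: str
    cutoff: float
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    sensitivity: float
    specificity: float
    n_below: int
    n_above: int


@dataclass
class SurvivalFit:
    variable: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    logrank_p: float | None = None


@dataclass
class CorrelogramResult:
    features: list[str]
    rho: np.ndarray          # Spearman rank correlations, symmetric, diag 1
    p_values: np.ndarray
    clusters: dict[str, int]  # feature -> cluster id (1..k)


@dataclass
class CombinedScoreResult:
    scores: pd.Series                  # per-patient score in {0,1,2,3}
    group_counts: pd.DataFrame         # rows: score 0..3; columns: pod24- / pod24+
    sensitivity: float                 # of score >= 2 for POD24
    specificity: float
    group_fits: list[SurvivalFit]      # Cox HR of each score group vs group 0
    logrank_p: float | None = None


# ---------------------------------------------------------------------------
# POD24


def derive_pod24(cohort: pd.DataFrame, horizon_months: float = 24.0) -> pd.Series:
    """POD24 label: a progression/relapse event at or before the horizon.

    Patients without an event by the horizon — including those censored
    earlier — are labeled 0.
    """
    for col in ("pfs_time_months", "pfs_event"):
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing column {col!r}")
    missing = cohort.loc[cohort["pfs_time_months"].isna(), "patient_id"].tolist() if "patient_id" in cohort else []
    if missing or cohort["pfs_time_months"].isna().any():
        raise ValueError(f"missing pfs_time_months for patients: {missing or 'unknown ids'}")
    pod24 = ((cohort["pfs_event"] == 1) & (cohort["pfs_time_months"] <= horizon_months)).astype(int)
    pod24.name = "pod24"
    return pod24


# ---------------------------------------------------------------------------
# Correlogram


def spearman_correlogram(
    features: pd.DataFrame,
    columns: list[str] | None = None,
    n_clusters: int = 4,
) -> CorrelogramResult:
    """Pairwise Spearman correlogram plus hierarchical feature clustering.

    Clusters come from average-linkage clustering on the distance 1 − |ρ|,
    cut at ``n_clusters``. A constant column yields undefined (NaN)
    correlations against every other feature.
    """
    columns = columns or [c for c in FEATURE_COLUMNS if c in features.columns]
    if len(features) < 3:
        raise ValueError("correlogram requires at least 3 patients")
    X = features[columns].to_numpy(dtype=float)
    k = len(columns)
    rho = np.ones((k, k))
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if np.ptp(X[:, i]) == 0 or np.ptp(X[:, j]) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = sps.spearmanr(X[:, i], X[:, j])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    dist = 1.0 - np.abs(np.nan_to_num(rho, nan=0.0))
    np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.average(squareform(dist, checks=False))
    assignment = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    clusters = {col: int(c) for col, c in zip(columns, assignment)}
    return CorrelogramResult(features=columns, rho=rho, p_values=pval, clusters=clusters)


# ---------------------------------------------------------------------------
# ROC cut-off


def _auc_delong(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC with its asymptotic (rank/structural-component) variance."""
    pos = values[labels == 1]
    neg = values[labels == 0]
    m, n = len(pos), len(neg)
    # psi(x, y) = 1 if x > y, 0.5 if tie, 0 otherwise
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    auc = psi.mean()
    v10 = psi.mean(axis=1)  # per-positive structural components
    v01 = psi.mean(axis=0)  # per-negative
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    return float(auc), float(var)


def roc_cutoff(values: np.ndarray | pd.Series, labels: np.ndarray | pd.Series, feature: str = "") -> CutoffResult:
    """Optimal dichotomization cut-off by maximizing sensitivity × specificity.

    "High" means value ≥ cut-off. Candidate cut-offs are midpoints between
    consecutive sorted unique values; ties in the product are broken toward
    the lower cut-off (the more sensitive choice). The AUC 95% CI uses the
    asymptotic rank-variance (DeLong-style) method.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present for ROC analysis")
    auc, var = _auc_delong(values, labels)
    half = 1.959963984540054 * np.sqrt(var)
    uniq = np.unique(values)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    if len(candidates) == 0:
        candidates = uniq  # all values identical: degenerate but defined
    pos = values[labels == 1]
    neg = values[labels == 0]
    best = None
    for c in candidates:  # ascending, so strict > keeps the lower tie
        sens = float(np.mean(pos >= c))
        spec = float(np.mean(neg < c))
        prod = sens * spec
        if best is None or prod > best[0] + 1e-15:
            best = (prod, c, sens, spec)
    _, cutoff, sens, spec = best
    return CutoffResult(
        feature=feature,
        cutoff=float(cutoff),
        auc=auc,
        auc_ci_low=float(np.clip(auc - half, 0.0, 1.0)),
        auc_ci_high=float(np.clip(auc + half, 0.0, 1.0)),
        sensitivity=sens,
        specificity=spec,
        n_below=int(np.sum(values < cutoff)),
        n_above=int(np.sum(values >= cutoff)),
    )


def roc_table(cohort: pd.DataFrame, pod24: pd.Series | None = None, columns: list[str] | None = None) -> pd.DataFrame:
    """ROC cut-off analysis for every feature column (mirrors a cut-off table)."""
    pod24 = derive_pod24(cohort) if pod24 is None else pod24
    columns = columns or [c for c in FEATURE_COLUMNS if c in cohort.columns]
    rows = []
    for col in columns:
        r = roc_cutoff(cohort[col], pod24, feature=col)
        rows.append(vars(r))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Survival


def censor_at_horizon(times, events, horizon: float | None):
    """Administratively censor follow-up at ``horizon`` months."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if horizon is None:
        return times, events
    out_events = np.where(times > horizon, 0, events)
    out_times = np.minimum(times, horizon)
    return out_times, out_events


def km_logrank(
    times,
    events,
    groups,
    horizon_months: float | None = None,
) -> tuple[dict, float, float]:
    """Kaplan–Meier curves per group and the log-rank comparison.

    Returns ``(fits, chi2, p)`` where ``fits`` maps group label to a fitted
    ``KaplanMeierFitter``. With more than two groups the multivariate
    log-rank test is used.
    """
    times, events = censor_at_horizon(times, events, horizon_months)
    groups = np.asarray(groups)
    if events.sum() == 0:
        raise ValueError("log-rank requires at least one event overall")
    fits = {}
    for g in np.unique(groups):
        sel = groups == g
        if sel.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(times[sel], events[sel])
        fits[g] = kmf
    uniq = np.unique(groups)
    if len(uniq) < 2:
        return fits, 0.0, 1.0
    if len(uniq) == 2:
        a, b = uniq
        res = logrank_test(times[groups == a], times[groups == b], events[groups == a], events[groups == b])
    else:
        res = multivariate_logrank_test(times, groups, events)
    return fits, float(res.test_statistic), float(res.p_value)


def cox_univariate(
    cohort: pd.DataFrame,
    covariate: str | pd.Series,
    endpoint: str = "pfs24",
    reference=None,
) -> list[SurvivalFit]:
    """Univariate proportional-hazards fit (Efron tie handling, Wald CI).

    ``covariate`` is a column name or a Series of binary/categorical values;
    categorical levels are contrasted against ``reference`` (the smallest
    level by default). ``endpoint`` is one of ``pfs24`` (PFS censored at
    24 months), ``pfs`` or ``os``. Returns one fit per non-reference level.
    """
    if endpoint not in ("pfs24", "pfs", "os"):
        raise ValueError(f"endpoint must be pfs24, pfs or os, got {endpoint!r}")
    tcol, ecol = ("os_time_months", "os_event") if endpoint == "os" else ("pfs_time_months", "pfs_event")
    horizon = 24.0 if endpoint == "pfs24" else None
    times, events = censor_at_horizon(cohort[tcol], cohort[ecol], horizon)
    cov = cohort[covariate] if isinstance(covariate, str) else covariate
    name = covariate if isinstance(covariate, str) else (cov.name or "covariate")
    cov = pd.Series(np.asarray(cov), name=name)
    levels = np.sort(pd.unique(cov))
    if reference is None:
        reference = levels[0]
    fits = []
    for level in levels:
        if level == reference:
            continue
        sel = (cov == reference) | (cov == level)
        x = (cov[sel] == level).astype(float).to_numpy()
        t, e = times[np.asarray(sel)], events[np.asarray(sel)]
        if e[x == 1].sum() == 0 or e[x == 0].sum() == 0:
            raise ValueError(
                f"no events in level {level if e[x == 1].sum() == 0 else reference!r} "
                f"of {name!r}: hazard ratio is not identifiable"
            )
        df = pd.DataFrame({"time": t, "event": e, name: x})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")  # Efron ties (lifelines default)
        hr = float(np.exp(cph.params_[name]))
        ci = cph.confidence_intervals_
        lo = float(np.exp(ci.iloc[0, 0]))
        hi = float(np.exp(ci.iloc[0, 1]))
        p = float(cph.summary.loc[name, "p"])
        _, _, lr_p = km_logrank(t, e, x)
        fits.append(
            SurvivalFit(
                variable=f"{name}={level} (ref: {reference})",
                hazard_ratio=hr,
                ci_low=lo,
                ci_high=hi,
                p_value=p,
                logrank_p=lr_p,
            )
        )
    return fits


def cox_table(cohort: pd.DataFrame, cutoffs: dict[str, float], endpoint: str = "pfs24") -> pd.DataFrame:
    """Univariate Cox fits for every dichotomized feature (high = ≥ cut-off)."""
    rows = []
    for col, cut in cutoffs.items():
        indicator = (cohort[col] >= cut).astype(int)
        indicator.name = col
        fit = cox_univariate(cohort, indicator, endpoint=endpoint)[0]
        rows.append({"feature": col, "cutoff": cut, **{k: v for k, v in vars(fit).items() if k != "variable"}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Combined score


def score_classification(scores, pod24, threshold: int = 2) -> tuple[float, float, pd.DataFrame]:
    """Sensitivity/specificity of ``score >= threshold`` for POD24.

    Returns ``(sensitivity, specificity, group_counts)`` where group_counts
    cross-tabulates score value against POD24 status.
    """
    scores = np.asarray(scores, dtype=int)
    pod24 = np.asarray(pod24, dtype=int)
    high = scores >= threshold
    tp = int(np.sum(high & (pod24 == 1)))
    fn = int(np.sum(~high & (pod24 == 1)))
    tn = int(np.sum(~high & (pod24 == 0)))
    fp = int(np.sum(high & (pod24 == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    counts = pd.DataFrame(
        {
            "pod24_neg": [int(np.sum((scores == s) & (pod24 == 0))) for s in range(scores.max() + 1)],
            "pod24_pos": [int(np.sum((scores == s) & (pod24 == 1))) for s in range(scores.max() + 1)],
        },
        index=pd.Index(range(scores.max() + 1), name="score"),
    )
    return sens, spec, counts


def combined_score(
    cohort: pd.DataFrame,
    cutoffs: dict[str, float],
    features: tuple[str, ...] = SCORE_FEATURES,
    pod24: pd.Series | None = None,
    endpoint: str = "pfs24",
    fit_cox: bool = True,
) -> CombinedScoreResult:
    """The 0-3 combined score: count of high indicators among the features.

    Each patient's score counts how many of the chosen features are at or
    above their cut-offs; sensitivity/specificity are reported for the
    "≥ 2 high parameters" rule against POD24, and each score group is
    contrasted against group 0 in a proportional-hazards fit.
    """
    missing = [f for f in features if f not in cutoffs]
    if missing:
        raise ValueError(f"missing cut-offs for features: {missing}")
    pod24 = derive_pod24(cohort) if pod24 is None else pd.Series(np.asarray(pod24, dtype=int))
    indicators = np.column_stack([(cohort[f].to_numpy() >= cutoffs[f]).astype(int) for f in features])
    scores = pd.Series(indicators.sum(axis=1), index=cohort.index, name="combined_score")
    sens, spec, counts = score_classification(scores, pod24)
    fits: list[SurvivalFit] = []
    lr_p = None
    if fit_cox:
        fits = cox_univariate(cohort, scores.rename("combined_score"), endpoint=endpoint, reference=0)
        tcol = "pfs_time_months" if endpoint.startswith("pfs") else "os_time_months"
        ecol = "pfs_event" if endpoint.startswith("pfs") else "os_event"
        horizon = 24.0 if endpoint == "pfs24" else None
        _, _, lr_p = km_logrank(cohort[tcol], cohort[ecol], scores, horizon_months=horizon)
    return CombinedScoreResult(
        scores=scores,
        group_counts=counts,
        sensitivity=sens,
        specificity=spec,
        group_fits=fits,
        logrank_p=lr_p,
    )
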