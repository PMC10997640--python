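"""Synthetic inputs with known ground truth.

Two generators are provided:

* :func:`make_phantom` — PET-like SUV volumes containing lesions of
  controlled geometry (spheres, ellipsoids, fused pairs, fragmented
  clusters) on a noisy background, together with the analytic values the
  shape features should converge to;
* :func:`make_cohort` — per-patient feature tables with a four-block
  correlation structure (activity / burden / massiveness-fragmentation /
  dispersion) and exponential survival times whose hazard depends on
  dichotomized TMTV, TVSR and medPCD with configurable hazard ratios.

Feature marginals are log-normal, moment-matched to a high-burden
follicular-lymphoma cohort (e.g. TMTV mean ≈ 868 cm³, SD ≈ 731 cm³), so
the downstream ROC and proportional-hazards stages see realistic dynamic
ranges; the exact marginals are not a correctness criterion. Correlation
is imposed through a latent Gaussian copula, which preserves ranks — the
natural choice since the analysis uses Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .io import FEATURE_COLUMNS, SuvVolume, MaskVolume
from .segmentation import label_components
from .stats import FEATURE_CLUSTERS, SCORE_FEATURES

# ---------------------------------------------------------------------------
# Phantoms


@dataclass
class LesionSpec:
    """One synthetic lesion.

    shape : {"sphere", "ellipsoid", "fused_pair", "fragmented_cluster"}
    center_mm : physical center of the lesion (cluster center for groups).
    size_mm : radius (sphere), semi-axes triple (ellipsoid), radius pair
        (fused_pair) or common radius (fragmented_cluster).
    peak_suv : SUV at the lesion core; must exceed the background.
    profile : "plateau" (uniform peak SUV inside the shape) or "gaussian"
        (isotropic falloff with sigma = radius).
    separation_mm : center-to-center distance for fused_pair (< r1+r2) and
        grid pitch for fragmented_cluster (> 2r keeps fragments disjoint).
    n_fragments : number of spheres in a fragmented_cluster (≤ 8, placed
        on the corners of a cube).
    """

    shape: str
    center_mm: tuple[float, float, float]
    size_mm: float | tuple
    peak_suv: float
    profile: str = "plateau"
    separation_mm: float = 0.0
    n_fragments: int = 8


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_suv: float = 0.5
    noise_sd: float = 0.1
    lesions: list[LesionSpec] = field(default_factory=list)
    decoys: list[LesionSpec] = field(default_factory=list)
    seed: int = 0


def _sphere_centers(les: LesionSpec) -> list[tuple[np.ndarray, float]]:
    """Expand a lesion spec into (center, radius) primitive spheres."""
    c = np.asarray(les.center_mm, dtype=float)
    if les.shape == "sphere":
        return [(c, float(les.size_mm))]
    if les.shape == "fused_pair":
        r1, r2 = les.size_mm
        half = les.separation_mm / 2.0
        return [(c - [half, 0, 0], float(r1)), (c + [half, 0, 0], float(r2))]
    if les.shape == "fragmented_cluster":
        r = float(les.size_mm)
        half = les.separation_mm / 2.0
        corners = [np.array([sx, sy, sz], dtype=float) * half
                   for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        return [(c + off, r) for off in corners[: les.n_fragments]]
    raise ValueError(f"not a sphere-based shape: {les.shape}")


def _paint_lesion(les: LesionSpec, coords: np.ndarray, spacing: np.ndarray, grid_extent: np.ndarray):
    """Return (suv contribution, analytic inside-mask) for one lesion."""
    inside = np.zeros(coords.shape[:3], dtype=bool)
    contrib = np.zeros(coords.shape[:3], dtype=float)
    if les.shape == "ellipsoid":
        axes = np.asarray(les.size_mm, dtype=float)
        center = np.asarray(les.center_mm, dtype=float)
        if np.any(center - axes < -spacing / 2) or np.any(center + axes > grid_extent + spacing / 2):
            raise ValueError(f"lesion at {les.center_mm} extends outside the grid")
        norm = np.linalg.norm((coords - center) / axes, axis=-1)
        inside = norm <= 1.0
        if les.profile == "plateau":
            contrib = np.where(inside, les.peak_suv, 0.0)
        else:
            contrib = les.peak_suv * np.exp(-0.5 * (2 * norm) ** 2)
    else:
        for center, r in _sphere_centers(les):
            if np.any(center - r < -spacing / 2) or np.any(center + r > grid_extent + spacing / 2):
                raise ValueError(f"lesion at {les.center_mm} extends outside the grid")
            d = np.linalg.norm(coords - center, axis=-1)
            inside |= d <= r
            if les.profile == "plateau":
                contrib = np.maximum(contrib, np.where(d <= r, les.peak_suv, 0.0))
            else:
                contrib = np.maximum(contrib, les.peak_suv * np.exp(-0.5 * (d / (r / 2.0)) ** 2))
    return contrib, inside


def sphere_expectations(radius_mm: float) -> dict[str, float]:
    """Closed-form feature values for a solid sphere of the given radius."""
    r = radius_mm
    return {
        "tmtv_cm3": 4.0 / 3.0 * np.pi * r**3 / 1000.0,
        "tmts_cm2": 4.0 * np.pi * r**2 / 100.0,
        "tvsr_mm": r / 3.0,
        "med_pcd_mm": r,
        "med_edge_mm": 2.0 * r,
        "n_roi": 1,
    }


def make_phantom(spec: PhantomSpec) -> tuple[SuvVolume, MaskVolume, dict]:
    """Build a phantom volume, its ground-truth mask, and analytic expectations.

    The ground-truth mask labels the analytic lesion interiors (fused pairs
    merge into one component; cluster fragments stay separate). The returned
    ``expectations`` dict carries whatever closed-form feature values exist
    for the requested geometry, including the two-lesion Dmax
    ``d + r1 + r2`` when exactly two primitive spheres are present.
    """
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.spacing, dtype=float)
    shape = tuple(spec.shape)
    grid_extent = (np.asarray(shape) - 1) * spacing
    idx = np.indices(shape).transpose(1, 2, 3, 0)
    coords = idx * spacing  # voxel centers, origin at voxel (0,0,0)

    values = np.full(shape, spec.background_suv, dtype=float)
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=shape)
    truth = np.zeros(shape, dtype=bool)
    for les in spec.lesions:
        contrib, inside = _paint_lesion(les, coords, spacing, grid_extent)
        values = np.maximum(values, contrib)
        if les.profile == "plateau":
            truth |= inside
        else:
            truth |= contrib >= 0.41 * les.peak_suv
    decoy = np.zeros(shape, dtype=bool)
    for les in spec.decoys:
        contrib, inside = _paint_lesion(les, coords, spacing, grid_extent)
        values = np.maximum(values, contrib)
        decoy |= inside
    values = np.clip(values, 0.0, None)

    labels, _ = label_components(truth, connectivity=26)
    vol = SuvVolume(values=values, spacing=tuple(spacing))
    mask = MaskVolume(labels=labels, spacing=tuple(spacing))
    exclusion = MaskVolume(labels=decoy.astype(np.int32), spacing=tuple(spacing)) if spec.decoys else None

    expectations: dict = {"n_roi": int(labels.max())}
    spheres = []
    for les in spec.lesions:
        if les.shape == "sphere" and len(spec.lesions) == 1:
            expectations.update(sphere_expectations(float(les.size_mm)))
        if les.shape in ("sphere", "fused_pair", "fragmented_cluster"):
            spheres.extend(_sphere_centers(les))
    if len(spheres) == 2:
        (c1, r1), (c2, r2) = spheres
        expectations["dmax_mm"] = float(np.linalg.norm(c1 - c2) + r1 + r2)
    expectations["exclusion"] = exclusion
    return vol, mask, expectations


# ---------------------------------------------------------------------------
# Cohorts


#: Log-normal marginal moments (mean, SD) per feature: a high-burden FL cohort.
DEFAULT_MARGINALS: dict[str, tuple[float, float]] = {
    "suv_max": (14.2, 7.0),
    "suv_mean": (4.3, 1.8),
    "tmtv_cm3": (867.8, 731.0),
    "tlg": (3857.3, 3819.5),
    "tmts_cm2": (1619.9, 1193.1),
    "tvsr_mm": (5.2, 1.6),
    "dmax_mm": (570.4, 198.3),
    "tumbb_cm3": (22571.7, 16054.2),
    "n_roi": (13.2, 13.2),
    "med_edge_mm": (37.2, 12.6),
    "med_pcd_mm": (37.6, 16.2),
    "it_erosion": (2.8, 0.8),
}

#: Dichotomization cut-offs of the score features (POD24-optimal values).
DEFAULT_CUTOFFS = {"tmtv_cm3": 1195.248, "tvsr_mm": 4.854, "med_pcd_mm": 36.932}

#: Hazard ratios per high indicator.
DEFAULT_HAZARD_RATIOS = {"tmtv_cm3": 4.341, "tvsr_mm": 3.204, "med_pcd_mm": 4.507}


@dataclass
class CohortSpec:
    """Generative model for a synthetic patient cohort.

    Survival follows an exponential (optionally Weibull) time-to-progression
    whose log hazard is additive in the three dichotomized score features;
    the baseline hazard is calibrated so the expected POD24 prevalence
    matches ``pod24_prevalence``. Censoring is independent exponential,
    calibrated to the target overall censoring fraction.
    """

    n: int = 126
    pod24_prevalence: float = 0.222
    within_rho: float = 0.8
    between_rho: float = 0.2
    cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    hazard_ratios: dict = field(default_factory=lambda: dict(DEFAULT_HAZARD_RATIOS))
    censoring_fraction: float = 0.25
    baseline: str = "exponential"
    weibull_shape: float = 1.0
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pod24_prevalence < 1:
            raise ValueError("pod24_prevalence must be in (0, 1)")
        if self.within_rho <= self.between_rho:
            raise ValueError("within-block correlation must exceed between-block correlation")
        if self.baseline not in ("exponential", "weibull"):
            raise ValueError(f"baseline must be exponential or weibull, got {self.baseline!r}")


def block_correlation_matrix(within: float, between: float, columns=FEATURE_COLUMNS) -> np.ndarray:
    """The 4-block feature correlation matrix (unit diagonal)."""
    block_of = {}
    for b, cols in FEATURE_CLUSTERS.items():
        for c in cols:
            block_of[c] = b
    k = len(columns)
    R = np.full((k, k), between)
    for i, ci in enumerate(columns):
        for j, cj in enumerate(columns):
            if block_of[ci] == block_of[cj]:
                R[i, j] = within
    np.fill_diagonal(R, 1.0)
    eig = np.linalg.eigvalsh(R)
    if eig.min() < -1e-10:
        raise ValueError(f"correlation matrix is not positive semi-definite (min eigenvalue {eig.min():.3g})")
    return R


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def simulate_outcomes(
    features: pd.DataFrame,
    cutoffs: dict[str, float],
    hazard_ratios: dict[str, float],
    prevalence: float = 0.222,
    censoring_fraction: float = 0.25,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Attach exponential survival outcomes to an existing feature table.

    The hazard is additive in the log of each feature's hazard ratio,
    switched on when the feature is at or above its cut-off; the baseline
    hazard is calibrated so the expected 24-month event fraction equals
    ``prevalence``. Returns a copy of ``features`` with pfs/os/pod24
    columns appended.
    """
    rng = rng or np.random.default_rng(0)
    n = len(features)
    log_mult = np.zeros(n)
    for col, cut in cutoffs.items():
        log_mult += np.log(hazard_ratios.get(col, 1.0)) * (features[col].to_numpy() >= cut)
    mult = np.exp(log_mult)
    h0 = optimize.brentq(lambda h: float(np.mean(1 - np.exp(-h * mult * 24.0))) - prevalence, 1e-10, 10.0)
    rates = h0 * mult
    event_times = rng.exponential(1.0 / rates)
    if censoring_fraction > 0:
        rc = optimize.brentq(lambda r: float(np.mean(r / (r + rates))) - censoring_fraction, 1e-12, 1e4)
        censor_times = rng.exponential(1.0 / rc, size=n)
    else:
        censor_times = np.full(n, np.inf)
    out = features.copy()
    out["pfs_time_months"] = np.minimum(event_times, censor_times)
    out["pfs_event"] = (event_times <= censor_times).astype(int)
    death_times = event_times + rng.exponential(60.0, size=n)
    out["os_time_months"] = np.minimum(death_times, np.maximum(censor_times, out["pfs_time_months"]))
    out["os_event"] = (death_times <= np.maximum(censor_times, out["pfs_time_months"])).astype(int)
    out["pod24"] = ((out["pfs_event"] == 1) & (out["pfs_time_months"] <= 24.0)).astype(int)
    return out


def make_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a cohort table and its generative ground truth.

    Returns ``(cohort, truth)``; truth records the block memberships, the
    true cut-offs and hazard ratios, the calibrated baseline hazard, the
    per-patient high indicators and the realized censoring fraction.
    """
    rng = np.random.default_rng(spec.seed)
    columns = list(spec.marginals)
    R = block_correlation_matrix(spec.within_rho, spec.between_rho, columns)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(columns)))
    Z = rng.standard_normal((spec.n, len(columns))) @ L.T

    cohort = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(spec.n)]})
    for j, col in enumerate(columns):
        mu, sigma = _lognormal_params(*spec.marginals[col])
        vals = np.exp(mu + sigma * Z[:, j])
        if col == "n_roi":
            vals = np.maximum(1, np.rint(vals))
        cohort[col] = vals

    # hazard: additive log-hazard in the dichotomized score features
    log_mult = np.zeros(spec.n)
    indicators = {}
    for colname, cut in spec.cutoffs.items():
        ind = (cohort[colname].to_numpy() >= cut).astype(int)
        indicators[colname] = ind
        log_mult += np.log(spec.hazard_ratios.get(colname, 1.0)) * ind
    mult = np.exp(log_mult)

    def prevalence(h0: float) -> float:
        if spec.baseline == "exponential":
            p = 1.0 - np.exp(-h0 * mult * 24.0)
        else:
            p = 1.0 - np.exp(-h0 * mult * 24.0**spec.weibull_shape)
        return float(p.mean())

    h0 = optimize.brentq(lambda h: prevalence(h) - spec.pod24_prevalence, 1e-10, 10.0)
    rates = h0 * mult
    u = rng.uniform(size=spec.n)
    if spec.baseline == "exponential":
        event_times = -np.log(u) / rates
    else:
        event_times = (-np.log(u) / rates) ** (1.0 / spec.weibull_shape)

    # independent exponential censoring calibrated to the target fraction
    if spec.censoring_fraction > 0 and spec.baseline == "exponential":
        def cens_frac(rc: float) -> float:
            return float(np.mean(rc / (rc + rates)))

        rc = optimize.brentq(lambda r: cens_frac(r) - spec.censoring_fraction, 1e-12, 1e4)
        censor_times = rng.exponential(1.0 / rc, size=spec.n)
    elif spec.censoring_fraction > 0:
        censor_times = rng.exponential(event_times.mean() / spec.censoring_fraction, size=spec.n)
    else:
        censor_times = np.full(spec.n, np.inf)

    pfs_time = np.minimum(event_times, censor_times)
    pfs_event = (event_times <= censor_times).astype(int)
    # overall survival: death lags progression; few events, long follow-up
    death_times = event_times + rng.exponential(60.0, size=spec.n)
    os_time = np.minimum(death_times, np.maximum(censor_times, pfs_time))
    os_event = (death_times <= np.maximum(censor_times, pfs_time)).astype(int)

    cohort["pfs_time_months"] = pfs_time
    cohort["pfs_event"] = pfs_event
    cohort["os_time_months"] = os_time
    cohort["os_event"] = os_event
    cohort["pod24"] = ((pfs_event == 1) & (pfs_time <= 24.0)).astype(int)

    truth = {
        "blocks": {b: list(cols) for b, cols in FEATURE_CLUSTERS.items()},
        "cutoffs": dict(spec.cutoffs),
        "hazard_ratios": dict(spec.hazard_ratios),
        "baseline_hazard": h0,
        "indicators": pd.DataFrame(indicators),
        "censoring_fraction": float(1 - pfs_event.mean()),
        "event_times": event_times,
    }
    return cohort, truth
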