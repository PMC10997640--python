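"""The twelve per-patient PET parameters.

Four families of quantities are computed from a segmented lesion set:

* activity — SUVmax, SUVmean over the tumor voxels;
* burden — TMTV (cm³), TLG (SUV·cm³), TMTS (cm²);
* massiveness / fragmentation — TVSR (mm), medPCD (mm), medEDGE (mm),
  itErosion (erosion iterations);
* dispersion — Dmax (mm), TumBB (cm³), nROI.

Several of these have no universally agreed operational definition; the
:class:`FeatureConfig` selectors pin the variant used and are echoed into
every output so results remain interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

from .io import FEATURE_COLUMNS, SuvVolume
from .segmentation import Lesion, LesionSet

MM3_PER_CM3 = 1000.0
MM2_PER_CM2 = 100.0


@dataclass
class FeatureConfig:
    """Variant selectors for the under-specified feature definitions."""

    surface_method: str = "marching_cubes"          # or "voxel_faces"
    dmax_mode: str = "voxel_pair"                   # or "centroid_pair"
    medpcd_aggregation: str = "pooled_surface_voxels"   # or "per_lesion_median_then_median"
    mededge_mode: str = "median_lesion_max_diameter"
    iterosion_aggregation: str = "volume_weighted_mean"  # or "mean", "median"
    erosion_structuring_element: int = 26           # or 6

    _CHOICES = {
        "surface_method": ("marching_cubes", "voxel_faces"),
        "dmax_mode": ("voxel_pair", "centroid_pair"),
        "medpcd_aggregation": ("pooled_surface_voxels", "per_lesion_median_then_median"),
        "mededge_mode": ("median_lesion_max_diameter",),
        "iterosion_aggregation": ("volume_weighted_mean", "mean", "median"),
        "erosion_structuring_element": (6, 26),
    }

    def __post_init__(self) -> None:
        for name, choices in self._CHOICES.items():
            if getattr(self, name) not in choices:
                raise ValueError(f"{name} must be one of {choices}, got {getattr(self, name)!r}")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class FeaturePanel:
    """The twelve PET parameters of one patient."""

    suv_max: float
    suv_mean: float
    tmtv_cm3: float
    tlg: float
    tmts_cm2: float
    tvsr_mm: float
    dmax_mm: float
    tumbb_cm3: float
    n_roi: int
    med_edge_mm: float
    med_pcd_mm: float
    it_erosion: float

    def as_dict(self) -> dict:
        d = asdict(self)
        return {k: d[k] for k in FEATURE_COLUMNS}


def _require_lesions(lesions: LesionSet) -> None:
    if len(lesions) == 0:
        raise ValueError("feature extraction requires at least one lesion")


def suv_statistics(vol: SuvVolume, lesions: LesionSet) -> tuple[float, float]:
    """SUVmax and SUVmean over the union of all lesion voxels."""
    _require_lesions(lesions)
    vals = np.concatenate([vol.values[tuple(les.voxels.T)] for les in lesions])
    return float(vals.max()), float(vals.mean())


def tmtv(lesions: LesionSet) -> float:
    """Total metabolic tumor volume in cm³."""
    _require_lesions(lesions)
    return sum(les.volume_mm3 for les in lesions) / MM3_PER_CM3


def tlg(vol: SuvVolume, lesions: LesionSet) -> float:
    """Total lesion glycolysis: Σ SUV × voxel volume (SUV·cm³)."""
    _require_lesions(lesions)
    voxvol_cm3 = lesions.voxel_volume_mm3 / MM3_PER_CM3
    total = 0.0
    for les in lesions:
        total += float(vol.values[tuple(les.voxels.T)].sum()) * voxvol_cm3
    return total


def _lesion_surface_area_mm2(les: Lesion, spacing, method: str) -> float:
    """Surface area of one binary lesion in mm².

    The marching-cubes variant extracts the 0.5 iso-surface of the binary
    mask after a one-voxel Gaussian pre-smoothing, which removes the
    voxelization staircase so the area converges to the true surface for
    smooth shapes; lesions too small to survive smoothing fall back to the
    raw binary iso-surface.
    """
    pad = 4  # room for the smoothing kernel so the surface closes
    lo = les.voxels.min(axis=0)
    hi = les.voxels.max(axis=0)
    sub = np.zeros(hi - lo + 2 * pad + 1, dtype=float)
    sub[tuple((les.voxels - lo + pad).T)] = 1.0
    if method == "marching_cubes":
        smoothed = ndimage.gaussian_filter(sub, sigma=1.0)
        field = smoothed if smoothed.max() > 0.5 else sub
        verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=spacing)
        return float(measure.mesh_surface_area(verts, faces))
    # voxel_faces: every face between a lesion voxel and a background voxel
    sx, sy, sz = spacing
    face_area = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    binary = sub > 0.5
    area = 0.0
    for axis in range(3):
        diff = np.diff(binary.astype(np.int8), axis=axis)
        area += np.count_nonzero(diff) * face_area[axis]
    return float(area)


def tmts(lesions: LesionSet, cfg: FeatureConfig | None = None) -> float:
    """Total metabolic tumor surface in cm² (summed over lesions)."""
    _require_lesions(lesions)
    cfg = cfg or FeatureConfig()
    total = sum(_lesion_surface_area_mm2(les, lesions.spacing, cfg.surface_method) for les in lesions)
    return total / MM2_PER_CM2


def tvsr(tmtv_cm3: float, tmts_cm2: float) -> float:
    """Tumor volume-surface ratio in mm: (TMTV mm³)/(TMTS mm²)."""
    if tmts_cm2 <= 0:
        raise ValueError("TVSR undefined for zero surface")
    return (tmtv_cm3 * MM3_PER_CM3) / (tmts_cm2 * MM2_PER_CM2)


def _max_pairwise_distance(points_mm: np.ndarray) -> float:
    """Largest Euclidean distance among points, convex-hull accelerated."""
    if len(points_mm) < 2:
        return 0.0
    pts = points_mm
    if len(pts) > 64:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) sets: fall back to all pairs
    return float(pdist(pts).max())


def dmax(lesions: LesionSet, cfg: FeatureConfig | None = None) -> float:
    """Largest distance between two tumor loci, in mm.

    ``voxel_pair`` (default): max distance between centers of any two tumor
    voxels across all lesions (a single lesion yields its own max extent).
    ``centroid_pair``: max distance between lesion centroids (0 if single).
    """
    _require_lesions(lesions)
    cfg = cfg or FeatureConfig()
    spacing = np.asarray(lesions.spacing)
    if cfg.dmax_mode == "centroid_pair":
        cents = np.array([les.centroid_mm for les in lesions])
        return _max_pairwise_distance(cents)
    # extremal voxel pairs lie on lesion surfaces, so pooling surface voxels suffices
    pts = np.concatenate([les.surface_voxels * spacing for les in lesions])
    return _max_pairwise_distance(pts)


def tumbb(lesions: LesionSet) -> float:
    """Volume of the axis-aligned bounding box of all tumor voxels, cm³."""
    _require_lesions(lesions)
    allvox = np.concatenate([les.voxels for les in lesions])
    extent = (allvox.max(axis=0) - allvox.min(axis=0) + 1) * np.asarray(lesions.spacing)
    return float(np.prod(extent)) / MM3_PER_CM3


def med_pcd(lesions: LesionSet, cfg: FeatureConfig | None = None) -> float:
    """Median distance between lesion centroids and their periphery, mm.

    Distances run from each lesion's centroid to each of its surface-voxel
    centers; by default all distances are pooled across lesions before
    taking the median.
    """
    _require_lesions(lesions)
    cfg = cfg or FeatureConfig()
    spacing = np.asarray(lesions.spacing)
    per_lesion = []
    for les in lesions:
        d = np.linalg.norm(les.surface_voxels * spacing - les.centroid_mm, axis=1)
        per_lesion.append(d)
    if cfg.medpcd_aggregation == "pooled_surface_voxels":
        return float(np.median(np.concatenate(per_lesion)))
    return float(np.median([np.median(d) for d in per_lesion]))


def med_edge(lesions: LesionSet, cfg: FeatureConfig | None = None) -> float:
    """Median over lesions of the maximal edge-to-edge extent, mm.

    Each lesion contributes the largest pairwise distance between its
    surface-voxel centers (its maximal diameter).
    """
    _require_lesions(lesions)
    cfg = cfg or FeatureConfig()
    spacing = np.asarray(lesions.spacing)
    diameters = [_max_pairwise_distance(les.surface_voxels * spacing) for les in lesions]
    return float(np.median(diameters))


def _erosion_count(les: Lesion, structure: np.ndarray) -> int:
    lo = les.voxels.min(axis=0)
    hi = les.voxels.max(axis=0)
    sub = np.zeros(hi - lo + 1, dtype=bool)
    sub[tuple((les.voxels - lo).T)] = True
    count = 0
    while sub.any():
        sub = ndimage.binary_erosion(sub, structure=structure, border_value=0)
        count += 1
    return count


def it_erosion(lesions: LesionSet, cfg: FeatureConfig | None = None) -> float:
    """Erosion depth: iterations of binary erosion needed to empty a lesion.

    Aggregated across lesions by volume-weighted mean by default, so the
    cohort statistic can be fractional.
    """
    _require_lesions(lesions)
    cfg = cfg or FeatureConfig()
    rank = 3 if cfg.erosion_structuring_element == 26 else 1
    structure = ndimage.generate_binary_structure(3, rank)
    counts = np.array([_erosion_count(les, structure) for les in lesions], dtype=float)
    if cfg.iterosion_aggregation == "volume_weighted_mean":
        weights = np.array([les.volume_mm3 for les in lesions])
        return float(np.average(counts, weights=weights))
    if cfg.iterosion_aggregation == "mean":
        return float(counts.mean())
    return float(np.median(counts))


def feature_panel(vol: SuvVolume, lesions: LesionSet, cfg: FeatureConfig | None = None) -> FeaturePanel:
    """Assemble all twelve parameters and assert their internal identities."""
    _require_lesions(lesions)
    cfg = cfg or FeatureConfig()
    smax, smean = suv_statistics(vol, lesions)
    v = tmtv(lesions)
    s = tmts(lesions, cfg)
    panel = FeaturePanel(
        suv_max=smax,
        suv_mean=smean,
        tmtv_cm3=v,
        tlg=tlg(vol, lesions),
        tmts_cm2=s,
        tvsr_mm=tvsr(v, s),
        dmax_mm=dmax(lesions, cfg),
        tumbb_cm3=tumbb(lesions),
        n_roi=lesions.n_roi,
        med_edge_mm=med_edge(lesions, cfg),
        med_pcd_mm=med_pcd(lesions, cfg),
        it_erosion=it_erosion(lesions, cfg),
    )
    assert abs(panel.tlg - panel.tmtv_cm3 * panel.suv_mean) <= 1e-6 * max(panel.tlg, 1e-12)
    assert panel.tumbb_cm3 >= panel.tmtv_cm3 * (1 - 1e-12)
    return panel
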