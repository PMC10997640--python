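"""Lesion segmentation by relative SUV thresholding.

The delineation rule is the EANM-style 41%-of-SUVmax threshold: a lesion is
the connected set of voxels whose SUV is at least ``threshold_fraction``
times the lesion's own maximum SUV. Because the lesion maximum is only
known once the lesion is delineated, growth is a fixed point: grow from a
seed at the current threshold, update the lesion maximum, re-grow, until
the region is stable. A global-threshold mode (fraction of the volume-wide
SUVmax) is available for cross-study comparisons.

Physiological uptake (brain, heart, urinary tract...) is excluded via an
optional user-supplied exclusion mask, standing in for the visual check an
imaging physician performs. Diffusely hot spleens are handled by the
dedicated 150%-of-liver-background rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import MaskVolume, SuvVolume

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}, got {connectivity}")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


@dataclass
class SegmentationConfig:
    """Parameters of the threshold-based segmentation.

    threshold_fraction : fraction of lesion SUVmax defining the iso-contour
        (0.41 default, the EANM lymphoma recommendation).
    seed_min_suv : absolute SUV floor for automatic seed detection (2.5).
    connectivity : voxel neighborhood, one of {6, 18, 26}.
    min_lesion_voxels : components smaller than this are discarded.
    global_threshold : threshold at a fraction of the volume-wide SUVmax
        instead of each lesion's own maximum.
    background_stat : statistic summarising liver/spleen ROI uptake for the
        spleen inclusion rule ("mean" or "median").
    """

    threshold_fraction: float = 0.41
    seed_min_suv: float = 2.5
    connectivity: int = 26
    min_lesion_voxels: int = 2
    global_threshold: bool = False
    background_stat: str = "mean"

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError(f"threshold_fraction must be in (0, 1), got {self.threshold_fraction}")
        if self.seed_min_suv <= 0:
            raise ValueError(f"seed_min_suv must be positive, got {self.seed_min_suv}")
        _structure(self.connectivity)
        if self.background_stat not in ("mean", "median"):
            raise ValueError(f"background_stat must be 'mean' or 'median', got {self.background_stat}")


@dataclass
class Lesion:
    """One segmented lesion with derived geometry (distances in mm)."""

    label: int
    voxels: np.ndarray          # (n, 3) int voxel indices
    volume_mm3: float
    centroid_mm: np.ndarray     # (3,) physical centroid of voxel centers
    surface_voxels: np.ndarray  # (m, 3) lesion voxels with a 6-neighbor outside
    suv_max: float
    suv_mean: float

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclass
class LesionSet:
    """All lesions of one patient plus the shared grid geometry."""

    lesions: list[Lesion]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.lesions)

    def __iter__(self):
        return iter(self.lesions)

    @property
    def n_roi(self) -> int:
        return len(self.lesions)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def to_mask(self, origin=(0.0, 0.0, 0.0)) -> MaskVolume:
        labels = np.zeros(self.shape, dtype=np.int32)
        for les in self.lesions:
            labels[tuple(les.voxels.T)] = les.label
        return MaskVolume(labels=labels, spacing=self.spacing, origin=origin)


def surface_voxel_mask(binary: np.ndarray) -> np.ndarray:
    """Voxels of ``binary`` with at least one 6-neighbor outside it."""
    eroded = ndimage.binary_erosion(binary, structure=_structure(6), border_value=0)
    return binary & ~eroded


def lesion_set_from_labels(
    labels: np.ndarray,
    spacing: tuple[float, float, float],
    suv: np.ndarray | None = None,
) -> LesionSet:
    """Build a :class:`LesionSet` from a consecutive label grid."""
    spacing_arr = np.asarray(spacing, dtype=float)
    voxvol = float(np.prod(spacing_arr))
    lesions = []
    for lab in range(1, int(labels.max()) + 1):
        binary = labels == lab
        idx = np.argwhere(binary)
        if len(idx) == 0:
            continue
        surf = np.argwhere(surface_voxel_mask(binary))
        vals = suv[tuple(idx.T)] if suv is not None else np.zeros(len(idx))
        lesions.append(
            Lesion(
                label=lab,
                voxels=idx,
                volume_mm3=len(idx) * voxvol,
                centroid_mm=idx.mean(axis=0) * spacing_arr,
                surface_voxels=surf,
                suv_max=float(vals.max()) if len(vals) else 0.0,
                suv_mean=float(vals.mean()) if len(vals) else 0.0,
            )
        )
    return LesionSet(lesions=lesions, spacing=tuple(spacing), shape=labels.shape)


def detect_seeds(
    vol: SuvVolume,
    cfg: SegmentationConfig | None = None,
    exclusion: MaskVolume | None = None,
) -> list[tuple[int, int, int]]:
    """Find candidate lesion seeds: 26-neighborhood local maxima above the floor.

    Returns voxel indices sorted by SUV descending; an empty list is valid.
    """
    cfg = cfg or SegmentationConfig()
    values = vol.values
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = values == ndimage.maximum_filter(values, footprint=footprint, mode="constant", cval=-np.inf)
    candidate = local_max & (values >= cfg.seed_min_suv)
    if exclusion is not None:
        candidate &= exclusion.labels == 0
    idx = np.argwhere(candidate)
    order = np.argsort(-values[tuple(idx.T)], kind="stable")
    return [tuple(int(i) for i in row) for row in idx[order]]


def grow_lesion(vol: SuvVolume, seed: tuple[int, int, int], cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Grow one lesion from a seed by fixed-point relative thresholding.

    Returns the boolean mask of the connected component containing the seed
    within ``{SUV >= threshold_fraction * lesion SUVmax}``, where the lesion
    SUVmax is the maximum reached inside the grown region; the region is
    re-grown until the maximum stops changing.
    """
    cfg = cfg or SegmentationConfig()
    values = vol.values
    struct = _structure(cfg.connectivity)
    if cfg.global_threshold:
        local_max = float(values.max())
    else:
        local_max = float(values[seed])
    while True:
        above = values >= cfg.threshold_fraction * local_max
        labels, _ = ndimage.label(above, structure=struct)
        region = labels == labels[seed]
        new_max = float(values[region].max())
        if new_max <= local_max or cfg.global_threshold:
            return region
        local_max = new_max


def label_components(binary: np.ndarray, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Connected-component labeling of a binary mask; returns (labels, nROI)."""
    labels, n = ndimage.label(np.asarray(binary, dtype=bool), structure=_structure(connectivity))
    return labels, int(n)


def segment_lesions(
    vol: SuvVolume,
    cfg: SegmentationConfig | None = None,
    exclusion: MaskVolume | None = None,
    seeds: list[tuple[int, int, int]] | None = None,
) -> tuple[MaskVolume, LesionSet]:
    """Segment all lesions of a volume.

    Seeds are detected automatically unless supplied. Regions grown from
    different seeds that overlap or touch are merged by the final
    connected-component labeling; components below ``min_lesion_voxels``
    are discarded; labels are assigned 1..nROI by descending volume.
    """
    cfg = cfg or SegmentationConfig()
    if seeds is None:
        seeds = detect_seeds(vol, cfg, exclusion)
    union = np.zeros(vol.values.shape, dtype=bool)
    for seed in seeds:
        if union[tuple(seed)]:
            continue  # already captured by a previous (hotter) seed
        union |= grow_lesion(vol, tuple(seed), cfg)
    if exclusion is not None:
        union &= exclusion.labels == 0
    labels, n = label_components(union, cfg.connectivity)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = [lab for lab, sz in zip(range(1, n + 1), sizes) if sz >= cfg.min_lesion_voxels]
    # relabel by descending volume (stable for ties: ascending original label)
    keep.sort(key=lambda lab: (-sizes[lab - 1], lab))
    out = np.zeros_like(labels)
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new
    mask = MaskVolume(labels=out, spacing=vol.spacing, origin=vol.origin)
    return mask, lesion_set_from_labels(out, vol.spacing, vol.values)


def spleen_inclusion_rule(
    vol: SuvVolume,
    spleen_roi: MaskVolume,
    liver_roi: MaskVolume,
    cfg: SegmentationConfig | None = None,
) -> tuple[bool, np.ndarray | None]:
    """Decide whether a diffusely hot spleen is included wholesale.

    The whole spleen ROI becomes a lesion iff its background statistic
    (mean by default) is strictly greater than 150% of the liver background.
    Returns ``(include, spleen voxel indices or None)``.
    """
    cfg = cfg or SegmentationConfig()
    stat = np.mean if cfg.background_stat == "mean" else np.median
    spleen_mask = spleen_roi.labels > 0
    liver_mask = liver_roi.labels > 0
    if not spleen_mask.any():
        raise ValueError("spleen ROI is empty")
    if not liver_mask.any():
        raise ValueError("liver ROI is empty")
    spleen_suv = float(stat(vol.values[spleen_mask]))
    liver_suv = float(stat(vol.values[liver_mask]))
    if spleen_suv > 1.5 * liver_suv:
        return True, np.argwhere(spleen_mask)
    return False, None
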