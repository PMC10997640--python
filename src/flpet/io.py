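"""Reading and writing the formats the pipeline touches.

Images are NIfTI-1 (via nibabel); cohort tables are plain CSV (via pandas).
Voxel indices are 0-based and the physical position of a voxel center is
``origin + index * spacing`` in mm; all distances in this package are
computed between voxel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: Fixed month length used whenever day-level times must be converted.
DAYS_PER_MONTH = 30.44

#: The twelve PET parameters, in canonical column order.
FEATURE_COLUMNS = [
    "suv_max",
    "suv_mean",
    "tmtv_cm3",
    "tlg",
    "tmts_cm2",
    "tvsr_mm",
    "dmax_mm",
    "tumbb_cm3",
    "n_roi",
    "med_edge_mm",
    "med_pcd_mm",
    "it_erosion",
]

#: Survival/outcome columns required in a cohort table.
OUTCOME_COLUMNS = ["pfs_time_months", "pfs_event", "os_time_months", "os_event"]


class FormatError(ValueError):
    """Raised when an input file violates a format precondition."""


@dataclass
class SuvVolume:
    """A 3-D grid of body-weight SUV with anisotropic voxel spacing.

    Parameters
    ----------
    values : ndarray
        3-D float array of SUV (dimensionless).
    spacing : tuple of float
        Per-axis voxel size in mm, strictly positive.
    origin : tuple of float
        Physical offset of voxel (0, 0, 0) in mm.
    orientation : str
        Axis-order convention tag (informational).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise FormatError(f"SUV volume must be 3-D, got {self.values.ndim}-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"voxel spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("SUV values must be finite")
        if np.any(self.values < 0):
            raise FormatError("SUV values must be non-negative")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class MaskVolume:
    """An integer label grid aligned to a paired :class:`SuvVolume`.

    Label 0 is background; labels 1..n_labels are lesions (consecutive).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError(f"mask must be 3-D, got {self.labels.ndim}-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_suv_volume(path: str | Path) -> SuvVolume:
    """Read a 3-D SUV image from a NIfTI file.

    Spacing is taken from the header zooms (mm); values are returned
    as stored (beyond NIfTI scl_slope/scl_inter scaling).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D single-channel image, got shape {data.shape} (header dim)")
    if np.iscomplexobj(data):
        raise FormatError(f"{path}: complex-valued data is not supported (header datatype)")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel spacing in header pixdim: {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return SuvVolume(values=np.asarray(data, dtype=float), spacing=tuple(float(z) for z in zooms), origin=origin)


def write_suv_volume(vol: SuvVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask_volume(path: str | Path, paired: SuvVolume) -> MaskVolume:
    """Read a label mask and align it with its paired SUV volume.

    Labels are relabeled to consecutive 1..K (in increasing original order),
    preserving which voxels share a label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.shape != paired.values.shape:
        raise FormatError(
            f"{path}: mask shape {data.shape} does not match paired volume shape {paired.values.shape}"
        )
    rounded = np.rint(data)
    if np.max(np.abs(data - rounded)) > 1e-6:
        raise FormatError(f"{path}: mask contains non-integer values beyond tolerance 1e-6")
    labels = rounded.astype(np.int32)
    labels = relabel_consecutive(labels)
    return MaskVolume(labels=labels, spacing=paired.spacing, origin=paired.origin)


def write_mask_volume(mask: MaskVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.int16), _affine(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Map nonzero labels bijectively onto 1..K, keeping increasing order."""
    uniq = np.unique(labels)
    uniq = uniq[uniq != 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(uniq, start=1):
        out[labels == old] = new
    return out


# ---------------------------------------------------------------------------
# Cohort tables


REQUIRED_COHORT_COLUMNS = ["patient_id"] + FEATURE_COLUMNS + OUTCOME_COLUMNS


def validate_cohort(table: pd.DataFrame, require_features: bool = True) -> pd.DataFrame:
    """Validate a cohort table; raise ``FormatError`` naming the problem."""
    required = REQUIRED_COHORT_COLUMNS if require_features else ["patient_id"] + OUTCOME_COLUMNS
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"cohort table missing required columns: {missing}")
    if table["patient_id"].duplicated().any():
        dups = table.loc[table["patient_id"].duplicated(), "patient_id"].tolist()
        raise FormatError(f"duplicate patient_id values: {dups}")
    for col in ("pfs_time_months", "os_time_months"):
        bad = table.loc[table[col] < 0, "patient_id"].tolist()
        if bad:
            raise FormatError(f"negative {col} for patients: {bad}")
    for col in ("pfs_event", "os_event"):
        bad = table.loc[~table[col].isin([0, 1]), "patient_id"].tolist()
        if bad:
            raise FormatError(f"{col} outside {{0,1}} for patients: {bad}")
    if require_features:
        feat = table[FEATURE_COLUMNS]
        if not np.all(np.isfinite(feat.to_numpy(dtype=float))):
            raise FormatError("feature columns contain non-finite values")
    return table


def read_cohort_csv(path: str | Path, require_features: bool = True) -> pd.DataFrame:
    """Read and validate a per-patient cohort CSV."""
    table = pd.read_csv(path)
    return validate_cohort(table, require_features=require_features)


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table; round-trip stable to float text precision."""
    table.to_csv(path, index=False, float_format="%.12g")
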