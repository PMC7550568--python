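"""Volume and cohort I/O.

The fractal-dimension estimator operates on 3-D binary masks with isotropic
voxels (e.g. a cortical-ribbon segmentation exported from a surface
reconstruction pipeline).  This module enforces that contract at load time:
voxels are binarized with a nonzero rule, spacing is read from the NIfTI
header, and — in strict mode, the default for estimation — anisotropy beyond
a 1e-3 relative tolerance is rejected, because an anisotropic grid silently
distorts the physical scale axis of the log-log fit.

Cohort tables (one row per subject: id, age, sex, eTIV and morphometric
feature columns) are plain CSV files read into pandas DataFrames after
validation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    AnisotropicVoxelsError,
    DuplicateSubjectIdError,
    FileUnreadableError,
    MissingColumnError,
    NonNumericValueError,
    NotThreeDimensionalError,
    PathNotWritableError,
)

#: relative tolerance on max/min voxel-spacing ratio for "isotropic"
ISOTROPY_RTOL = 1e-3

#: fixed encoding of sex strings to the 0/1 code used in design matrices
SEX_CODES = {"M": 0, "F": 1, "m": 0, "f": 1, "male": 0, "female": 1}


@dataclass
class VoxelVolume:
    """A 3-D binary mask with physical voxel spacing.

    Parameters
    ----------
    data
        3-D array with values in {0, 1}; 1 marks foreground.
    spacing
        Per-axis voxel size in mm; all entries must be positive.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise NotThreeDimensionalError(
                f"expected a 3-D array, got ndim={self.data.ndim}"
            )
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    def is_isotropic(self, rtol: float = ISOTROPY_RTOL) -> bool:
        s = self.spacing
        return max(s) / min(s) <= 1.0 + rtol

    @property
    def spacing_mm(self) -> float:
        """Scalar voxel size in mm; only meaningful for isotropic volumes."""
        if not self.is_isotropic():
            raise AnisotropicVoxelsError(
                f"spacing {self.spacing} is anisotropic; no scalar voxel size"
            )
        return self.spacing[0]

    def require_isotropic(self, rtol: float = ISOTROPY_RTOL) -> None:
        if not self.is_isotropic(rtol):
            raise AnisotropicVoxelsError(
                f"voxel spacing {self.spacing} exceeds isotropy tolerance {rtol}"
            )


def load_mask(path: str | os.PathLike, threshold_rule: str = "nonzero",
              strict: bool = True) -> VoxelVolume:
    """Load a NIfTI volume as a binary mask.

    Any nonzero voxel becomes foreground (covers both label images and
    float probability masks that were thresholded upstream).  With
    ``strict=True`` (the default), anisotropic voxel spacing raises
    :class:`AnisotropicVoxelsError`.
    """
    if threshold_rule != "nonzero":
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    try:
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FileUnreadableError(f"cannot read {path}: {exc}") from exc
    # tolerate trailing singleton dimensions (4-D files with one frame)
    while arr.ndim > 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim != 3:
        raise NotThreeDimensionalError(
            f"{path}: expected 3-D volume, got shape {arr.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    vol = VoxelVolume(data=(arr != 0).astype(np.uint8), spacing=spacing)
    if strict:
        vol.require_isotropic()
    return vol


def save_mask(vol: VoxelVolume, path: str | os.PathLike) -> None:
    """Write a mask to NIfTI (.nii or .nii.gz); exact round trip with
    :func:`load_mask`."""
    affine = np.diag([*vol.spacing, 1.0])
    img = nib.Nifti1Image(vol.data.astype(np.uint8), affine)
    img.header.set_zooms(vol.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise PathNotWritableError(f"cannot write {path}: {exc}") from exc


def load_cohort(path: str | os.PathLike,
                required_columns: Sequence[str] = ("subject_id", "age"),
                ) -> pd.DataFrame:
    """Load a subject table from CSV and validate it.

    Checks that required columns exist, that every required column other
    than ``subject_id`` is numeric, and that subject ids are unique.
    Returns a plain :class:`pandas.DataFrame`.
    """
    try:
        df = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise FileUnreadableError(f"cannot read {path}: {exc}") from exc
    return validate_cohort(df, required_columns)


def validate_cohort(df: pd.DataFrame,
                    required_columns: Sequence[str] = ("subject_id", "age"),
                    ) -> pd.DataFrame:
    """Validate an in-memory cohort table (shared by CSV load and tests)."""
    for col in required_columns:
        if col not in df.columns:
            raise MissingColumnError(f"required column {col!r} missing")
    for col in required_columns:
        if col == "subject_id":
            continue
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                raise NonNumericValueError(f"column {col!r} is not numeric")
            df = df.assign(**{col: coerced})
    if "subject_id" in df.columns and df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise DuplicateSubjectIdError(f"duplicated subject ids: {dupes}")
    if "age" in required_columns and (df["age"] <= 0).any():
        raise NonNumericValueError("ages must be strictly positive")
    return df
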