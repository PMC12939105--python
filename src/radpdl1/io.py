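"""NIfTI volume/mask IO and cohort manifests.

Volumes and masks travel as NIfTI with an axis-aligned affine whose
diagonal carries the voxel spacing; affines with shear or rotation are
rejected because the whole pipeline assumes axis-aligned grids.  Cohort
manifests are CSV with columns ``patient_id, volume_path, mask_path`` plus
optional ``pdl1_class`` (blank = unlabeled pool), ``time_months``,
``event`` and covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import LesionVolume

PDL1_ENCODINGS = {"<50%": 0, ">=50%": 1, "≥50%": 1}


def write_nifti(path, array: np.ndarray,
                spacing_mm: tuple[float, float, float]) -> None:
    affine = np.diag(list(spacing_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine)
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    aff = img.affine[:3, :3]
    off_diag = aff - np.diag(np.diag(aff))
    if np.abs(off_diag).max() > 1e-6:
        raise ValueError(
            f"{path}: affine has shear/rotation; the pipeline assumes "
            "axis-aligned grids")
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    return np.asarray(img.dataobj, dtype=np.float64), spacing


def write_volume(vol: LesionVolume, volume_path, mask_path) -> None:
    write_nifti(volume_path, vol.intensities, vol.spacing_mm)
    write_nifti(mask_path, vol.mask.astype(np.uint8), vol.spacing_mm)


def read_volume(volume_path, mask_path, patient_id: str = "") -> LesionVolume:
    intens, spacing = read_nifti(volume_path)
    mask, mspacing = read_nifti(mask_path)
    if any(abs(a - b) > 1e-5 for a, b in zip(spacing, mspacing)):
        raise ValueError(f"{patient_id}: volume and mask spacing disagree")
    return LesionVolume(intens, spacing, mask > 0.5, patient_id)


@dataclass
class CohortManifest:
    table: pd.DataFrame  # validated manifest rows
    root: Path           # paths in the table are resolved against this

    @property
    def labeled_ids(self) -> list[str]:
        return list(self.table.loc[self.table["pdl1_class"].notna(),
                                   "patient_id"])

    @property
    def unlabeled_ids(self) -> list[str]:
        return list(self.table.loc[self.table["pdl1_class"].isna(),
                                   "patient_id"])

    def load_volume(self, patient_id: str) -> LesionVolume:
        row = self.table.set_index("patient_id").loc[patient_id]
        return read_volume(self.root / row["volume_path"],
                           self.root / row["mask_path"], patient_id)


def read_manifest(csv_path, check_files: bool = True) -> CohortManifest:
    """Load and validate a cohort manifest CSV.

    Rows without a PD-L1 class form the unlabeled pool.  Duplicate ids,
    missing files, negative times and unknown label encodings are rejected
    with the offending rows named.
    """
    path = Path(csv_path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "volume_path", "mask_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")

    dup = df["patient_id"].duplicated(keep=False)
    if dup.any():
        raise ValueError(
            f"duplicate patient_id at rows {list(df.index[dup] + 2)}")

    if "pdl1_class" in df.columns:
        raw = df["pdl1_class"]
        decoded = []
        for i, v in raw.items():
            if pd.isna(v) or str(v).strip() == "":
                decoded.append(np.nan)
            elif str(v).strip() in PDL1_ENCODINGS:
                decoded.append(float(PDL1_ENCODINGS[str(v).strip()]))
            elif str(v).strip() in {"0", "1", "0.0", "1.0"}:
                decoded.append(float(int(float(v))))
            else:
                raise ValueError(
                    f"row {i + 2}: pdl1_class {v!r} not in "
                    "{<50%, >=50%, 0, 1}")
        df["pdl1_class"] = decoded
    else:
        df["pdl1_class"] = np.nan

    if "time_months" in df.columns:
        bad = df["time_months"].notna() & (df["time_months"] <= 0)
        if bad.any():
            raise ValueError(
                f"non-positive time_months at rows {list(df.index[bad] + 2)}")

    root = path.parent
    if check_files:
        for i, row in df.iterrows():
            for col in ("volume_path", "mask_path"):
                if not (root / row[col]).exists():
                    raise ValueError(f"row {i + 2}: missing file {row[col]}")
    return CohortManifest(df, root)


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=True)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id")
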