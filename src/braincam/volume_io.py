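"""Volumes, cohort tables, resampling, and the BMI formula.

Volumes are NIfTI-1 images (via nibabel) holding a single 3D intensity
grid together with voxel spacing and an affine mapping grid indices to
world (mm) coordinates.  Cohorts are CSV tables with the fixed header
``subject_id,volume_path,age_years,sex,bmi``; the bmi column may be empty
for prediction-only cohorts.

Intensities are used as stored: no normalization is applied before the
network unless explicitly requested downstream.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DimensionalityError, DomainError, ValidationError

__all__ = [
    "Volume",
    "SubjectRecord",
    "CohortTable",
    "read_volume",
    "write_volume",
    "resample_volume",
    "compute_bmi",
    "read_cohort",
    "write_cohort_csv",
    "split_cohort",
]

COHORT_COLUMNS = ["subject_id", "volume_path", "age_years", "sex", "bmi"]


@dataclass
class Volume:
    """A 3D scalar intensity grid with spatial reference metadata."""

    intensities: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    space_label: str = ""
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise DimensionalityError(
                f"a Volume must be 3D, got {self.intensities.ndim} dimensions"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("volume intensities must all be finite")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValidationError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4×4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.intensities.shape)


@dataclass
class SubjectRecord:
    """One subject: volume reference, covariates, and (optional) target BMI."""

    subject_id: str
    volume_ref: "str | os.PathLike | Volume"
    age_years: float
    sex_code: int
    bmi_kg_m2: float | None = None

    def __post_init__(self):
        if self.sex_code not in (0, 1):
            raise ValidationError(
                f"subject {self.subject_id!r}: sex code must be 0 or 1, got {self.sex_code}"
            )
        if self.age_years < 0 or not math.isfinite(self.age_years):
            raise ValidationError(f"subject {self.subject_id!r}: invalid age {self.age_years}")
        if self.bmi_kg_m2 is not None:
            if not math.isfinite(self.bmi_kg_m2) or self.bmi_kg_m2 <= 0:
                raise ValidationError(
                    f"subject {self.subject_id!r}: BMI must be positive and finite, "
                    f"got {self.bmi_kg_m2}"
                )

    def load_volume(self, base_dir=None) -> Volume:
        if isinstance(self.volume_ref, Volume):
            return self.volume_ref
        path = os.fspath(self.volume_ref)
        if base_dir is not None and not os.path.isabs(path):
            path = os.path.join(os.fspath(base_dir), path)
        return read_volume(path)


@dataclass
class CohortTable:
    """An ordered collection of subject records with a split label."""

    records: list[SubjectRecord]
    split_label: str = "unsplit"
    base_dir: str | None = None

    def __post_init__(self):
        if self.split_label not in ("train", "validation", "test", "unsplit"):
            raise ValidationError(f"unknown split label {self.split_label!r}")
        seen = set()
        for r in self.records:
            if r.subject_id in seen:
                raise ValidationError(f"duplicate subject_id {r.subject_id!r} in cohort")
            seen.add(r.subject_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]


def read_volume(path) -> Volume:
    """Read a NIfTI-1 volume; shape, voxel size and affine come from the header."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    elif data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D image, got {data.ndim} dimensions {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    raw_label = img.header["descrip"].item()
    label = raw_label.decode(errors="replace") if isinstance(raw_label, bytes) else str(raw_label)
    return Volume(
        intensities=np.asarray(data, dtype=np.float32),
        voxel_size_mm=tuple(float(z) for z in zooms),
        space_label=label,
        affine=img.affine,
    )


def write_volume(volume: Volume, path) -> None:
    """Write a Volume as NIfTI-1 (use .nii.gz for compression)."""
    path = os.fspath(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    img = nib.Nifti1Image(np.asarray(volume.intensities, dtype=np.float32), volume.affine)
    img.header.set_zooms(volume.voxel_size_mm)
    if volume.space_label:
        img.header["descrip"] = volume.space_label.encode()[:79]
    nib.save(img, path)


def resample_volume(volume: Volume, factor: float, spline_order: int = 3) -> Volume:
    """Rescale a volume by ``factor`` with spline interpolation.

    Output axis lengths are round(input × factor); voxel size scales by
    1/factor.  ``factor=0.5`` maps 182×218×182 (1 mm) grids to 91×109×91
    (2 mm) grids.
    """
    if factor <= 0:
        raise DomainError(f"resampling factor must be positive, got {factor}")
    if not 0 <= spline_order <= 5:
        raise DomainError(f"spline order must be in 0..5, got {spline_order}")
    if factor == 1.0:
        return replace(volume, intensities=volume.intensities.copy(), affine=volume.affine.copy())
    data = ndimage.zoom(np.asarray(volume.intensities, dtype=np.float64), factor, order=spline_order)
    new_affine = volume.affine.copy()
    new_affine[:3, :3] = new_affine[:3, :3] / factor
    return Volume(
        intensities=data.astype(volume.intensities.dtype),
        voxel_size_mm=tuple(v / factor for v in volume.voxel_size_mm),
        space_label=volume.space_label,
        affine=new_affine,
    )


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index: weight (kg) divided by squared height (m)."""
    if weight_kg <= 0 or not math.isfinite(weight_kg):
        raise DomainError(f"weight must be positive, got {weight_kg}")
    if height_m <= 0 or not math.isfinite(height_m):
        raise DomainError(f"height must be positive, got {height_m}")
    return weight_kg / height_m**2


def read_cohort(csv_path) -> CohortTable:
    """Read a cohort CSV (``subject_id,volume_path,age_years,sex,bmi``).

    Relative volume paths are resolved against the CSV's directory.
    """
    csv_path = os.fspath(csv_path)
    df = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{csv_path}: missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based, counting the header line
        sid = row["subject_id"]
        try:
            age = float(row["age_years"])
        except ValueError:
            raise ValidationError(f"{csv_path} row {rowno}: unparseable age {row['age_years']!r}")
        if row["sex"] not in ("0", "1"):
            raise ValidationError(f"{csv_path} row {rowno}: sex must be 0 or 1, got {row['sex']!r}")
        bmi_text = row["bmi"].strip()
        if bmi_text == "":
            bmi = None
        else:
            try:
                bmi = float(bmi_text)
            except ValueError:
                raise ValidationError(f"{csv_path} row {rowno}: unparseable bmi {bmi_text!r}")
        records.append(
            SubjectRecord(
                subject_id=sid,
                volume_ref=row["volume_path"],
                age_years=age,
                sex_code=int(row["sex"]),
                bmi_kg_m2=bmi,
            )
        )
    return CohortTable(records=records, base_dir=os.path.dirname(os.path.abspath(csv_path)))


def write_cohort_csv(table: CohortTable, csv_path) -> None:
    rows = []
    for r in table.records:
        if isinstance(r.volume_ref, Volume):
            raise ValidationError(
                f"subject {r.subject_id!r} holds an in-memory volume; write volumes first"
            )
        rows.append(
            {
                "subject_id": r.subject_id,
                "volume_path": os.fspath(r.volume_ref),
                "age_years": r.age_years,
                "sex": r.sex_code,
                "bmi": "" if r.bmi_kg_m2 is None else r.bmi_kg_m2,
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(csv_path, index=False)


def split_cohort(
    table: CohortTable,
    fractions: tuple[float, float, float],
    seed: int,
) -> tuple[CohortTable, CohortTable, CohortTable]:
    """Randomly split a cohort into disjoint train/validation/test tables.

    Validation and test sizes are round(n × fraction); the remainder goes
    to the training set.  Deterministic given ``seed``.
    """
    f_train, f_val, f_test = fractions
    if any(f < 0 for f in fractions):
        raise DomainError(f"fractions must be non-negative, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise DomainError(f"fractions must sum to 1, got {fractions}")
    n = len(table)
    if n < 3:
        raise DomainError(f"need at least 3 records to split, got {n}")
    n_val = int(round(n * f_val))
    n_test = int(round(n * f_test))
    n_train = n - n_val - n_test
    if n_train < 0:
        raise DomainError("rounded validation and test sizes exceed the cohort")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    order = [table.records[i] for i in perm]
    return (
        CohortTable(order[:n_train], "train", base_dir=table.base_dir),
        CohortTable(order[n_train : n_train + n_val], "validation", base_dir=table.base_dir),
        CohortTable(order[n_train + n_val :], "test", base_dir=table.base_dir),
    )
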