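"""Core grid/cohort containers and NIfTI / CSV input-output.

Volumes are body-weight SUV voxel grids (dimensionless intensities) with
physical voxel spacing in millimetres.  Masks are single-lesion binary
volumes on the same grid.  Cohort tables carry per-patient nodal-status
labels (histology reference), the clinician's visual PET nodal reading,
a scanner identifier and, optionally, one column per radiomic feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

#: 3x3x3 all-ones structuring element: 26-connectivity, the convention used
#: throughout for zones, components and neighbourhoods.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

COHORT_COLUMNS = ("patient_id", "ln_histology", "visual_detection", "scanner_id")


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive lengths in mm, got {spacing}")
    return spacing


@dataclass
class PETVolume:
    """A 3D SUV voxel grid with physical spacing (mm) and origin (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"expected 3 dimensions, got {values.ndim}")
        if any(n < 1 for n in values.shape):
            raise ValueError(f"degenerate volume shape {values.shape}")
        bad = ~np.isfinite(values)
        if bad.any():
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValueError(f"non-finite voxel value at index {idx}")
        if (values < 0).any():
            idx = tuple(int(i) for i in np.argwhere(values < 0)[0])
            raise ValueError(f"negative SUV at index {idx}")
        self.values = values
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class VOIMask:
    """Binary tumour mask: one 26-connected lesion with >= 2 voxels."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise ValueError(f"expected 3 dimensions, got {mask.ndim}")
        mask = mask.astype(bool)
        n = int(mask.sum())
        if n == 0:
            raise ValueError("empty mask")
        if n < 2:
            raise ValueError("mask has fewer than 2 foreground voxels")
        _, n_comp = ndimage.label(mask, structure=STRUCT_26)
        if n_comp != 1:
            raise ValueError(f"{n_comp} connected components (expected 1)")
        self.mask = mask
        self.spacing = _check_spacing(self.spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def check_compatible(self, volume: PETVolume) -> None:
        if self.mask.shape != volume.shape:
            raise ValueError(
                f"grid mismatch: mask {self.mask.shape} vs volume {volume.shape}"
            )
        if not np.allclose(self.spacing, volume.spacing, rtol=1e-6):
            raise ValueError(
                f"spacing mismatch: mask {self.spacing} vs volume {volume.spacing}"
            )


def _affine(spacing, origin) -> np.ndarray:
    affine = np.diag([*spacing, 1.0])
    affine[:3, 3] = origin
    return affine


def write_volume(volume: PETVolume, path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float64), _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def read_volume(path) -> PETVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3 dimensions, got {data.ndim}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return PETVolume(np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), origin)


def write_mask(mask: VOIMask, path) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(mask.spacing, (0, 0, 0)))
    nib.save(img, str(path))


def read_mask(path, reference: PETVolume) -> VOIMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3 dimensions, got {data.ndim}")
    if data.shape != reference.shape:
        raise ValueError(f"grid mismatch: mask {data.shape} vs volume {reference.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not np.allclose(zooms, reference.spacing, rtol=1e-4):
        raise ValueError(f"spacing mismatch: mask {zooms} vs volume {reference.spacing}")
    data = np.asarray(data, dtype=np.float64)
    rounded = np.rint(data)
    if np.abs(data - rounded).max() > 1e-6 or not np.isin(rounded, (0, 1)).all():
        raise ValueError("mask voxels must be binary (0/1 within 1e-6)")
    return VOIMask(rounded.astype(bool), reference.spacing)


# ---------------------------------------------------------------------------
# Cohort table


@dataclass
class PatientRecord:
    patient_id: str
    ln_histology: int
    visual_detection: int
    scanner_id: str
    features: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for name in ("ln_histology", "visual_detection"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(
                    f"patient {self.patient_id!r}: column {name!r} must be 0/1, got {v!r}"
                )
            setattr(self, name, int(v))


class Cohort:
    """Ordered collection of patient records; the unit of all statistics."""

    def __init__(self, records: Sequence[PatientRecord]):
        records = list(records)
        ids = [r.patient_id for r in records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate patient ids: {dupes}")
        self.records = records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i) -> PatientRecord:
        return self.records[i]

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    @property
    def ln_histology(self) -> np.ndarray:
        return np.array([r.ln_histology for r in self.records], dtype=int)

    @property
    def visual_detection(self) -> np.ndarray:
        return np.array([r.visual_detection for r in self.records], dtype=int)

    @property
    def scanner_ids(self) -> list[str]:
        return [r.scanner_id for r in self.records]

    @property
    def n_positive(self) -> int:
        return int(self.ln_histology.sum())

    @property
    def feature_names(self) -> list[str]:
        for r in self.records:
            if r.features is not None:
                return list(r.features)
        return []

    def feature_frame(self) -> pd.DataFrame:
        """Per-patient feature table (rows = patients, columns = features)."""
        if any(r.features is None for r in self.records):
            missing = [r.patient_id for r in self.records if r.features is None]
            raise ValueError(f"features not extracted for patients {missing}")
        return pd.DataFrame(
            [r.features for r in self.records], index=self.patient_ids
        )

    def feature_values(self, name: str) -> np.ndarray:
        return self.feature_frame()[name].to_numpy(dtype=float)

    def with_features(self, frame: pd.DataFrame) -> "Cohort":
        """Return a copy with features attached from a per-patient DataFrame."""
        out = []
        for r in self.records:
            if r.patient_id not in frame.index:
                raise ValueError(f"no feature row for patient {r.patient_id!r}")
            out.append(
                PatientRecord(
                    r.patient_id,
                    r.ln_histology,
                    r.visual_detection,
                    r.scanner_id,
                    {k: float(v) for k, v in frame.loc[r.patient_id].items()},
                )
            )
        return Cohort(out)

    def subset(self, indices) -> "Cohort":
        return Cohort([self.records[i] for i in indices])

    def to_frame(self) -> pd.DataFrame:
        base = pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "ln_histology": self.ln_histology,
                "visual_detection": self.visual_detection,
                "scanner_id": self.scanner_ids,
            }
        )
        if all(r.features is not None for r in self.records):
            feats = self.feature_frame().reset_index(drop=True)
            base = pd.concat([base, feats], axis=1)
        return base

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_cohort_table(path) -> Cohort:
    """Read a cohort CSV (header: patient_id, ln_histology, visual_detection,
    scanner_id, plus optional feature columns)."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    for col in ("ln_histology", "visual_detection"):
        for row, v in enumerate(df[col]):
            if v not in (0, 1):
                raise ValueError(f"row {row}, column {col!r}: value {v!r} not in {{0, 1}}")
    feat_cols = [c for c in df.columns if c not in COHORT_COLUMNS]
    records = []
    for _, row in df.iterrows():
        feats = {c: float(row[c]) for c in feat_cols} if feat_cols else None
        records.append(
            PatientRecord(
                str(row["patient_id"]),
                int(row["ln_histology"]),
                int(row["visual_detection"]),
                str(row["scanner_id"]),
                feats,
            )
        )
    return Cohort(records)
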