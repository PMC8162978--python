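"""Shared data containers for the radiogenomics ensemble pipeline.

Conventions used throughout the package:

* The **minority class is ``mutant``** and is the positive class for
  sensitivity; the majority class is ``wildtype``.
* Classifier outputs are **pseudo-probabilities** of the minority class,
  real values in ``[0, 1]`` with no calibration guarantee.
* A :class:`ScoreMatrix` stores one row per model and one column per
  sample; it is the substrate every voting scheme operates on.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

MINORITY = "mutant"
MAJORITY = "wildtype"

#: metadata columns of a feature-table CSV, in canonical order
META_COLUMNS = ("sample_id", "patient_id", "label", "synthetic")


def as_minority_bool(labels) -> np.ndarray:
    """Coerce labels given as strings, bools or {0,1} ints to a boolean
    array that is True for the minority/positive (mutant) class."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        known = set(np.unique(arr.astype(str)))
        if not known <= {MINORITY, MAJORITY}:
            raise ValueError(f"unknown labels {known - {MINORITY, MAJORITY}}")
        return arr.astype(str) == MINORITY
    return arr.astype(bool)


def labels_from_bool(minority: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(minority, bool), MINORITY, MAJORITY)


@dataclasses.dataclass
class FeatureTable:
    """Labelled samples x features matrix with patient identity.

    Wraps a :class:`pandas.DataFrame` whose columns are
    ``sample_id, patient_id, label[, synthetic], <feature columns...>``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("sample_id", "patient_id", "label"):
            if col not in self.frame.columns:
                raise ValueError(f"feature table is missing column {col!r}")
        if "synthetic" not in self.frame.columns:
            self.frame = self.frame.copy()
            self.frame.insert(3, "synthetic", False)
        self.frame["synthetic"] = self.frame["synthetic"].astype(bool)
        if self.frame["patient_id"].isna().any():
            raise ValueError("patient_id must be non-null")
        labels = set(self.frame["label"].astype(str))
        if not labels <= {MINORITY, MAJORITY}:
            raise ValueError(f"labels must be {MINORITY}/{MAJORITY}, got {labels}")
        if not self.feature_names:
            raise ValueError("feature table has no feature columns")
        self.frame = self.frame.reset_index(drop=True)

    # -- accessors ---------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in META_COLUMNS]

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        """Boolean vector, True for minority (mutant) samples."""
        return as_minority_bool(self.frame["label"].to_numpy())

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy(str)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.frame["sample_id"].to_numpy(str)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.frame["patient_id"].to_numpy(str)

    @property
    def synthetic(self) -> np.ndarray:
        return self.frame["synthetic"].to_numpy(bool)

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def minority_count(self) -> int:
        return int(self.y.sum())

    # -- transforms --------------------------------------------------
    def subset(self, rows) -> "FeatureTable":
        """Row subset by positional indices or boolean mask."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            sub = self.frame.loc[rows]
        else:
            sub = self.frame.iloc[rows]
        return FeatureTable(sub.reset_index(drop=True))

    def select(self, features: Sequence[str]) -> "FeatureTable":
        """Column subset keeping metadata and the named features, in order."""
        missing = [f for f in features if f not in self.frame.columns]
        if missing:
            raise KeyError(f"unknown features {missing}")
        cols = [c for c in META_COLUMNS if c in self.frame.columns] + list(features)
        return FeatureTable(self.frame[cols].copy())

    # -- IO ----------------------------------------------------------
    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path, dtype={"sample_id": str, "patient_id": str}))


@dataclasses.dataclass
class ScoreMatrix:
    """Per-model minority-class pseudo-probabilities.

    ``scores[i, j]`` is model i's pseudo-probability that sample j is
    mutant. All voting schemes consume this container.
    """

    scores: np.ndarray
    model_ids: list[str] = None
    sample_ids: list[str] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        if self.scores.ndim != 2 or self.scores.size == 0:
            raise ValueError("scores must be a nonempty 2D array")
        if np.any(~np.isfinite(self.scores)):
            raise ValueError("scores contain non-finite entries")
        if self.scores.min() < 0 or self.scores.max() > 1:
            raise ValueError("scores must lie in [0, 1]")
        m, n = self.scores.shape
        if self.model_ids is None:
            self.model_ids = [f"model_{i:02d}" for i in range(m)]
        if self.sample_ids is None:
            self.sample_ids = [f"S{j:04d}" for j in range(n)]
        if len(self.model_ids) != m or len(self.sample_ids) != n:
            raise ValueError("id lengths do not match matrix shape")

    @property
    def n_models(self) -> int:
        return self.scores.shape[0]

    @property
    def n_samples(self) -> int:
        return self.scores.shape[1]

    def subset_models(self, idx) -> "ScoreMatrix":
        idx = np.asarray(idx, int)
        return ScoreMatrix(
            self.scores[idx], [self.model_ids[i] for i in idx], list(self.sample_ids)
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(self.scores, index=self.model_ids, columns=self.sample_ids).to_csv(
            path, index_label="model_id"
        )

    @classmethod
    def from_csv(cls, path) -> "ScoreMatrix":
        df = pd.read_csv(path, index_col="model_id")
        return cls(df.to_numpy(float), [str(i) for i in df.index], [str(c) for c in df.columns])


@dataclasses.dataclass
class TumorVolume:
    """3D intensity grid plus binary segmentation mask and voxel spacing.

    Arrays are indexed ``(x, y, z)``; ``spacing`` is ``(dx, dy, dz)`` in mm.
    """

    intensities: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, float)
        self.mask = np.asarray(self.mask, bool)
        if self.intensities.ndim != 3 or self.intensities.shape != self.mask.shape:
            raise ValueError("intensities and mask must be 3D arrays of equal shape")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def save(self, prefix) -> tuple[Path, Path]:
        """Write ``<prefix>_img.nii.gz`` / ``<prefix>_mask.nii.gz``."""
        prefix = Path(prefix)
        affine = np.diag((*self.spacing, 1.0))
        img_path = prefix.with_name(prefix.name + "_img.nii.gz")
        mask_path = prefix.with_name(prefix.name + "_mask.nii.gz")
        nib.save(nib.Nifti1Image(self.intensities.astype(np.float32), affine), img_path)
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine), mask_path)
        return img_path, mask_path

    @classmethod
    def load(cls, img_path, mask_path) -> "TumorVolume":
        img = nib.load(str(img_path))
        mask = nib.load(str(mask_path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, float), np.asarray(mask.dataobj) > 0, spacing)


@dataclasses.dataclass
class VotingResult:
    """Per-sample ensemble decision.

    Invariant (holds for every scheme in :mod:`radscav.ensemble`):
    ``predicted label == mutant  <=>  ensemble score >= 0.5``.
    """

    labels: np.ndarray  # "mutant"/"wildtype" per sample
    scores: np.ndarray  # minority pseudo-probability per sample
    vote_counts: np.ndarray | None = None  # minority votes per sample (SCAV)

    @property
    def minority_mask(self) -> np.ndarray:
        return as_minority_bool(self.labels)


@dataclasses.dataclass
class MetricsReport:
    """Accuracy / sensitivity / specificity / AUC with the raw 2x2 counts.

    Mutant (minority) is the positive class. Ratios that are undefined on
    a degenerate fold (single-class truth) are reported as NaN, never
    silently coerced to 0.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
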