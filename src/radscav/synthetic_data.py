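"""Synthetic stand-ins for the radiogenomics study data.

Three generators with known ground truth make every downstream stage
testable without the original CT/genomic cohort:

``generate_feature_table``
    An imbalanced two-class radiomic-style feature table. Informative
    features are class-conditional Gaussians with a standardized mean
    shift (``effect_size``); the rest are class-independent standard
    normals. Defaults mirror the study cohort: 83 samples, 266
    features, 14% mutant prevalence (the EGFR-like case; 24% is the
    KRAS-like case).

``generate_score_matrix``
    A correlated-but-diverse bank of probabilistic base models. Every
    model sees the same class-separating latent score and adds its own
    noise, so model diversity — the quantity voting exploits — is one
    knob (``model_noise_sd``) and per-model strength another
    (``discrimination``).

``generate_tumor_volume``
    An ellipsoidal tumor with Gaussian texture inside an otherwise
    air-valued grid, as a fixture for feature extraction and slice
    selection.

All generators are bit-reproducible given spec + seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import MAJORITY, MINORITY, FeatureTable, ScoreMatrix, TumorVolume, as_minority_bool

__all__ = [
    "SyntheticSpec",
    "ScoreBankSpec",
    "generate_feature_table",
    "generate_score_matrix",
    "generate_tumor_volume",
]


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of the synthetic feature table (defaults = study-like)."""

    n_samples: int = 83
    n_features: int = 266
    n_informative: int = 10
    minority_fraction: float = 0.14
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_features <= 0:
            raise ValueError("n_samples and n_features must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must be in [0, n_features]")
        if not 0.0 < self.minority_fraction < 0.5:
            raise ValueError("minority_fraction must lie in (0, 0.5)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclasses.dataclass
class ScoreBankSpec:
    """Parameters of the synthetic bank of probabilistic models."""

    n_models: int = 10
    discrimination: float = 1.0
    model_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.discrimination < 0 or self.model_noise_sd < 0:
            raise ValueError("discrimination and model_noise_sd must be >= 0")


def generate_feature_table(spec: SyntheticSpec) -> FeatureTable:
    """Imbalanced two-class feature table with known informative features.

    The minority (mutant) count is exactly ``round(n * minority_fraction)``.
    Informative features (the first ``n_informative`` columns,
    ``f_0001...``) shift their mean by ``effect_size`` (unit variance) in
    the mutant class; the remaining columns are label-independent
    N(0, 1) noise. One synthetic patient per sample.
    """
    n_min = int(round(spec.n_samples * spec.minority_fraction))
    if spec.n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if n_min < 2:
        raise ValueError("minority count < 2: too small for SMOTE/CV")
    rng = np.random.default_rng(spec.seed)
    y = np.zeros(spec.n_samples, bool)
    y[:n_min] = True  # order carries no information: features are iid given label
    X = rng.standard_normal((spec.n_samples, spec.n_features))
    X[y, : spec.n_informative] += spec.effect_size
    width = len(str(spec.n_features))
    names = [f"f_{i + 1:0{max(width, 4)}d}" for i in range(spec.n_features)]
    frame = pd.DataFrame(X, columns=names)
    frame.insert(0, "sample_id", [f"S{i + 1:04d}" for i in range(spec.n_samples)])
    frame.insert(1, "patient_id", [f"P{i + 1:04d}" for i in range(spec.n_samples)])
    frame.insert(2, "label", np.where(y, MINORITY, MAJORITY))
    return FeatureTable(frame)


def generate_score_matrix(labels, spec: ScoreBankSpec) -> ScoreMatrix:
    """Correlated bank of per-model minority pseudo-probabilities.

    ``p_ij = logistic(discrimination * u_j + e_ij)`` with a shared
    latent ``u_j = log(pi / (1 - pi)) + 1{j minority}`` (``pi`` = the
    minority fraction of ``labels``) and independent per-model noise
    ``e_ij ~ N(0, model_noise_sd)``.

    The latent is the class indicator anchored at the prior log-odds:
    classifiers fit to a rare-positive cohort emit minority
    pseudo-probabilities that sit below 0.5 for most samples and cross
    it only for clear minority cases, which is the regime that makes
    plain average voting insensitive and selective voting worthwhile.
    The latent still separates the classes exactly, so with zero noise
    every model is a perfect ranker whatever the discrimination; noise
    makes the models weak and diverse while the shared latent keeps
    them positively correlated.
    """
    y = as_minority_bool(labels)
    if y.size == 0 or y.all() or not y.any():
        raise ValueError("labels must be nonempty with both classes present")
    rng = np.random.default_rng(spec.seed)
    frac = y.mean()
    u = np.log(frac / (1.0 - frac)) + y.astype(float)
    e = rng.normal(0.0, spec.model_noise_sd, size=(spec.n_models, y.size))
    p = expit(spec.discrimination * u[None, :] + e)
    return ScoreMatrix(p, sample_ids=[f"S{j + 1:04d}" for j in range(y.size)])


def generate_tumor_volume(
    shape: tuple[int, int, int] = (64, 64, 64),
    axes: tuple[float, float, float] = (20.0, 15.0, 10.0),
    texture_sd: float = 10.0,
    seed: int = 0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    base_intensity: float = 40.0,
    background: float = -1000.0,
) -> TumorVolume:
    """Ellipsoidal tumor with Gaussian texture in an air-valued grid.

    The mask is the discretized ellipsoid of the given semi-axes (in
    voxels) centered in the grid; intensities inside are a uniform
    soft-tissue base plus N(0, texture_sd) texture, and a constant
    air-like background outside. Intensities are in Hounsfield-style
    units but carry no acquisition physics.
    """
    shape = tuple(int(s) for s in shape)
    axes = tuple(float(a) for a in axes)
    if any(a < 1 for a in axes):
        raise ValueError("every semi-axis must be >= 1 voxel")
    if any(2 * a >= s for a, s in zip(axes, shape)):
        raise ValueError("ellipsoid does not fit inside the volume extent")
    if texture_sd < 0:
        raise ValueError("texture_sd must be >= 0")
    rng = np.random.default_rng(seed)
    center = [(s - 1) / 2.0 for s in shape]
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    mask = rho2 <= 1.0
    intensities = np.full(shape, background, float)
    intensities[mask] = base_intensity + rng.normal(0.0, texture_sd, int(mask.sum()))
    return TumorVolume(intensities, mask, spacing)
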