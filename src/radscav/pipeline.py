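"""Experiment orchestration.

Two skeletons are provided:

1. **Tabular experiment** — a leakage-free 10-fold cross-validation
   over *feature selection -> SMOTE -> classifier -> metrics* for a
   grid of base-model configurations (2 rankers x 4 feature-set sizes
   x 4 learners = 32 configs by default), followed by an ensemble of
   the top training-AUC models combined with SCAV / average / maximum
   voting. Every training-only stage (selection, SMOTE, fitting,
   member ranking, SCAV threshold tuning) sees training rows only.

2. **Image-branch data preparation** — picking up to three 128x128
   tumor ROIs per volume (largest-area axial slice plus the slices two
   steps away) and patient-grouped train/validation/test splitting, so
   that any probabilistic image classifier's scores can enter the
   ensemble stage through a :class:`ScoreMatrix`.

Classifiers are deliberately *adapters around packaged learners*
(scikit-learn, with default-style hyperparameters): the method under
test is everything around them, not the learners themselves.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import ensemble as voting_mod
from .datatypes import (
    FeatureTable,
    MetricsReport,
    ScoreMatrix,
    TumorVolume,
    VotingResult,
    as_minority_bool,
)
from .feature_selection import rank_features
from .metrics import auc, metrics_report
from .resampling import SmoteParams, smote

__all__ = [
    "BaseModelConfig",
    "ClassifierAdapter",
    "CVResult",
    "EnsembleOutcome",
    "default_configs",
    "make_adapter",
    "run_split",
    "run_cv",
    "run_ensemble_experiment",
    "select_slices",
    "SliceROI",
    "grouped_split",
    "CLASSIFIER_NAMES",
]

CLASSIFIER_NAMES = ("rf", "svm", "gbm", "nnet")


@dataclasses.dataclass(frozen=True)
class BaseModelConfig:
    """One of the base-model configurations of the tabular experiment."""

    selector: str  # "mann_whitney" | "relieff"
    k_features: int  # typically 5, 10, 15, 20
    classifier: str  # adapter name
    use_smote: bool = True

    @property
    def name(self) -> str:
        tag = "smote" if self.use_smote else "raw"
        return f"{self.selector}-k{self.k_features}-{self.classifier}-{tag}"


def default_configs(
    selectors=("mann_whitney", "relieff"),
    k_features=(5, 10, 15, 20),
    classifiers=CLASSIFIER_NAMES,
    use_smote: bool = True,
) -> list[BaseModelConfig]:
    """The full selector x feature-count x learner grid (32 by default)."""
    return [
        BaseModelConfig(s, k, c, use_smote)
        for s, k, c in itertools.product(selectors, k_features, classifiers)
    ]


class _MeanScoreClassifier(BaseEstimator, ClassifierMixin):
    """Trivial deterministic scorer for tests and fast smoke runs.

    Standardizes features on the training set, aligns each feature's
    sign with the minority class, and squashes the per-sample mean
    through a logistic. No iterative fitting, fully deterministic.
    """

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, bool)
        self.mu_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd == 0, 1.0, sd)
        Z = (X - self.mu_) / self.sd_
        self.sign_ = np.sign(Z[y].mean(axis=0) - Z[~y].mean(axis=0))
        self.sign_[self.sign_ == 0] = 1.0
        self.classes_ = np.array([False, True])
        return self

    def predict_proba(self, X):
        Z = (np.asarray(X, float) - self.mu_) / self.sd_
        p = 1.0 / (1.0 + np.exp(-(Z * self.sign_).mean(axis=1)))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return self.predict_proba(X)[:, 1] >= 0.5


def make_adapter(name: str, seed: int = 0) -> "ClassifierAdapter":
    """Build a named classifier adapter with a bound seed.

    Learners keep scikit-learn's default-style hyperparameters; scaled
    inputs are used for the margin/gradient-based learners.
    """
    if name == "rf":
        est = RandomForestClassifier(random_state=seed)
    elif name == "svm":
        est = make_pipeline(StandardScaler(), SVC(probability=True, random_state=seed))
    elif name == "gbm":
        est = GradientBoostingClassifier(random_state=seed)
    elif name == "nnet":
        est = make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(32,), max_iter=1000, random_state=seed),
        )
    elif name == "mean":
        est = _MeanScoreClassifier()
    else:
        raise ValueError(f"unknown classifier {name!r}")
    return ClassifierAdapter(name, est)


@dataclasses.dataclass
class ClassifierAdapter:
    """Contract: fit on training rows, emit minority pseudo-probabilities."""

    name: str
    estimator: BaseEstimator

    def fit(self, table: FeatureTable) -> "ClassifierAdapter":
        self.estimator = clone(self.estimator).fit(table.X, table.y)
        return self

    def score_samples(self, table: FeatureTable) -> np.ndarray:
        proba = self.estimator.predict_proba(table.X)
        cls = list(self.estimator.classes_)
        p = proba[:, cls.index(True)]
        if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
            raise ValueError(f"adapter {self.name!r} returned out-of-range scores")
        return p


def _child_seed(*keys: int) -> int:
    """Deterministic sub-seed below 2**31 from a tuple of integers."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


@dataclasses.dataclass
class SplitOutput:
    """Result of one train/test pass for one configuration."""

    selected_features: list[str]
    test_scores: np.ndarray  # minority pseudo-probabilities, test rows
    train_scores: np.ndarray  # scores on the original (non-synthetic) train rows
    train_auc: float
    report: MetricsReport  # test-fold metrics


def run_split(
    table: FeatureTable,
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    config: BaseModelConfig,
    seed: int = 0,
    relieff_neighbors: int = 10,
) -> SplitOutput:
    """Train/evaluate one configuration on an explicit row split.

    The unit of the cross-validation loop: feature selection, optional
    SMOTE and model fitting all consume the training rows only.
    """
    train = table.subset(np.asarray(train_idx, int))
    test = table.subset(np.asarray(test_idx, int))
    n_neighbors = min(relieff_neighbors, max(1, train.minority_count - 1))
    sel = rank_features(train, config.selector, config.k_features, n_neighbors)
    train_sel = train.select(sel.selected)
    fit_table = train_sel
    if config.use_smote:
        k = min(5, train_sel.minority_count - 1)
        fit_table = smote(train_sel, SmoteParams(k_neighbors=k, seed=_child_seed(seed, 1)))
    adapter = make_adapter(config.classifier, seed=_child_seed(seed, 2))
    adapter.fit(fit_table)
    train_scores = adapter.score_samples(train_sel)  # original rows only
    test_scores = adapter.score_samples(test.select(sel.selected))
    rep = metrics_report(test.y, test_scores >= 0.5, test_scores)
    return SplitOutput(sel.selected, test_scores, train_scores, auc(train.y, train_scores), rep)


@dataclasses.dataclass
class CVResult:
    """Everything the ensemble stage needs from a cross-validation run."""

    configs: list[BaseModelConfig]
    labels: np.ndarray  # truth per sample ("mutant"/"wildtype")
    score_matrix: ScoreMatrix  # pooled out-of-fold scores, configs x samples
    fold_of_sample: np.ndarray  # test-fold index per sample
    fold_metrics: dict[str, list[MetricsReport]]  # config name -> per-fold reports
    mean_train_auc: np.ndarray  # per config, mean of fold-training AUCs
    fold_train_indices: list[np.ndarray]  # per fold, the training row indices
    fold_train_scores: list[np.ndarray]  # per fold, configs x train-rows scores
    selected_features: dict[str, list[list[str]]]  # config name -> per-fold selections


def run_cv(
    table: FeatureTable,
    configs: Sequence[BaseModelConfig],
    folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified leakage-free cross-validation over a config grid."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if table.minority_count < folds:
        raise ValueError("minority class too small to stratify into this many folds")
    configs = list(configs)
    y = table.y
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled = np.full((len(configs), table.n_samples), np.nan)
    fold_of_sample = np.full(table.n_samples, -1, int)
    fold_metrics: dict[str, list[MetricsReport]] = {c.name: [] for c in configs}
    selected: dict[str, list[list[str]]] = {c.name: [] for c in configs}
    train_aucs = np.zeros((len(configs), folds))
    fold_train_indices: list[np.ndarray] = []
    fold_train_scores: list[np.ndarray] = []
    for f, (tr, te) in enumerate(skf.split(table.X, y)):
        fold_of_sample[te] = f
        fold_train_indices.append(tr)
        tr_scores = np.empty((len(configs), tr.size))
        for ci, cfg in enumerate(configs):
            out = run_split(table, tr, te, cfg, seed=_child_seed(seed, f, ci))
            pooled[ci, te] = out.test_scores
            tr_scores[ci] = out.train_scores
            train_aucs[ci, f] = out.train_auc
            fold_metrics[cfg.name].append(out.report)
            selected[cfg.name].append(out.selected_features)
        fold_train_scores.append(tr_scores)
    assert not np.isnan(pooled).any()  # every sample scored exactly once
    matrix = ScoreMatrix(pooled, [c.name for c in configs], list(table.sample_ids))
    return CVResult(
        configs,
        table.labels,
        matrix,
        fold_of_sample,
        fold_metrics,
        train_aucs.mean(axis=1),
        fold_train_indices,
        fold_train_scores,
        selected,
    )


@dataclasses.dataclass
class EnsembleOutcome:
    voting: str
    member_ids: list[str]
    threshold: int | None  # SCAV count threshold, tuned on training folds
    result: VotingResult  # on pooled out-of-fold scores
    report: MetricsReport


def tune_scav_threshold(cv: CVResult, members: np.ndarray) -> int:
    """Pick the SCAV threshold maximizing mean training-fold AUC.

    For each candidate ``t`` the SCAV ensemble of the member models is
    evaluated on every fold's *training* rows and the AUCs averaged;
    ties resolve to the smallest ``t``. Test rows are never touched.
    """
    y = np.asarray(cv.labels)
    m = len(members)
    mean_aucs = []
    for t in range(1, m + 1):
        vals = []
        for tr, scores in zip(cv.fold_train_indices, cv.fold_train_scores):
            res = voting_mod.scav_vote(scores[members], t)
            vals.append(auc(y[tr], res.scores))
        mean_aucs.append(np.mean(vals))
    return int(np.argmax(mean_aucs)) + 1


def run_ensemble_experiment(
    cv: CVResult, k_members: int, voting: str = "scav"
) -> EnsembleOutcome:
    """Ensemble the top-``k`` training-AUC models over pooled CV scores."""
    members = voting_mod.rank_members(cv.mean_train_auc, k_members)
    t = tune_scav_threshold(cv, members) if voting == "scav" else None
    sub = cv.score_matrix.subset_models(members)
    result = voting_mod.vote(sub, voting, t)
    rep = metrics_report(cv.labels, result.labels, result.scores)
    return EnsembleOutcome(voting, list(sub.model_ids), t, result, rep)


# ---------------------------------------------------------------------------
# image branch
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SliceROI:
    """One 128x128 axial crop centered on the tumor cross-section."""

    z: int
    image: np.ndarray
    mask: np.ndarray


def _crop_centered(plane: np.ndarray, center: tuple[int, int], size: int, pad_value):
    out = np.full((size, size), pad_value, dtype=plane.dtype)
    half = size // 2
    r0, c0 = center[0] - half, center[1] - half
    rs0, cs0 = max(r0, 0), max(c0, 0)
    rs1 = min(r0 + size, plane.shape[0])
    cs1 = min(c0 + size, plane.shape[1])
    out[rs0 - r0 : rs1 - r0, cs0 - c0 : cs1 - c0] = plane[rs0:rs1, cs0:cs1]
    return out


def select_slices(
    volume: TumorVolume,
    offset: int = 2,
    min_area_fraction: float = 0.1,
    size: int = 128,
    pad_value: float | None = None,
) -> list[SliceROI]:
    """Pick up to three tumor ROIs along z.

    The central slice is the one with the largest mask area (ties to
    the lowest z); the two candidates sit ``offset`` slices above and
    below — immediately consecutive slices are skipped as too similar.
    A candidate whose mask area falls below ``min_area_fraction`` of
    the central area (no clear piece of tumor) is discarded. Each kept
    slice is cropped to ``size x size`` centered on its mask centroid,
    constant-padded at the borders.
    """
    areas = volume.mask.sum(axis=(0, 1))
    z_central = int(np.argmax(areas))
    central_area = int(areas[z_central])
    if pad_value is None:
        pad_value = float(volume.intensities.min())
    candidates = [z_central]
    for z in (z_central - offset, z_central + offset):
        if 0 <= z < volume.mask.shape[2] and areas[z] >= min_area_fraction * central_area:
            candidates.append(z)
    rois = []
    for z in sorted(candidates):
        m = volume.mask[:, :, z]
        centroid = tuple(int(round(c)) for c in np.argwhere(m).mean(axis=0))
        rois.append(
            SliceROI(
                z,
                _crop_centered(volume.intensities[:, :, z], centroid, size, float(pad_value)),
                _crop_centered(m, centroid, size, False),
            )
        )
    return rois


def _largest_remainder(total: int, fractions: Sequence[float]) -> np.ndarray:
    raw = np.asarray(fractions) * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


SPLIT_NAMES = ("train", "validation", "test")


def grouped_split(
    patient_ids: Sequence[str],
    patient_labels,
    fractions: tuple[float, float, float] = (0.65, 0.15, 0.20),
    seed: int = 0,
) -> dict[str, str]:
    """Patient-level train/validation/test assignment.

    All samples of a patient share one split. Split sizes follow the
    fractions by largest remainder; the minority class is stratified
    across splits, and whenever the minority patient count permits
    (>= number of splits) every split receives at least one minority
    patient.
    """
    patients = [str(p) for p in patient_ids]
    if len(set(patients)) != len(patients):
        raise ValueError("patient_ids must be unique")
    if len(patients) < 5:
        raise ValueError("need at least 5 patients to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    y = as_minority_bool(patient_labels)
    if y.size != len(patients):
        raise ValueError("one label per patient required")
    n_splits = len(fractions)
    targets = _largest_remainder(len(patients), fractions)
    min_counts = _largest_remainder(int(y.sum()), fractions)
    if y.sum() >= n_splits:
        while (min_counts == 0).any():
            min_counts[int(np.argmax(min_counts))] -= 1
            min_counts[int(np.argmin(min_counts))] += 1
    maj_counts = targets - min_counts
    while (maj_counts < 0).any():  # tiny cohorts: shift minority overflow
        s = int(np.argmin(maj_counts))
        g = int(np.argmax(maj_counts))
        min_counts[s] -= 1
        min_counts[g] += 1
        maj_counts = targets - min_counts
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for is_min, counts in ((True, min_counts), (False, maj_counts)):
        group = [p for p, m in zip(patients, y) if m == is_min]
        group = [group[i] for i in rng.permutation(len(group))]
        pos = 0
        for split_name, c in zip(SPLIT_NAMES, counts):
            for p in group[pos : pos + c]:
                assignment[p] = split_name
            pos += c
    return assignment
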