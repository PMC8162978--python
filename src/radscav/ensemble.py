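"""Voting schemes for ensembles of probabilistic classifiers.

The centrepiece is Selective Class Average Voting (SCAV), a rule built
for class-imbalanced problems. Given per-model minority-class
pseudo-probabilities, SCAV first counts the models that vote for the
minority class (pseudo-probability >= 0.5). If that count reaches a
threshold ``t``, the sample is labelled minority and its ensemble score
is the average over the *minority-voting* models only; otherwise it is
labelled majority and the score averages the majority-voting models.
Averaging only over the winning side keeps a handful of confident
minority votes from being washed out by a sea of indifferent majority
scores — the failure mode of plain average voting at 14-24% prevalence.

Conventions (documented because the ">="/">" choices matter):

* a model "votes minority" iff its pseudo-probability is >= 0.5
  (ties go to the rare class);
* "count reaches the threshold" is ``votes >= t``, so ``t = 1`` is the
  any-vote rule and ``t = m`` demands unanimity;
* the majority-branch score is still the *minority*-class
  pseudo-probability (averaged over majority-voting models), keeping a
  single score axis for ROC analysis.

Under these conventions the final 0.5 re-threshold provably agrees with
the branch decision: the minority branch averages values >= 0.5 and the
majority branch values < 0.5.
"""

from __future__ import annotations

import numpy as np

from .datatypes import ScoreMatrix, VotingResult, labels_from_bool
from .metrics import auc

__all__ = [
    "scav_vote",
    "average_vote",
    "maximum_vote",
    "select_threshold",
    "rank_members",
    "vote",
]

#: a model votes for the minority class iff its score reaches this cut
MODEL_VOTE_CUT = 0.5


def _scores(matrix) -> np.ndarray:
    if isinstance(matrix, ScoreMatrix):
        return matrix.scores
    arr = np.atleast_2d(np.asarray(matrix, float))
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    return arr


def scav_vote(matrix, t: int) -> VotingResult:
    """Selective Class Average Voting with minority-vote threshold ``t``."""
    p = _scores(matrix)
    m = p.shape[0]
    if not 1 <= t <= m:
        raise ValueError(f"threshold t={t} outside [1, {m}]")
    votes = p >= MODEL_VOTE_CUT
    counts = votes.sum(axis=0)
    minority = counts >= t
    scores = np.empty(p.shape[1])
    for j in range(p.shape[1]):
        side = votes[:, j] if minority[j] else ~votes[:, j]
        # the selected side is nonempty: counts[j] >= t >= 1 on the
        # minority branch, counts[j] < t <= m on the majority branch
        scores[j] = p[side, j].mean()
    return VotingResult(labels_from_bool(scores >= 0.5), scores, counts)


def average_vote(matrix) -> VotingResult:
    """Plain average of all model pseudo-probabilities, cut at 0.5."""
    p = _scores(matrix)
    scores = p.mean(axis=0)
    return VotingResult(labels_from_bool(scores >= 0.5), scores)


def maximum_vote(matrix) -> VotingResult:
    """Defer to the most confident model per sample.

    Confidence of model i on sample j is ``max(p_ij, 1 - p_ij)``; ties
    go to the lowest model index. The selected model's
    pseudo-probability becomes the ensemble score.
    """
    p = _scores(matrix)
    confidence = np.maximum(p, 1.0 - p)
    chosen = confidence.argmax(axis=0)  # argmax takes the lowest index on ties
    scores = p[chosen, np.arange(p.shape[1])]
    return VotingResult(labels_from_bool(scores >= 0.5), scores)


def vote(matrix, voting: str, t: int | None = None) -> VotingResult:
    """Dispatch on voting scheme name: ``scav`` | ``average`` | ``maximum``."""
    if voting == "scav":
        if t is None:
            raise ValueError("SCAV requires a threshold t")
        return scav_vote(matrix, t)
    if voting == "average":
        return average_vote(matrix)
    if voting == "maximum":
        return maximum_vote(matrix)
    raise ValueError(f"unknown voting scheme {voting!r}")


def select_threshold(train_matrix, train_labels) -> int:
    """Tune the SCAV count threshold on training data.

    Evaluates every ``t`` in ``1..m`` and returns the one whose SCAV
    ensemble score maximizes the training AUC; ties resolve to the
    smallest ``t``. Must only ever see training rows.
    """
    p = _scores(train_matrix)
    aucs = [auc(train_labels, scav_vote(p, t).scores) for t in range(1, p.shape[0] + 1)]
    return int(np.argmax(aucs)) + 1


def rank_members(training_aucs, k: int) -> np.ndarray:
    """Indices of the ``k`` models with the largest training AUC.

    Ties resolve to the lower model index; the returned order is the
    selection order (best first) and is stable across runs.
    """
    scores = np.asarray(training_aucs, float)
    if not 1 <= k <= scores.size:
        raise ValueError(f"k={k} outside [1, {scores.size}]")
    order = np.argsort(-scores, kind="stable")
    return order[:k]
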