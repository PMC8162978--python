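"""Evaluation metrics with the mutant (minority) class as positive.

Four metrics are reported for every experiment: accuracy, sensitivity
(true-positive rate on mutants), specificity (true-negative rate on
wildtype) and the area under the ROC curve. AUC is computed in its
rank-statistic form — the fraction of (positive, negative) pairs where
the positive sample receives the higher score, ties counted 1/2 — which
is identical to trapezoidal integration of the ROC curve.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata

from .datatypes import MetricsReport, as_minority_bool

__all__ = ["confusion_metrics", "auc", "metrics_report"]


def confusion_metrics(labels, predicted) -> MetricsReport:
    """Accuracy/sensitivity/specificity from hard predictions.

    Parameters may be boolean arrays, ``{0,1}`` ints or
    ``mutant``/``wildtype`` strings. When the truth contains a single
    class, the undefined ratio is NaN and a warning is emitted.
    """
    y = as_minority_bool(labels)
    p = as_minority_bool(predicted)
    if y.shape != p.shape:
        raise ValueError("labels and predictions differ in length")
    tp = int(np.sum(y & p))
    fn = int(np.sum(y & ~p))
    tn = int(np.sum(~y & ~p))
    fp = int(np.sum(~y & p))
    n = tp + fn + tn + fp
    if n == 0:
        raise ValueError("empty label vector")
    accuracy = (tp + tn) / n
    if tp + fn == 0:
        warnings.warn("no positive (mutant) samples: sensitivity undefined")
        sensitivity = float("nan")
    else:
        sensitivity = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative (wildtype) samples: specificity undefined")
        specificity = float("nan")
    else:
        specificity = tn / (tn + fp)
    return MetricsReport(accuracy, sensitivity, specificity, None, tp, fp, tn, fn)


def auc(labels, scores) -> float:
    """Pairwise-rank AUC of minority pseudo-probabilities.

    Equivalent to the normalized Mann-Whitney U statistic: average ranks
    give tied pairs half credit.
    """
    y = as_minority_bool(labels)
    s = np.asarray(scores, float)
    if y.shape != s.shape:
        raise ValueError("labels and scores differ in length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def metrics_report(labels, predicted, scores=None) -> MetricsReport:
    """Full report; AUC included when pseudo-probabilities are given."""
    rep = confusion_metrics(labels, predicted)
    if scores is not None:
        rep.auc = auc(labels, scores)
    return rep
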