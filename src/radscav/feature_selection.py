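"""Filter-style feature ranking on training data.

Two rankers, used one at a time:

* **Mann-Whitney**: the two-sided rank-sum p-value of each feature
  between mutant and wildtype training samples; features sort by
  ascending p-value. Exact p-values are used for small tie-free
  samples, the tie-corrected normal approximation otherwise (scipy's
  ``method='auto'``).
* **ReliefF**: a deterministic all-instances variant. Every training
  instance contributes the difference between its mean distance to the
  nearest ``n_neighbors`` misses (other class) and nearest hits (same
  class), feature-wise, on range-normalized features.

Ties in either score break lexicographically by feature name so a
selection is reproducible down to the ordering.

Both rankers must only ever see training rows; the pipeline enforces
this and a leakage test guards it.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import mannwhitneyu

from .datatypes import FeatureTable

__all__ = ["SelectionResult", "mann_whitney_rank", "relieff_rank", "rank_features"]


@dataclasses.dataclass
class SelectionResult:
    """Full feature ranking plus the selected top-k subset."""

    ranked_features: list[str]  # best first
    scores: np.ndarray  # aligned with ranked_features
    method: str  # "mann_whitney" | "relieff"
    k: int

    @property
    def selected(self) -> list[str]:
        return self.ranked_features[: self.k]


def _check(table: FeatureTable, k: int) -> None:
    if not 1 <= k <= table.n_features:
        raise ValueError(f"k={k} outside [1, {table.n_features}]")
    y = table.y
    if y.all() or not y.any():
        raise ValueError("both classes must be present to rank features")


def _order(names, scores, ascending: bool) -> list[int]:
    key = scores if ascending else -scores
    return sorted(range(len(names)), key=lambda i: (key[i], names[i]))


def mann_whitney_rank(table: FeatureTable, k: int) -> SelectionResult:
    """Rank features by two-sided rank-sum p-value, ascending."""
    _check(table, k)
    y = table.y
    X = table.X
    pvals = np.empty(table.n_features)
    for i in range(table.n_features):
        col = X[:, i]
        if np.ptp(col) == 0:
            pvals[i] = 1.0  # no separation possible
            continue
        p = mannwhitneyu(col[y], col[~y], alternative="two-sided", method="auto").pvalue
        pvals[i] = 1.0 if np.isnan(p) else min(float(p), 1.0)
    order = _order(table.feature_names, pvals, ascending=True)
    return SelectionResult(
        [table.feature_names[i] for i in order], pvals[order], "mann_whitney", k
    )


def relieff_rank(table: FeatureTable, k: int, n_neighbors: int = 10) -> SelectionResult:
    """Rank features by deterministic ReliefF weight, descending.

    For each instance the ``n_neighbors`` nearest hits and misses are
    found by Euclidean distance on range-normalized features (distance
    ties break on sample index). The weight update per feature is
    ``sum(|diff to misses|) - sum(|diff to hits|)`` normalized by
    ``n_samples * n_neighbors``; constant features get weight 0.
    """
    _check(table, k)
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    y = table.y
    for cls, cnt in (("minority", y.sum()), ("majority", (~y).sum())):
        if cnt < n_neighbors + 1:
            raise ValueError(f"{cls} class needs >= n_neighbors+1 samples")
    X = table.X
    rng_width = np.ptp(X, axis=0)
    safe = np.where(rng_width == 0, 1.0, rng_width)
    Z = (X - X.min(axis=0)) / safe
    Z[:, rng_width == 0] = 0.0
    n = table.n_samples
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    weights = np.zeros(table.n_features)
    idx = np.arange(n)
    for i in range(n):
        same = idx[(y == y[i]) & (idx != i)]
        other = idx[y != y[i]]
        hits = same[np.lexsort((same, d2[i, same]))][:n_neighbors]
        misses = other[np.lexsort((other, d2[i, other]))][:n_neighbors]
        weights += np.abs(Z[i] - Z[misses]).sum(axis=0)
        weights -= np.abs(Z[i] - Z[hits]).sum(axis=0)
    weights /= n * n_neighbors
    order = _order(table.feature_names, weights, ascending=False)
    return SelectionResult(
        [table.feature_names[i] for i in order], weights[order], "relieff", k
    )


def rank_features(
    table: FeatureTable, method: str, k: int, n_neighbors: int = 10
) -> SelectionResult:
    """Dispatch on ranker name: ``mann_whitney`` (``mw``) or ``relieff``."""
    if method in ("mann_whitney", "mw"):
        return mann_whitney_rank(table, k)
    if method == "relieff":
        return relieff_rank(table, k, n_neighbors)
    raise ValueError(f"unknown selection method {method!r}")
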