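"""SMOTE oversampling of the minority (mutant) class.

Synthetic minority samples are linear interpolations between a minority
sample and one of its k nearest minority neighbours:

    x_new = x_i + g * (x_nn - x_i),   g ~ Uniform(0, 1)

so every synthetic point lies on a segment between two originals.
Neighbours are found by Euclidean distance on features standardized by
the (training) table's mean/sd; synthetic values are mapped back to the
original scale afterwards — an affine round-trip, so the convex-
combination property survives exactly.

Only oversampling is performed (no majority undersampling): synthesis
repeats until the minority count reaches ``target_ratio`` times the
majority count, within one sample. Original rows pass through
bit-identically; synthetic rows carry ``synthetic=True``. SMOTE is only
ever applied to training rows — the pipeline enforces this.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .datatypes import MINORITY, FeatureTable

__all__ = ["SmoteParams", "smote"]


@dataclasses.dataclass
class SmoteParams:
    k_neighbors: int = 5
    target_ratio: float = 1.0  # 1.0 = balanced classes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0.0 < self.target_ratio <= 1.5:
            raise ValueError("target_ratio must lie in (0, 1.5]")


def smote(table: FeatureTable, params: SmoteParams | None = None) -> FeatureTable:
    """Oversample the minority class to ``target_ratio`` x majority."""
    params = params or SmoteParams()
    y = table.y
    n_min = int(y.sum())
    n_maj = int((~y).sum())
    if n_min < 2:
        raise ValueError("minority count < 2: SMOTE needs at least two samples")
    if params.k_neighbors >= n_min:
        raise ValueError("k_neighbors must be < minority count")
    n_new = int(round(params.target_ratio * n_maj)) - n_min
    if n_new <= 0:
        return table

    X = table.X
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    min_idx = np.flatnonzero(y)
    Zmin = Z[min_idx]

    # k nearest minority neighbours of each minority sample (excluding self)
    d2 = ((Zmin[:, None, :] - Zmin[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, : params.k_neighbors]

    rng = np.random.default_rng(params.seed)
    rows = []
    for j in range(n_new):
        i = j % n_min  # cycle bases deterministically
        neighbour = nn[i, rng.integers(params.k_neighbors)]
        g = rng.random()
        z_new = Zmin[i] + g * (Zmin[neighbour] - Zmin[i])
        rows.append(z_new * sd + mu)

    synth = pd.DataFrame(np.asarray(rows), columns=table.feature_names)
    synth.insert(0, "sample_id", [f"syn_{j + 1:04d}" for j in range(n_new)])
    synth.insert(1, "patient_id", table.patient_ids[min_idx[np.arange(n_new) % n_min]])
    synth.insert(2, "label", MINORITY)
    synth.insert(3, "synthetic", True)
    out = pd.concat([table.frame, synth], ignore_index=True)
    return FeatureTable(out)
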