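"""Synthetic minority oversampling (SMOTE) of the training split.

Every minority class is oversampled up to the majority-class count
(one-versus-rest, 'auto' strategy). A synthetic sample is built by
picking a minority row x, one of its k nearest same-class neighbours
x_nn (Euclidean distance), and returning x + u * (x_nn - x) with
u ~ Uniform(0, 1) — i.e. a uniform draw on the segment between the two.
Original rows are preserved verbatim; synthetic rows are tagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import FeatureTable

__all__ = ["SmoteConfig", "smote_balance"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    strategy: str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.strategy != "auto":
            raise ValueError("only strategy='auto' (equalize to majority) is supported")


def smote_balance(train: FeatureTable, cfg: SmoteConfig) -> FeatureTable:
    """Equalize class counts of a training table by SMOTE interpolation.

    Binary 0/1 flag columns are interpolated like any other numeric
    column, so synthetic rows may hold fractional flag values.

    Raises if any feature value is missing (handle missing data upstream)
    or if a minority class has a single member (no neighbour to
    interpolate toward). When a class has fewer than ``k_neighbors + 1``
    members, k is clamped to ``class size - 1`` with a warning.
    """
    X = train.features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError(
            "missing values in feature columns; drop or fill incomplete rows before balancing"
        )
    y = train.labels
    classes, counts = np.unique(y, return_counts=True)
    majority = counts.max()
    rng = np.random.default_rng(cfg.seed)

    new_rows: list[np.ndarray] = []
    new_labels: list[int] = []
    for c, n_c in zip(classes, counts):
        deficit = int(majority - n_c)
        if deficit == 0:
            continue
        if n_c < 2:
            raise ValueError(f"class {c} has a single sample; SMOTE needs at least 2")
        k = cfg.k_neighbors
        if n_c - 1 < k:
            k = int(n_c - 1)
            log.warning("class %s has %d samples; clamping k_neighbors to %d", c, n_c, k)
        Xc = X[y == c]
        # pairwise Euclidean distances within the class; self excluded from neighbours
        d2 = ((Xc[:, None, :] - Xc[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn_idx = np.argsort(d2, axis=1, kind="stable")[:, :k]

        seeds = rng.integers(0, n_c, size=deficit)
        picks = rng.integers(0, k, size=deficit)
        gaps = rng.uniform(0.0, 1.0, size=deficit)
        for s, p, u in zip(seeds, picks, gaps):
            x = Xc[s]
            x_nn = Xc[nn_idx[s, p]]
            new_rows.append(x + u * (x_nn - x))
            new_labels.append(int(c))

    if not new_rows:
        return train.copy()

    synth_df = pd.DataFrame(np.vstack(new_rows), columns=train.feature_names)
    out_features = pd.concat([train.features, synth_df], ignore_index=True)
    out = FeatureTable(
        features=out_features,
        labels=np.concatenate([y, np.array(new_labels, dtype=int)]),
        condition=train.condition,
        split=np.concatenate([train.split, np.full(len(new_labels), "train", dtype=object)]),
        patient_ids=train.patient_ids
        + [f"synthetic_{i}" for i in range(len(new_labels))],
        synthetic=np.concatenate(
            [train.synthetic, np.ones(len(new_labels), dtype=bool)]
        ),
    )
    return out
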