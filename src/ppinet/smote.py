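"""Synthetic minority oversampling (SMOTE).

Each synthetic minority sample is drawn by picking a real minority point
x, one of its k nearest minority neighbors x_nn (Euclidean distance on
standardized features), and returning x + u * (x_nn - x) with
u ~ Uniform(0, 1): a random point on the segment between neighbors.
Synthetic points therefore stay inside the convex hull of the minority
class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    target_count: int | None = None  # absolute positive count after oversampling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def smote_oversample(positives: pd.DataFrame, config: SmoteConfig) -> pd.DataFrame:
    """Oversample minority rows to ``config.target_count`` total rows.

    Rows must be fully numeric with no missing values.  The original rows
    are returned first, followed by the synthetic ones (index reset, with a
    ``synthetic__<i>`` marker in a trailing level-free index).
    """
    n = len(positives)
    target = config.target_count if config.target_count is not None else 2 * n
    if target < n:
        raise ValueError(f"SMOTE target {target} below original count {n}")
    k = config.k_neighbors
    if n < k + 1:
        raise ValueError(f"SMOTE needs at least k+1={k + 1} minority rows, got {n}")
    values = positives.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("SMOTE input must be imputed (no missing values)")
    n_synthetic = target - n
    if n_synthetic == 0:
        return positives.reset_index(drop=True)

    # neighbor search on standardized features so no coordinate dominates
    scale = values.std(axis=0)
    scale[scale == 0] = 1.0
    standardized = (values - values.mean(axis=0)) / scale
    nn = NearestNeighbors(n_neighbors=k + 1).fit(standardized)
    neighbor_idx = nn.kneighbors(standardized, return_distance=False)[:, 1:]  # drop self

    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, n, size=n_synthetic)
    picks = rng.integers(0, k, size=n_synthetic)
    gaps = rng.uniform(0.0, 1.0, size=n_synthetic)
    base = values[seeds]
    neighbors = values[neighbor_idx[seeds, picks]]
    synthetic = base + gaps[:, None] * (neighbors - base)

    out = pd.DataFrame(
        np.vstack([values, synthetic]), columns=positives.columns
    )
    out.index = [f"orig__{i}" for i in range(n)] + [f"synthetic__{i}" for i in range(n_synthetic)]
    return out
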