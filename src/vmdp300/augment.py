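"""SMOTE class balancing for the 1:7 target/non-target imbalance.

One target among eight stimulus objects leaves the feature tables with a
7:1 majority of non-P300 rows.  Synthetic minority rows are generated by the
classic SMOTE rule: pick a minority row x, one of its k nearest minority
neighbours x_nn (Euclidean distance on the raw feature values), and emit
x + u * (x_nn - x) with u ~ Uniform(0, 1).  All original rows pass through
unmodified; synthetic rows are flagged.

Neighbour ties at equal distance are broken by row index so a seeded run is
fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .features import FeatureTable

logger = logging.getLogger(__name__)

__all__ = ["SmoteConfig", "smote_balance", "smote_sample"]


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    seed: int = 0
    target_ratio: float = 1.0  # desired minority/majority count ratio

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0 < self.target_ratio <= 1:
            raise ValueError("target_ratio must be in (0, 1]")


def _knn_indices(points: np.ndarray, k: int, chunk: int = 512) -> np.ndarray:
    """Indices of the k nearest neighbours of each point among the points.

    Self is excluded; ties broken by ascending row index (stable lexsort),
    so the result is independent of any RNG.
    """
    n = points.shape[0]
    out = np.empty((n, k), dtype=int)
    sq = (points**2).sum(axis=1)
    order = np.arange(n)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        d2 = sq[sl, None] - 2.0 * points[sl] @ points.T + sq[None, :]
        np.maximum(d2, 0.0, out=d2)
        d2[np.arange(sl.stop - sl.start), order[sl]] = np.inf  # drop self
        for i in range(d2.shape[0]):
            idx = np.lexsort((order, d2[i]))
            out[sl.start + i] = idx[:k]
    return out


def smote_sample(
    minority: np.ndarray, n_synthetic: int, config: SmoteConfig
) -> np.ndarray:
    """Generate ``n_synthetic`` interpolated minority points."""
    minority = np.asarray(minority, dtype=float)
    n_min = minority.shape[0]
    if n_min < config.k_neighbors + 1:
        raise ValueError(
            f"minority class has {n_min} rows; SMOTE with k="
            f"{config.k_neighbors} needs at least {config.k_neighbors + 1}"
        )
    if n_synthetic == 0:
        return np.empty((0, minority.shape[1]))
    nn = _knn_indices(minority, config.k_neighbors)
    rng = np.random.default_rng(config.seed)
    base = rng.integers(0, n_min, size=n_synthetic)
    pick = rng.integers(0, config.k_neighbors, size=n_synthetic)
    u = rng.random(n_synthetic)
    neighbours = minority[nn[base, pick]]
    return minority[base] + u[:, None] * (neighbours - minority[base])


def smote_balance(table: FeatureTable, config: SmoteConfig = SmoteConfig()) -> FeatureTable:
    """Balance a feature table by oversampling the minority class.

    Output rows = all original rows (unchanged, in order) followed by the
    synthetic minority rows; ``synthetic`` flags mark provenance.  The
    synthetic count is ``round(target_ratio * majority) - minority``
    (nothing is generated when the table is already balanced).
    """
    values, labels = table.values, table.labels
    if not np.isfinite(values).all():
        raise ValueError("features must be finite")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"expected two classes, got {classes.tolist()}")
    minority_class = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_synthetic = max(0, int(round(config.target_ratio * n_maj)) - n_min)
    if n_synthetic == 0:
        logger.info("classes already satisfy target_ratio; nothing to synthesise")
        return FeatureTable(
            values=values.copy(),
            labels=labels.copy(),
            mode_id=table.mode_id,
            names=table.names,
            synthetic=np.zeros(len(labels), dtype=bool),
        )
    minority = values[labels == minority_class]
    synth = smote_sample(minority, n_synthetic, config)
    logger.info(
        "SMOTE: %d minority + %d majority -> +%d synthetic rows",
        n_min, n_maj, n_synthetic,
    )
    return FeatureTable(
        values=np.vstack([values, synth]),
        labels=np.concatenate([labels, np.full(n_synthetic, minority_class)]),
        mode_id=table.mode_id,
        names=table.names,
        synthetic=np.concatenate(
            [np.zeros(len(labels), dtype=bool), np.ones(n_synthetic, dtype=bool)]
        ),
    )
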