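"""SMOTE oversampling and dataset balancing.

Synthetic minority over-sampling: each synthetic example is a random convex
combination ``x + u (z - x)`` of a minority sample ``x`` and one of its k
nearest minority neighbours ``z`` (Euclidean metric, k = 5 by default).
Balancing augments the minority class this way and optionally subsamples the
majority class.

Applying SMOTE to a whole dataset before cross-validation leaks synthetic
copies of held-out information into training folds and overestimates
performance; :func:`noduletex.evaluate.cross_validate` therefore applies it
inside training folds by default, with a whole-dataset mode retained for
comparison with the study design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["Dataset", "smote_oversample", "balance_dataset"]


@dataclass
class Dataset:
    """Feature matrix with labels and patient grouping.

    ``y`` is binary (1 = malignant, 0 = benign by convention).  ``groups``
    carries patient ids so cross-validation can keep a patient's ROIs
    together; synthetic rows get group ``None``-equivalent (empty string).
    """

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    feature_names: List[str]
    synthetic: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.groups = np.asarray(self.groups)
        n = self.X.shape[0]
        if not (len(self.y) == len(self.groups) == n):
            raise ValueError("inconsistent lengths")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names do not match X columns")
        if np.isnan(self.X).any():
            raise ValueError("missing values in feature matrix")
        if self.synthetic is None:
            self.synthetic = np.zeros(n, dtype=bool)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def class_counts(self) -> dict:
        vals, counts = np.unique(self.y, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def smote_oversample(minority: np.ndarray, amount_pct: int, k: int = 5,
                     seed: int = 0) -> np.ndarray:
    """Generate ``(amount_pct/100) * m`` synthetic minority rows.

    ``amount_pct`` must be a positive multiple of 100.  Each original row
    spawns ``amount_pct/100`` synthetic rows, each placed uniformly at random
    on the segment to one of the row's k nearest neighbours (neighbours may
    repeat when ``amount_pct/100 > k``, as in the original algorithm).
    """
    minority = np.asarray(minority, dtype=float)
    m = minority.shape[0]
    if amount_pct <= 0 or amount_pct % 100:
        raise ValueError("amount_pct must be a positive multiple of 100")
    if m <= k:
        raise ValueError(f"need more than k={k} minority samples, got {m}")
    reps = amount_pct // 100
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    # first neighbour is the point itself
    idx = nn.kneighbors(minority, return_distance=False)[:, 1:]
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(m):
        picks = rng.integers(0, k, size=reps)
        u = rng.random(reps)
        for r in range(reps):
            z = minority[idx[i, picks[r]]]
            rows.append(minority[i] + u[r] * (z - minority[i]))
    return np.asarray(rows)


def balance_dataset(ds: Dataset, amount_pct: int = 300, k: int = 5,
                    majority_target: int | str = "match",
                    seed: int = 0, passthrough: bool = False) -> Dataset:
    """SMOTE-augment the minority class and subsample the majority.

    ``majority_target`` is either an explicit count (must not exceed the
    majority size: subsampling is without replacement) or ``"match"`` to
    subsample down to the new minority size.  ``passthrough=True`` returns
    the dataset unchanged (no-op mode for already balanced data).
    """
    if passthrough:
        return ds
    counts = ds.class_counts()
    if len(counts) != 2:
        raise ValueError("need exactly two classes")
    minority_label = min(counts, key=counts.get)
    majority_label = max(counts, key=counts.get)
    min_mask = ds.y == minority_label
    maj_mask = ~min_mask
    synth = smote_oversample(ds.X[min_mask], amount_pct, k, seed)
    new_min_size = int(min_mask.sum()) + synth.shape[0]
    if majority_target == "match":
        target = new_min_size
    else:
        target = int(majority_target)
    maj_idx = np.flatnonzero(maj_mask)
    if target > len(maj_idx):
        raise ValueError(
            f"majority_target {target} exceeds majority size {len(maj_idx)}; "
            "under-sampling cannot grow a class")
    rng = np.random.default_rng(seed + 1)
    keep = np.sort(rng.choice(maj_idx, size=target, replace=False))
    orig_idx = np.concatenate([np.flatnonzero(min_mask), keep])
    X = np.vstack([ds.X[orig_idx], synth])
    y = np.concatenate([ds.y[orig_idx],
                        np.full(synth.shape[0], minority_label, dtype=ds.y.dtype)])
    groups = np.concatenate([ds.groups[orig_idx],
                             np.full(synth.shape[0], "", dtype=ds.groups.dtype)])
    synthetic = np.concatenate([np.zeros(len(orig_idx), dtype=bool),
                                np.ones(synth.shape[0], dtype=bool)])
    return Dataset(X=X, y=y, groups=groups,
                   feature_names=list(ds.feature_names), synthetic=synthetic)
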