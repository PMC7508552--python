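"""kNN classification of risk trajectories and accuracy-vs-duration curves.

Protocol: spectral clustering of the full dataset provides ground-truth
labels; a 70/30 patient-level split is drawn; spectral clustering is re-run
on the training subset's full-window rows to generate training labels; both
train and test rows are truncated to the first m hours of data and a
5-nearest-neighbor vote (Euclidean distance) predicts test labels. Cluster
numberings from the two clustering runs are matched by descending septic
shock prevalence, so the metric is invariant to arbitrary label permutations.
Bootstrap resampling of the test set yields percentile 90% confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .cluster import ClusterParams, order_clusters_by_outcome, spectral_clustering
from .exceptions import InputError
from .traj import TrajectoryMatrix


def split_train_test(n_or_matrix, fraction: float = 0.7,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Patient-level random split; returns (train_idx, test_idx)."""
    if not 0.0 < fraction < 1.0:
        raise InputError(f"fraction must lie in (0, 1), got {fraction}")
    n = (n_or_matrix.n_patients if isinstance(n_or_matrix, TrajectoryMatrix)
         else int(n_or_matrix))
    if n < 2:
        raise InputError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * fraction))
    n_train = min(max(n_train, 1), n - 1)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def knn_predict(train_X: np.ndarray, train_y: np.ndarray, test_X: np.ndarray,
                k: int = 5) -> np.ndarray:
    """Majority vote among the k nearest training rows (Euclidean).

    Vote ties resolve to the label of the single nearest neighbor among the
    tied classes.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    train_y = np.asarray(train_y)
    if train_X.shape[1] != test_X.shape[1]:
        raise InputError(f"dimension mismatch: train has {train_X.shape[1]} "
                         f"columns, test has {test_X.shape[1]}")
    if len(train_X) < k:
        raise InputError(f"need at least k={k} training rows")
    d = cdist(test_X, train_X)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    out = np.empty(len(test_X), dtype=train_y.dtype)
    for i in range(len(test_X)):
        votes = train_y[order[i]]
        labs, counts = np.unique(votes, return_counts=True)
        winners = labs[counts == counts.max()]
        if len(winners) == 1:
            out[i] = winners[0]
        else:  # tie: first neighbor whose label is among the tied classes
            for v in votes:
                if v in winners:
                    out[i] = v
                    break
    return out


@dataclass
class ClassifierEval:
    durations_h: np.ndarray
    accuracy: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_boot: int
    seed: int
    split_fraction: float
    n_train: int = 0
    n_test: int = 0
    extras: dict = field(default_factory=dict)


def evaluate_accuracy_vs_duration(matrix: TrajectoryMatrix,
                                  ground_truth_labels: np.ndarray,
                                  shock_flags: np.ndarray,
                                  params: ClusterParams | None = None,
                                  durations_h=None, n_boot: int = 1000,
                                  fraction: float = 0.7,
                                  k_neighbors: int = 5,
                                  seed: int = 0) -> ClassifierEval:
    """Classification accuracy as a function of observed trajectory duration.

    ``ground_truth_labels`` are outcome-ordered cluster numbers from
    clustering the entire dataset; training labels are regenerated by
    clustering the train subset's full-window rows (with the same number of
    clusters) and ordering them by shock prevalence, so equal numbers are
    considered equivalent.
    """
    params = params or ClusterParams()
    values = matrix.values
    gt = np.asarray(ground_truth_labels)
    flags = np.asarray(shock_flags, dtype=bool)
    if durations_h is None:
        durations_h = np.arange(0, int(matrix.window[1]) + 1)
    durations_h = np.asarray(durations_h, dtype=float)
    if durations_h.max() > matrix.window[1] + 1e-9:
        raise InputError("duration exceeds the trajectory window")

    train_idx, test_idx = split_train_test(len(values), fraction, seed)
    n_clusters = len(np.unique(gt))
    train_res = spectral_clustering(values[train_idx], params, k=n_clusters)
    train_res.patient_ids = [matrix.patient_ids[i] for i in train_idx]
    train_labels = order_clusters_by_outcome(
        train_res, flags[train_idx]).assignments

    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, len(test_idx), size=(n_boot, len(test_idx)))
    acc = np.empty(len(durations_h))
    lo = np.empty(len(durations_h))
    hi = np.empty(len(durations_h))
    rel = matrix.relative_times_h
    for i, m in enumerate(durations_h):
        cols = (rel >= -1e-9) & (rel <= m + 1e-9)
        pred = knn_predict(values[np.ix_(train_idx, np.nonzero(cols)[0])],
                           train_labels,
                           values[np.ix_(test_idx, np.nonzero(cols)[0])],
                           k=k_neighbors)
        correct = (pred == gt[test_idx]).astype(float)
        acc[i] = correct.mean()
        boot_acc = correct[boot_idx].mean(axis=1)
        lo[i], hi[i] = np.quantile(boot_acc, [0.05, 0.95])
    return ClassifierEval(durations_h=durations_h, accuracy=acc, ci_lower=lo,
                          ci_upper=hi, n_boot=n_boot, seed=seed,
                          split_fraction=fraction, n_train=len(train_idx),
                          n_test=len(test_idx))
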