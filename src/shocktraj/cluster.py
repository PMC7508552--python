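"""Spectral clustering of risk trajectories, written out in full.

The pipeline is the classical one: a Gaussian affinity over Euclidean
distances between trajectory rows, ``w_ij = exp(-(d_ij / sigma)^2)``; the
graph Laplacian (unnormalized ``L = D - W`` or symmetric-normalized
``L = I - D^{-1/2} W D^{-1/2}``); the eigengap heuristic to choose the number
of clusters k; the spectral embedding into the bottom-k eigenvectors (rows
renormalized to unit length in the normalized variant); and k-means on the
embedding. Clusters are finally renumbered 1..k in descending order of septic
shock prevalence so that cluster 1 is always the highest-risk group.

A raw squared-Euclidean kernel over a 13-dimensional risk vector can drive
every off-diagonal weight to ~0, so by default distances are rescaled by the
median pairwise distance before the kernel (sigma = 1 on that scale); the
literal unit-bandwidth kernel is available with ``distance_scaling="none"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .exceptions import ConfigError, InputError, NumericalError
from .traj import TrajectoryMatrix


@dataclass
class ClusterParams:
    sigma: float = 1.0
    distance_scaling: str = "median_knn"  # or "median_pairwise" / "none"
    knn_k: int = 7
    laplacian: str = "sym_normalized"  # or "unnormalized"
    k_max: int = 8
    kmeans_restarts: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ConfigError("sigma: must be > 0")
        if self.k_max < 2:
            raise ConfigError("k_max: must be >= 2")
        if self.knn_k < 1:
            raise ConfigError("knn_k: must be >= 1")
        if self.distance_scaling not in ("none", "median_pairwise", "median_knn"):
            raise ConfigError(f"distance_scaling: unknown {self.distance_scaling!r}")
        if self.laplacian not in ("unnormalized", "sym_normalized"):
            raise ConfigError(f"laplacian: unknown {self.laplacian!r}")


@dataclass
class SpectralDecomposition:
    eigenvalues: np.ndarray  # ascending
    eigenvectors: np.ndarray  # columns matched to eigenvalues

    @property
    def gaps(self) -> np.ndarray:
        """``gaps[k]`` = lambda_{k+1} - lambda_k (1-based k, so index k-1)."""
        return np.diff(self.eigenvalues)


@dataclass
class ClusterResult:
    k: int
    assignments: np.ndarray  # per-row cluster labels
    patient_ids: list[str]
    decomposition: SpectralDecomposition
    params: ClusterParams
    ordered: bool = False
    low_confidence: bool = False
    prevalence: dict[int, float] = field(default_factory=dict)

    def assignment_map(self) -> dict[str, int]:
        return dict(zip(self.patient_ids, (int(a) for a in self.assignments)))


# ---------------------------------------------------------------- primitives
def affinity_matrix(X: np.ndarray, params: ClusterParams | None = None
                    ) -> np.ndarray:
    """Gaussian-kernel affinity ``w_ij = exp(-(d_ij / sigma)^2)``.

    ``d`` is the Euclidean distance between trajectory rows, optionally
    rescaled before the kernel. ``median_knn`` (default) divides by the median
    distance to the ``knn_k``-th nearest neighbor - a self-tuning bandwidth on
    the within-cluster scale, which keeps the affinity graph informative when
    cluster separations are small relative to the data's overall spread;
    ``median_pairwise`` divides by the median pairwise distance; ``none``
    applies the literal unit-bandwidth kernel. Symmetric with unit diagonal.
    """
    params = params or ClusterParams()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("affinity_matrix expects a 2-D matrix with >= 2 rows")
    if not np.isfinite(X).all():
        raise InputError("affinity_matrix input contains non-finite values")
    d = pdist(X, metric="euclidean")
    if params.distance_scaling == "median_pairwise":
        med = np.median(d)
        if med > 0:
            d = d / med
    elif params.distance_scaling == "median_knn":
        D = squareform(d)
        np.fill_diagonal(D, np.inf)
        k = min(params.knn_k, len(D) - 1)
        med = float(np.median(np.partition(D, k - 1, axis=1)[:, k - 1]))
        if med > 0:
            d = d / med
    w = np.exp(-((d / params.sigma) ** 2))
    W = squareform(w)
    np.fill_diagonal(W, 1.0)
    return W


def graph_laplacian(W: np.ndarray, variant: str = "sym_normalized") -> np.ndarray:
    """Graph Laplacian of a symmetric nonnegative affinity matrix."""
    W = np.asarray(W, dtype=float)
    if not np.allclose(W, W.T, atol=1e-10):
        raise InputError("affinity matrix must be symmetric")
    deg = W.sum(axis=1)
    if (deg <= 0).any():
        raise InputError("zero-degree row: isolated node in the affinity graph")
    if variant == "unnormalized":
        return np.diag(deg) - W
    if variant == "sym_normalized":
        inv_sqrt = 1.0 / np.sqrt(deg)
        return np.eye(len(W)) - (inv_sqrt[:, None] * W) * inv_sqrt[None, :]
    raise ConfigError(f"laplacian: unknown variant {variant!r}")


def spectral_decomposition(L: np.ndarray) -> SpectralDecomposition:
    """Full symmetric eigendecomposition with ascending eigenvalues."""
    try:
        vals, vecs = scipy.linalg.eigh(L)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise NumericalError(f"eigensolver failed: {exc}") from exc
    return SpectralDecomposition(eigenvalues=vals, eigenvectors=vecs)


def eigengap_select_k(decomposition: SpectralDecomposition | np.ndarray,
                      k_max: int = 8) -> int:
    """Number of clusters by the eigengap heuristic.

    k = argmax over 2..k_max of (lambda_{k+1} - lambda_k); ties break toward
    the smaller k, so a featureless spectrum yields the minimum admissible k.
    """
    vals = (decomposition.eigenvalues
            if isinstance(decomposition, SpectralDecomposition)
            else np.asarray(decomposition, dtype=float))
    if k_max + 1 > len(vals):
        raise InputError(f"k_max={k_max} needs at least {k_max + 1} eigenvalues, "
                         f"got {len(vals)}")
    gaps = np.diff(vals)  # gaps[k-1] = lambda_{k+1} - lambda_k
    ks = np.arange(2, k_max + 1)
    return int(ks[np.argmax(gaps[ks - 1])])


def spectral_embed(L: np.ndarray, k: int,
                   variant: str = "sym_normalized") -> np.ndarray:
    """Rows-by-k embedding from the eigenvectors of the k smallest eigenvalues.

    In the symmetric-normalized variant embedding rows are renormalized to
    unit length (zero rows are left as zero).
    """
    if k < 2:
        raise InputError("k must be >= 2")
    if k > len(L):
        raise InputError(f"k={k} exceeds the number of rows {len(L)}")
    try:
        vals, vecs = scipy.linalg.eigh(L, subset_by_index=[0, k - 1])
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise NumericalError(f"eigensolver failed for k={k}: {exc}") from exc
    emb = vecs
    if variant == "sym_normalized":
        norms = np.linalg.norm(emb, axis=1, keepdims=True)
        emb = np.where(norms > 0, emb / np.where(norms > 0, norms, 1.0), 0.0)
    return emb


def kmeans_cluster(embedding: np.ndarray, k: int, restarts: int = 50,
                   seed: int = 0) -> np.ndarray:
    """Best-of-restarts k-means labels (k-means++ seeding, fixed seed)."""
    embedding = np.asarray(embedding, dtype=float)
    if k > len(embedding):
        raise InputError(f"k={k} exceeds the number of rows {len(embedding)}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    return km.fit_predict(embedding)


# ------------------------------------------------------------------ pipeline
def spectral_clustering(X: TrajectoryMatrix | np.ndarray,
                        params: ClusterParams | None = None,
                        k: int | None = None) -> ClusterResult:
    """Affinity -> Laplacian -> eigengap -> embedding -> k-means.

    ``k`` overrides the eigengap choice when given. The result is flagged
    low-confidence when the winning gap is less than twice the median gap in
    the searched range.
    """
    params = params or ClusterParams()
    if isinstance(X, TrajectoryMatrix):
        ids, values = list(X.patient_ids), X.values
    else:
        values = np.asarray(X, dtype=float)
        ids = [str(i) for i in range(len(values))]
    W = affinity_matrix(values, params)
    L = graph_laplacian(W, params.laplacian)
    decomp = spectral_decomposition(L)
    k_max = min(params.k_max, len(values) - 1)
    if k is None:
        k = eigengap_select_k(decomp, k_max)
    search = decomp.gaps[1:k_max]
    low_conf = bool(search.size > 1
                    and search.max() < 2.0 * np.median(search))
    emb = spectral_embed(L, k, params.laplacian)
    labels = kmeans_cluster(emb, k, params.kmeans_restarts, params.seed)
    return ClusterResult(k=int(k), assignments=labels, patient_ids=ids,
                         decomposition=decomp, params=params,
                         low_confidence=low_conf)


def order_clusters_by_outcome(result: ClusterResult,
                              shock_flags: Sequence[bool] | Mapping[str, bool]
                              ) -> ClusterResult:
    """Renumber clusters 1..k in descending septic-shock prevalence.

    Prevalence ties break toward the larger cluster. ``shock_flags`` is either
    per-row or a mapping patient id -> flag.
    """
    if isinstance(shock_flags, Mapping):
        flags = np.array([bool(shock_flags[p]) for p in result.patient_ids])
    else:
        flags = np.asarray(list(shock_flags), dtype=bool)
    if len(flags) != len(result.assignments):
        raise InputError("shock_flags length does not match assignments")
    labels = np.unique(result.assignments)
    stats = []
    for lab in labels:
        mask = result.assignments == lab
        stats.append((float(flags[mask].mean()), int(mask.sum()), lab))
    # sort by prevalence desc, then size desc
    stats.sort(key=lambda s: (-s[0], -s[1], s[2]))
    remap = {old: new + 1 for new, (_, _, old) in enumerate(stats)}
    new_assign = np.array([remap[a] for a in result.assignments])
    prevalence = {remap[old]: prev for prev, _, old in stats}
    return replace(result, assignments=new_assign, ordered=True,
                   prevalence=prevalence)


# ------------------------------------------------------------------- utility
def normalized_cut(W: np.ndarray, labels: np.ndarray) -> float:
    """Normalized-cut value of a partition: sum_A cut(A, ~A) / vol(A)."""
    W = np.asarray(W, dtype=float)
    labels = np.asarray(labels)
    total = 0.0
    deg = W.sum(axis=1)
    for lab in np.unique(labels):
        mask = labels == lab
        vol = deg[mask].sum()
        if vol <= 0:
            return np.inf
        cut = W[np.ix_(mask, ~mask)].sum()
        total += cut / vol
    return float(total)


def min_ncut_bipartition(W: np.ndarray) -> tuple[float, np.ndarray]:
    """Exhaustive minimum normalized cut over all bipartitions (small n only)."""
    n = len(W)
    if n > 20:
        raise InputError("exhaustive search is limited to n <= 20 rows")
    best, best_labels = np.inf, None
    for code in range(1, 2 ** (n - 1)):
        labels = np.array([(code >> i) & 1 for i in range(n)])
        val = normalized_cut(W, labels)
        if val < best:
            best, best_labels = val, labels
    return float(best), best_labels
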