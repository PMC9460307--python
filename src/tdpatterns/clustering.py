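"""Kernel k-means on MDTW distances with silhouette and Dunn indices.

The MDTW distance matrix is mapped to a similarity kernel (Gaussian on
the distance, median-heuristic bandwidth by default) and clustered by
kernel k-means: k-means in the implicit feature space, using only the
kernel trick

    ||phi(i) - mu_c||^2 = K_ii - (2/|c|) sum_{j in c} K_ij
                          + (1/|c|^2) sum_{j,l in c} K_jl.

MDTW is not guaranteed to produce a positive semidefinite kernel, so an
optional diagonal-shift repair adds |lambda_min| to the diagonal when the
smallest eigenvalue is negative; this preserves the off-diagonal
structure and keeps the kernel-trick algebra valid.

Cluster-count selection uses the silhouette and Dunn internal validity
indices computed on the original distances; higher values indicate
tighter, better-separated clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mdtw import DistanceMatrix

__all__ = [
    "KernelConfig",
    "ClusterResult",
    "distance_to_kernel",
    "kernel_kmeans",
    "silhouette_index",
    "dunn_index",
    "select_k",
]


@dataclass(frozen=True)
class KernelConfig:
    """Distance-to-kernel map.

    transform
        ``gaussian_sq`` (default): K_ij = exp(-d_ij^2 / (2 sigma^2)).
        ``gaussian``: K_ij = exp(-d_ij / (2 sigma^2)) — treats the MDTW
        value, itself a sum of squared differences, as already squared.
    sigma_rule
        ``median_offdiag`` (default) sets sigma to the median
        off-diagonal distance; ``fixed`` uses ``sigma_value``.
    psd_repair
        ``diagonal_shift`` (default) adds |lambda_min| + 1e-10 to the
        diagonal when the minimum eigenvalue is negative; ``none`` skips.
    """

    transform: str = "gaussian_sq"
    sigma_rule: str = "median_offdiag"
    sigma_value: float | None = None
    psd_repair: str = "diagonal_shift"

    def __post_init__(self) -> None:
        if self.transform not in ("gaussian_sq", "gaussian"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.sigma_rule not in ("median_offdiag", "fixed"):
            raise ValueError(f"unknown sigma_rule {self.sigma_rule!r}")
        if self.sigma_rule == "fixed" and not (self.sigma_value and self.sigma_value > 0):
            raise ValueError("fixed sigma_rule requires positive sigma_value")
        if self.psd_repair not in ("diagonal_shift", "none"):
            raise ValueError(f"unknown psd_repair {self.psd_repair!r}")


def _as_matrix(D) -> np.ndarray:
    if isinstance(D, DistanceMatrix):
        return D.values
    return np.asarray(D, dtype=float)


def distance_to_kernel(D, config: KernelConfig = KernelConfig()) -> np.ndarray:
    """Map a distance matrix to a similarity kernel with unit diagonal."""
    d = _as_matrix(D)
    if config.sigma_rule == "fixed":
        sigma = float(config.sigma_value)
    else:
        iu = np.triu_indices(d.shape[0], k=1)
        sigma = float(np.median(d[iu]))
        if sigma <= 0:
            raise ValueError("median off-diagonal distance is zero; use a fixed sigma")
    if config.transform == "gaussian_sq":
        K = np.exp(-(d**2) / (2.0 * sigma**2))
    else:
        K = np.exp(-d / (2.0 * sigma**2))
    K = (K + K.T) / 2.0
    if config.psd_repair == "diagonal_shift":
        lam_min = float(np.linalg.eigvalsh(K)[0])
        if lam_min < 0:
            K = K + np.eye(K.shape[0]) * (abs(lam_min) + 1e-10)
    return K


@dataclass
class ClusterResult:
    """Outcome of one kernel k-means solve (best of ``n_init`` starts)."""

    labels: np.ndarray          # 1..k
    objective: float
    n_iter: int
    k: int
    seed: int | None
    n_init: int
    objective_history: list[float] = field(default_factory=list)
    all_histories: list[list[float]] = field(default_factory=list)
    silhouette: float | None = None
    dunn: float | None = None

    def to_frame(self, ids: Sequence[str] | None = None) -> pd.DataFrame:
        ids = list(ids) if ids is not None else list(range(len(self.labels)))
        return pd.DataFrame({"participant_id": ids, "label": self.labels})


def _kkmeans_once(K: np.ndarray, k: int, rng: np.random.Generator, max_iter: int):
    n = K.shape[0]
    Kd = np.diag(K).copy()
    # seed from k distinct medoids, assign by single-point kernel distance
    medoids = rng.choice(n, size=k, replace=False)
    d0 = Kd[:, None] - 2.0 * K[:, medoids] + Kd[medoids][None, :]
    labels = np.argmin(d0, axis=1)
    history: list[float] = []
    for it in range(1, max_iter + 1):
        S = np.zeros((n, k))
        S[np.arange(n), labels] = 1.0
        counts = S.sum(axis=0)
        # reseed any empty cluster from the point farthest from its centroid
        while (counts == 0).any():
            occupied = counts > 0
            Sn = S[:, occupied] / counts[occupied]
            KS = K @ Sn
            quad = np.einsum("nc,nc->c", Sn, K @ Sn)
            d_occ = Kd[:, None] - 2.0 * KS + quad[None, :]
            cur = d_occ[np.arange(n), np.searchsorted(np.flatnonzero(occupied), labels)]
            far = int(np.argmax(cur))
            empty = int(np.flatnonzero(counts == 0)[0])
            S[far, labels[far]] = 0.0
            S[far, empty] = 1.0
            labels[far] = empty
            counts = S.sum(axis=0)
        Sn = S / counts
        KS = K @ Sn                                   # (n, k)
        quad = np.einsum("nc,nc->c", Sn, K @ Sn)      # (k,)
        dist2 = Kd[:, None] - 2.0 * KS + quad[None, :]
        new_labels = np.argmin(dist2, axis=1)
        obj = float(dist2[np.arange(n), new_labels].sum())
        history.append(obj)
        if np.array_equal(new_labels, labels):
            return labels, obj, it, history
        labels = new_labels
    return labels, history[-1], max_iter, history


def kernel_kmeans(
    K,
    k: int,
    n_init: int = 20,
    max_iter: int = 100,
    seed: int | None = None,
) -> ClusterResult:
    """Kernel k-means; returns the best of ``n_init`` random starts.

    Labels are reported 1-based.  Within a run the objective (sum of
    squared feature-space distances to centroids) is nonincreasing
    across iterations; empty clusters are reseeded from the point
    farthest from its current centroid.
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for n={n}")
    if k == 1:
        labels = np.ones(n, dtype=int)
        obj = float(np.diag(K).sum() - K.sum() / n)
        return ClusterResult(labels, obj, 0, k, seed, n_init, [obj], [[obj]])
    rng = np.random.default_rng(seed)
    best = None
    histories: list[list[float]] = []
    for _ in range(n_init):
        labels, obj, n_iter, hist = _kkmeans_once(K, k, rng, max_iter)
        histories.append(hist)
        if best is None or obj < best[1] - 1e-12:
            best = (labels, obj, n_iter, hist)
    labels, obj, n_iter, hist = best
    return ClusterResult(
        labels=labels + 1,
        objective=obj,
        n_iter=n_iter,
        k=k,
        seed=seed,
        n_init=n_init,
        objective_history=hist,
        all_histories=histories,
    )


def _check_labels(D: np.ndarray, labels: np.ndarray) -> list[np.ndarray]:
    labels = np.asarray(labels)
    if labels.shape[0] != D.shape[0]:
        raise ValueError("labels length must match distance matrix")
    groups = [np.flatnonzero(labels == u) for u in np.unique(labels)]
    return groups


def silhouette_index(D, labels) -> float:
    """Mean silhouette width on a precomputed distance matrix.

    For point i: a = mean distance to its own cluster (excluding self),
    b = smallest mean distance to another cluster, s = (b-a)/max(a,b).
    Members of singleton clusters contribute 0 by convention.
    """
    d = _as_matrix(D)
    groups = _check_labels(d, labels)
    if len(groups) < 2:
        raise ValueError("silhouette needs at least two clusters")
    labels = np.asarray(labels)
    s = np.zeros(d.shape[0])
    means = np.stack([d[:, g].mean(axis=1) for g in groups], axis=1)  # (n, k)
    sizes = np.array([g.size for g in groups])
    for ci, g in enumerate(groups):
        if g.size == 1:
            s[g] = 0.0
            continue
        a = d[np.ix_(g, g)].sum(axis=1) / (sizes[ci] - 1)
        b = np.min(np.delete(means[g], ci, axis=1), axis=1)
        denom = np.maximum(a, b)
        with np.errstate(invalid="ignore"):
            si = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
        s[g] = si
    return float(s.mean())


def dunn_index(D, labels) -> float:
    """Minimum between-cluster distance over maximum within-cluster diameter."""
    d = _as_matrix(D)
    groups = _check_labels(d, labels)
    if len(groups) < 2:
        raise ValueError("Dunn index needs at least two clusters")
    diam = max(
        float(d[np.ix_(g, g)].max()) if g.size > 1 else 0.0 for g in groups
    )
    if diam <= 0:
        raise ValueError("Dunn index undefined: zero maximum intra-cluster diameter")
    sep = min(
        float(d[np.ix_(gi, gj)].min())
        for a, gi in enumerate(groups)
        for gj in groups[a + 1 :]
    )
    return sep / diam


def select_k(
    D,
    k_range: Iterable[int],
    kernel_config: KernelConfig = KernelConfig(),
    n_init: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Validity-index table over candidate cluster counts.

    One kernel k-means solve per k; silhouette and Dunn are evaluated on
    the original distances.  Higher values indicate better clustering.
    """
    d = _as_matrix(D)
    K = distance_to_kernel(d, kernel_config)
    rows = []
    for k in k_range:
        if not 2 <= k <= d.shape[0] - 1:
            raise ValueError(f"k={k} outside [2, n-1]")
        res = kernel_kmeans(K, k, n_init=n_init, seed=seed)
        try:
            dunn = dunn_index(d, res.labels)
        except ValueError:
            dunn = float("nan")  # zero diameters (duplicated points)
        rows.append(
            {
                "k": k,
                "silhouette": silhouette_index(d, res.labels),
                "dunn": dunn,
                "objective": res.objective,
            }
        )
    return pd.DataFrame(rows)
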