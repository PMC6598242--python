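"""Spectral clustering of enriched terms with eigengap model selection.

The similarity matrix is treated as a graph affinity. The number of
clusters, when not fixed by the user, is chosen with the eigengap heuristic
on the symmetric normalized Laplacian L = I - D^{-1/2} A D^{-1/2}: with
ascending eigenvalues l_1 <= ... <= l_n, k is the argmax over 1..k_max of
l_{k+1} - l_k. The first gap is eligible, so a single-cluster answer is
possible. Clustering itself is scikit-learn spectral clustering on the
precomputed affinity, seeded for determinism.

Labels are canonicalized after clustering: cluster 0 is the cluster holding
the lexicographically smallest term id, cluster 1 the smallest id among the
rest, and so on — making label vectors comparable across runs.

Each cluster is represented by its medoid, the member with the largest mean
similarity to all members of the cluster (itself included), ties broken by
smallest term id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import laplacian
from sklearn.cluster import SpectralClustering

from .semsim import SimilarityMatrix

__all__ = [
    "ClusterAssignment",
    "eigengap_k",
    "spectral_cluster",
    "medoids",
    "DEFAULT_K_MAX",
]

#: cap on the cluster counts scanned by the eigengap search
DEFAULT_K_MAX = 15


@dataclass(frozen=True)
class ClusterAssignment:
    terms: tuple[str, ...]
    labels: tuple[int, ...]  # cluster index per term, 0..k-1
    k: int
    medoids: tuple[str, ...]  # one term id per cluster index
    seed: int

    def __post_init__(self) -> None:
        present = set(self.labels)
        if present != set(range(self.k)):
            raise ValueError("cluster labels must cover 0..k-1 with no gaps")
        if len(self.medoids) != self.k:
            raise ValueError("exactly one medoid per cluster required")
        for c, m in enumerate(self.medoids):
            if self.labels[self.terms.index(m)] != c:
                raise ValueError(f"medoid {m} not in cluster {c}")

    def medoid_flags(self) -> tuple[bool, ...]:
        med = set(self.medoids)
        return tuple(t in med for t in self.terms)


def _check_affinity(sim: SimilarityMatrix, min_n: int) -> np.ndarray:
    a = np.asarray(sim.values, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("affinity must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    if a.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} terms, got {a.shape[0]}")
    return a


def eigengap_k(sim: SimilarityMatrix, k_max: int | None = None) -> int:
    """Eigengap estimate of the cluster count.

    ``k_max`` defaults to min(15, n-1). The spectrum of the symmetric
    normalized Laplacian is computed densely (enriched-term sets are small),
    and the first index of the maximal gap wins ties.
    """
    a = _check_affinity(sim, min_n=3)
    n = a.shape[0]
    if k_max is None:
        k_max = min(DEFAULT_K_MAX, n - 1)
    if not (1 <= k_max <= n - 1):
        raise ValueError(f"k_max must be in [1, {n - 1}], got {k_max}")
    lap = laplacian(a, normed=True)
    eigvals = np.sort(eigh(lap, eigvals_only=True))
    gaps = eigvals[1 : k_max + 1] - eigvals[:k_max]
    return int(np.argmax(gaps)) + 1


def _canonical_relabel(
    terms: tuple[str, ...], raw_labels: np.ndarray
) -> tuple[int, ...]:
    order: dict[int, str] = {}
    for t, lab in zip(terms, raw_labels):
        lab = int(lab)
        if lab not in order or t < order[lab]:
            order[lab] = t
    remap = {
        old: new
        for new, old in enumerate(sorted(order, key=order.__getitem__))
    }
    return tuple(remap[int(l)] for l in raw_labels)


def spectral_cluster(
    sim: SimilarityMatrix, k: int, seed: int = 0
) -> ClusterAssignment:
    """Seeded spectral clustering of the precomputed affinity into k groups."""
    a = _check_affinity(sim, min_n=1)
    n = a.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == 1:
        raw = np.zeros(n, dtype=int)
    elif k == n:
        raw = np.arange(n)
    else:
        model = SpectralClustering(
            n_clusters=k,
            affinity="precomputed",
            random_state=int(seed),
        )
        with warnings.catch_warnings():
            # disconnected affinities (exact block structure) are expected
            warnings.filterwarnings(
                "ignore", message="Graph is not fully connected"
            )
            raw = model.fit_predict(a)
    labels = _canonical_relabel(sim.terms, np.asarray(raw))
    meds = medoids(sim, labels)
    return ClusterAssignment(
        terms=sim.terms, labels=labels, k=k, medoids=meds, seed=int(seed)
    )


def medoids(
    sim: SimilarityMatrix, labels: tuple[int, ...] | list[int]
) -> tuple[str, ...]:
    """Per cluster, the member with the largest mean within-cluster
    similarity (self included); exact ties go to the smallest term id."""
    a = np.asarray(sim.values, dtype=float)
    labels = tuple(int(l) for l in labels)
    k = max(labels) + 1
    out: list[str] = []
    for c in range(k):
        idx = [i for i, l in enumerate(labels) if l == c]
        if not idx:
            raise ValueError(f"cluster {c} is empty")
        sub = a[np.ix_(idx, idx)]
        means = sub.mean(axis=1)
        best = means.max()
        candidates = [sim.terms[idx[j]] for j in range(len(idx))
                      if means[j] >= best - 1e-12]
        out.append(min(candidates))
    return tuple(out)
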