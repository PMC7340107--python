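"""Uniform supervised/unsupervised clustering contracts over a registry of
algorithm adapters.

Supervised algorithms receive the desired partition count n
(labels = S(F, n)); unsupervised algorithms determine the cluster
structure themselves (labels = U(F)) and may legitimately return one
cluster, many more clusters than there are spike classes, or nothing at
all — downstream scoring handles all three regimes.  Euclidean distance
is the metric throughout.

Adapters wrap scikit-learn implementations where they exist; k-medoids
and fuzzy c-means are implemented here directly.  An adapter failure
degrades to an *empty* partition (plus a logged diagnostic) rather than
aborting an evaluation grid.  Density-based adapters label noise points:
if at least one true cluster was found, noise is collected into one
dedicated extra cluster (so accuracy keeps its total-spike denominator);
if everything is noise the partition is empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import (
    DBSCAN,
    OPTICS,
    AffinityPropagation,
    AgglomerativeClustering,
    Birch,
    KMeans,
    MeanShift,
    SpectralClustering,
)
from sklearn.mixture import BayesianGaussianMixture, GaussianMixture

from spikecompat.features import FeatureSet

logger = logging.getLogger(__name__)

SUPERVISED = "supervised"
UNSUPERVISED = "unsupervised"


@dataclass
class AlgorithmSpec:
    """One clustering algorithm plus its parameters and seed."""

    name: str
    mode: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (SUPERVISED, UNSUPERVISED):
            raise ValueError(f"mode must be '{SUPERVISED}' or '{UNSUPERVISED}'")

    def with_seed(self, seed: int) -> "AlgorithmSpec":
        return replace(self, seed=seed)


@dataclass
class Partition:
    """An integer labeling of M points into k clusters.

    Labels are densely re-indexed 1..k on construction so downstream
    scores are invariant to whatever ids the algorithm emitted.  An empty
    partition (k == 0) records that the algorithm produced no clusters.
    """

    labels: np.ndarray
    k: int = -1
    empty: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).ravel().astype(np.int64)
        if self.empty:
            self.labels = np.zeros(len(self.labels), dtype=np.int64)
            self.k = 0
        else:
            uniq, dense = np.unique(self.labels, return_inverse=True)
            self.labels = dense.astype(np.int64) + 1
            self.k = len(uniq)
            if self.k == 0:
                self.empty = True

    @classmethod
    def empty_partition(cls, M: int) -> "Partition":
        return cls(labels=np.zeros(M, dtype=np.int64), empty=True)

    @classmethod
    def from_labels(cls, raw: np.ndarray, noise_label: Optional[int] = None) -> "Partition":
        """Build a partition from raw adapter labels.

        ``noise_label`` (e.g. -1 from DBSCAN/OPTICS) points are pooled into
        one extra cluster; if *all* points are noise the partition is empty.
        """
        raw = np.asarray(raw).ravel()
        if len(raw) == 0:
            return cls.empty_partition(0)
        if noise_label is not None:
            noise = raw == noise_label
            if noise.all():
                return cls.empty_partition(len(raw))
            if noise.any():
                raw = raw.copy()
                raw[noise] = raw.max() + 1
        return cls(labels=raw)

    @property
    def M(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# hand-rolled adapters (no maintained implementation in the dependency set)


def _kmedoids_labels(X: np.ndarray, k: int, seed: int, max_iter: int = 100) -> np.ndarray:
    """Voronoi-iteration k-medoids (PAM-style alternate assignment/update)."""
    rng = np.random.default_rng(seed)
    M = len(X)
    D = cdist(X, X)
    medoids = rng.choice(M, size=k, replace=False)
    for _ in range(max_iter):
        assign = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.nonzero(assign == c)[0]
            if len(members) == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    return np.argmin(D[:, medoids], axis=1)


def _fuzzy_cmeans_labels(
    X: np.ndarray, c: int, seed: int, m: float = 2.0, max_iter: int = 300, tol: float = 1e-6
) -> np.ndarray:
    """Classic fuzzy c-means; memberships hardened by arg-max."""
    rng = np.random.default_rng(seed)
    M = len(X)
    U = rng.random((M, c)) + 1e-9
    U /= U.sum(axis=1, keepdims=True)
    for _ in range(max_iter):
        Um = U**m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        dist = cdist(X, centers) + 1e-12
        inv = dist ** (-2.0 / (m - 1.0))
        U_new = inv / inv.sum(axis=1, keepdims=True)
        if np.abs(U_new - U).max() < tol:
            U = U_new
            break
        U = U_new
    return np.argmax(U, axis=1)


# ---------------------------------------------------------------------------
# registry

_SupervisedFn = Callable[[np.ndarray, int, dict, int], np.ndarray]
_UnsupervisedFn = Callable[[np.ndarray, dict, int], np.ndarray]


def _run_kmeans(X, n, params, seed):
    return KMeans(n_clusters=n, n_init=params.get("n_init", 10), random_state=seed).fit_predict(X)


def _run_kmedoids(X, n, params, seed):
    return _kmedoids_labels(X, n, seed, max_iter=params.get("max_iter", 100))


def _run_agglomerative(X, n, params, seed):
    return AgglomerativeClustering(n_clusters=n, linkage=params.get("linkage", "ward")).fit_predict(X)


def _run_birch(X, n, params, seed):
    return Birch(n_clusters=n, threshold=params.get("threshold", 0.5)).fit_predict(X)


def _run_spectral(X, n, params, seed):
    return SpectralClustering(
        n_clusters=n, random_state=seed, assign_labels=params.get("assign_labels", "kmeans"),
        n_init=params.get("n_init", 10),
    ).fit_predict(X)


def _run_gmm(X, n, params, seed):
    return GaussianMixture(
        n_components=n, random_state=seed, n_init=params.get("n_init", 3),
        covariance_type=params.get("covariance_type", "full"),
    ).fit_predict(X)


def _run_vbgmm(X, n, params, seed):
    return BayesianGaussianMixture(
        n_components=n, random_state=seed, n_init=params.get("n_init", 3),
        covariance_type=params.get("covariance_type", "full"),
        max_iter=params.get("max_iter", 200),
    ).fit_predict(X)


def _run_fcm(X, n, params, seed):
    return _fuzzy_cmeans_labels(X, n, seed, m=params.get("m", 2.0))


def _run_affinity(X, params, seed):
    return AffinityPropagation(random_state=seed, damping=params.get("damping", 0.9)).fit_predict(X)


def _run_meanshift(X, params, seed):
    return MeanShift(bandwidth=params.get("bandwidth")).fit_predict(X)


def _run_dbscan(X, params, seed):
    return DBSCAN(eps=params.get("eps", 0.5), min_samples=params.get("min_samples", 5)).fit_predict(X)


def _run_optics(X, params, seed):
    return OPTICS(min_samples=params.get("min_samples", 5)).fit_predict(X)


_SUPERVISED_ADAPTERS: Dict[str, _SupervisedFn] = {
    "kmeans": _run_kmeans,
    "kmedoids": _run_kmedoids,
    "agglomerative": _run_agglomerative,
    "birch": _run_birch,
    "spectral": _run_spectral,
    "gmm": _run_gmm,
    "vbgmm": _run_vbgmm,
    "fcm": _run_fcm,
}

_UNSUPERVISED_ADAPTERS: Dict[str, _UnsupervisedFn] = {
    "affinity_propagation": _run_affinity,
    "meanshift": _run_meanshift,
    "dbscan": _run_dbscan,
    "optics": _run_optics,
}

#: Density-based adapters that emit -1 noise labels.
_NOISE_LABELLED = {"dbscan", "optics"}


def registry() -> List[AlgorithmSpec]:
    """Default specs for every wrapped algorithm.

    Further algorithms from the spike-sorting literature (SPC, Chameleon,
    CURE, ROCK, CAST, ISO-SPLIT, Klustakwik, DIANA, and the
    protein-interaction graph clusterers) have no maintained
    implementation in this dependency set; they can be added by
    registering an adapter with :func:`register_adapter`.
    """
    specs = [AlgorithmSpec(name=n, mode=SUPERVISED) for n in _SUPERVISED_ADAPTERS]
    specs += [AlgorithmSpec(name=n, mode=UNSUPERVISED) for n in _UNSUPERVISED_ADAPTERS]
    return specs


def get_spec(name: str) -> AlgorithmSpec:
    """Look up a registry spec by name; unknown names list the alternatives."""
    for spec in registry():
        if spec.name == name:
            return spec
    available = sorted(list(_SUPERVISED_ADAPTERS) + list(_UNSUPERVISED_ADAPTERS))
    raise KeyError(f"unknown algorithm {name!r}; available: {available}")


def register_adapter(name: str, mode: str, fn) -> None:
    """Register an external adapter (supervised: fn(X, n, params, seed),
    unsupervised: fn(X, params, seed); both return raw integer labels)."""
    if mode == SUPERVISED:
        _SUPERVISED_ADAPTERS[name] = fn
    elif mode == UNSUPERVISED:
        _UNSUPERVISED_ADAPTERS[name] = fn
    else:
        raise ValueError(f"mode must be '{SUPERVISED}' or '{UNSUPERVISED}'")


def run_supervised(spec: AlgorithmSpec, fs: FeatureSet, n: int) -> Partition:
    """labels = S(F, n): cluster with a user-specified partition count.

    Returns a partition with k <= n clusters, deterministic given
    spec.seed.  Adapter failures degrade to an empty partition.
    """
    if spec.mode != SUPERVISED:
        raise ValueError(f"{spec.name} is not a supervised algorithm")
    if n < 1:
        raise ValueError("partition count n must be >= 1")
    if n == 1:
        return Partition(labels=np.ones(fs.M, dtype=np.int64))
    adapter = _SUPERVISED_ADAPTERS.get(spec.name)
    if adapter is None:
        raise KeyError(f"unknown supervised algorithm {spec.name!r}; available: {sorted(_SUPERVISED_ADAPTERS)}")
    try:
        raw = adapter(fs.matrix, n, spec.params, spec.seed)
    except Exception:  # noqa: BLE001 - grid runs must survive adapter failures
        logger.exception("adapter %s failed on feature-set %s; returning empty partition", spec.name, fs.label)
        return Partition.empty_partition(fs.M)
    return Partition.from_labels(raw)


def run_unsupervised(spec: AlgorithmSpec, fs: FeatureSet) -> Partition:
    """labels = U(F): the algorithm determines the cluster structure itself."""
    if spec.mode != UNSUPERVISED:
        raise ValueError(f"{spec.name} is not an unsupervised algorithm")
    adapter = _UNSUPERVISED_ADAPTERS.get(spec.name)
    if adapter is None:
        raise KeyError(f"unknown unsupervised algorithm {spec.name!r}; available: {sorted(_UNSUPERVISED_ADAPTERS)}")
    try:
        raw = adapter(fs.matrix, spec.params, spec.seed)
    except Exception:  # noqa: BLE001
        logger.exception("adapter %s failed on feature-set %s; returning empty partition", spec.name, fs.label)
        return Partition.empty_partition(fs.M)
    noise = -1 if spec.name in _NOISE_LABELLED else None
    return Partition.from_labels(raw, noise_label=noise)


def run(spec: AlgorithmSpec, fs: FeatureSet, n: Optional[int] = None) -> Partition:
    """Dispatch on spec.mode (supervised needs ``n``)."""
    if spec.mode == SUPERVISED:
        if n is None:
            raise ValueError(f"supervised algorithm {spec.name} requires a partition count n")
        return run_supervised(spec, fs, n)
    return run_unsupervised(spec, fs)
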