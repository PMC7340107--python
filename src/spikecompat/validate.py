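"""The scoring stack: best-match confusion matrix, accuracy, external and
internal validity indices, NII normalization, inverted-RMSE consistency
ranking, compatibility categories, and the index-consistency diagnostic.

A clustering result is judged along two complementary axes.  *External*
indices (Rand, Jaccard) and accuracy compare the labeling against ground
truth.  *Internal* indices (Davies-Bouldin, Ball-Hall, Trace-W) look only
at the geometry of the clusters in feature space; to make them comparable
across criteria and feature-sets they are rescaled into normalized
internal indices (NII) relative to the ground-truth value r:

    NII(i) = 1 - |r - i| / (max(I) - min(I)),

the range taken over all observed values plus r, so NII is in [0, 1] and
the ground-truth partition scores exactly 1.  An algorithm's consistency
across all feature-sets is one minus the root-mean-squared deviation of
its external indices from the ideal value 1 (the "inverted RMSE"); ranks
on that score map to six compatibility categories.  Low variance among
the three NII values for one algorithm-featureset pair ("index
consistency") marks a compatible algorithm; high variance flags an
incompatible one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import comb

from spikecompat.cluster import (
    SUPERVISED,
    AlgorithmSpec,
    Partition,
    run_supervised,
    run_unsupervised,
)
from spikecompat.features import FeatureSet

logger = logging.getLogger(__name__)

GROUND_TRUTH = "ground-truth"
EXTERNAL_CRITERIA = ("rand", "jaccard", "accuracy")
INTERNAL_CRITERIA = ("DB", "BH", "TrW")
CATEGORIES = ("ideal", "most-compatible", "compatible", "average", "least-compatible", "non-compatible")

LabelsLike = Union[np.ndarray, Sequence[int], Partition]


def _as_partition_labels(partition: LabelsLike) -> Tuple[np.ndarray, bool]:
    """Return (labels, empty) from a Partition or a raw label vector."""
    if isinstance(partition, Partition):
        return partition.labels, partition.empty
    labels = np.asarray(partition).ravel().astype(np.int64)
    return labels, len(labels) == 0


def _check_lengths(gt: np.ndarray, labels: np.ndarray) -> None:
    if len(gt) != len(labels):
        raise ValueError(f"length mismatch: {len(gt)} ground-truth vs {len(labels)} cluster labels")


@dataclass
class ConfusionMatrix:
    """L x L best-match count table (rows = ground-truth classes,
    columns = the classes whose matched clusters received the spikes)."""

    counts: np.ndarray
    mapping: Dict[int, int]  # ground-truth class -> matched cluster label
    discarded: int
    class_ids: np.ndarray

    @property
    def L(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        idx = [f"class_{c}" for c in self.class_ids]
        return pd.DataFrame(self.counts, index=idx, columns=idx)


def match_confusion_matrix(gt_labels: np.ndarray, partition: LabelsLike) -> ConfusionMatrix:
    """Build the best-match confusion matrix between classes and clusters.

    Classes and clusters are matched one-to-one, greedily by descending
    co-occurrence count (ties: lower class label, then lower cluster
    label), so each matched cluster "is" its class and true matches
    occupy the diagonal.  A class's spikes landing in a *different
    matched* cluster fill the off-diagonal cell of that cluster's class;
    spikes in unmatched clusters (an algorithm that produced too many
    clusters) cannot be placed in the L x L table and are counted in
    ``discarded``.  An empty partition yields the all-zero matrix.

    Set ``match_confusion_matrix.optimal = True``-style behavior via
    :func:`optimal_confusion_matrix` for the exhaustive-assignment variant.
    """
    gt = np.asarray(gt_labels).ravel().astype(np.int64)
    labels, empty = _as_partition_labels(partition)
    if not empty:
        _check_lengths(gt, labels)
    classes = np.unique(gt)
    L = len(classes)
    if empty:
        return ConfusionMatrix(
            counts=np.zeros((L, L), dtype=np.int64), mapping={}, discarded=0, class_ids=classes
        )
    clusters = np.unique(labels)
    class_pos = {c: i for i, c in enumerate(classes)}
    cluster_pos = {c: j for j, c in enumerate(clusters)}
    cont = np.zeros((L, len(clusters)), dtype=np.int64)
    for g, c in zip(gt, labels):
        cont[class_pos[g], cluster_pos[c]] += 1
    # Greedy one-to-one best match.  Ties are broken by the lower class
    # label, then by the cluster's full per-class count column (a
    # label-invariant signature), then by the cluster label itself: scores
    # must not change when cluster ids are permuted, and clusters with
    # identical columns are genuinely interchangeable.
    candidates = [
        (cont[i, j], classes[i], tuple(cont[:, j]), clusters[j])
        for i in range(L)
        for j in range(len(clusters))
        if cont[i, j] > 0
    ]
    candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    mapping: Dict[int, int] = {}
    used_clusters: set = set()
    for count, cls, _sig, clu in candidates:
        if cls in mapping or clu in used_clusters:
            continue
        mapping[cls] = clu
        used_clusters.add(clu)
    cluster_to_class = {clu: cls for cls, clu in mapping.items()}
    counts = np.zeros((L, L), dtype=np.int64)
    discarded = 0
    for i, cls in enumerate(classes):
        for j, clu in enumerate(clusters):
            n = cont[i, j]
            if n == 0:
                continue
            if clu in cluster_to_class:
                counts[i, class_pos[cluster_to_class[clu]]] += n
            else:
                discarded += n
    return ConfusionMatrix(counts=counts, mapping=mapping, discarded=int(discarded), class_ids=classes)


def optimal_confusion_matrix(gt_labels: np.ndarray, partition: LabelsLike) -> ConfusionMatrix:
    """Best-match confusion matrix with the exhaustive optimal (Hungarian)
    class-cluster assignment instead of the greedy one."""
    from scipy.optimize import linear_sum_assignment

    gt = np.asarray(gt_labels).ravel().astype(np.int64)
    labels, empty = _as_partition_labels(partition)
    classes = np.unique(gt)
    L = len(classes)
    if empty:
        return ConfusionMatrix(
            counts=np.zeros((L, L), dtype=np.int64), mapping={}, discarded=0, class_ids=classes
        )
    _check_lengths(gt, labels)
    clusters = np.unique(labels)
    class_pos = {c: i for i, c in enumerate(classes)}
    cluster_pos = {c: j for j, c in enumerate(clusters)}
    cont = np.zeros((L, len(clusters)), dtype=np.int64)
    for g, c in zip(gt, labels):
        cont[class_pos[g], cluster_pos[c]] += 1
    rows, cols = linear_sum_assignment(cont, maximize=True)
    mapping = {int(classes[i]): int(clusters[j]) for i, j in zip(rows, cols) if cont[i, j] > 0}
    cluster_to_class = {clu: cls for cls, clu in mapping.items()}
    counts = np.zeros((L, L), dtype=np.int64)
    discarded = 0
    for i in range(L):
        for j in range(len(clusters)):
            n = cont[i, j]
            if n == 0:
                continue
            clu = clusters[j]
            if clu in cluster_to_class:
                counts[i, class_pos[cluster_to_class[clu]]] += n
            else:
                discarded += n
    return ConfusionMatrix(counts=counts, mapping=mapping, discarded=int(discarded), class_ids=classes)


def accuracy(cm: ConfusionMatrix, M: int) -> float:
    """Percent of all M spikes sorted without confusion: 100 * tr(ConfM) / M.

    The denominator is the total spike count, not the matrix total, so
    spikes discarded into unmatched clusters still count against the
    algorithm.
    """
    if M <= 0:
        raise ValueError("M must be positive")
    return 100.0 * float(np.trace(cm.counts)) / M


def _pair_counts(gt: np.ndarray, labels: np.ndarray) -> Tuple[float, float, float, float]:
    """(TP, FP, FN, total_pairs) from the contingency table."""
    classes, gt_idx = np.unique(gt, return_inverse=True)
    clusters, cl_idx = np.unique(labels, return_inverse=True)
    cont = np.zeros((len(classes), len(clusters)), dtype=np.int64)
    np.add.at(cont, (gt_idx, cl_idx), 1)
    n = len(gt)
    tp = comb(cont, 2).sum()
    same_gt = comb(cont.sum(axis=1), 2).sum()
    same_cl = comb(cont.sum(axis=0), 2).sum()
    total = comb(n, 2)
    return float(tp), float(same_cl - tp), float(same_gt - tp), float(total)


def rand_index(gt_labels: np.ndarray, partition: LabelsLike) -> float:
    """Pair-counting Rand index in [0, 1]; an empty partition scores 0
    (the worst case, an algorithm that produced no clusters)."""
    gt = np.asarray(gt_labels).ravel().astype(np.int64)
    labels, empty = _as_partition_labels(partition)
    if empty:
        return 0.0
    _check_lengths(gt, labels)
    if len(gt) < 2:
        raise ValueError("Rand index needs at least 2 points")
    tp, fp, fn, total = _pair_counts(gt, labels)
    tn = total - tp - fp - fn
    return (tp + tn) / total


def jaccard_index(gt_labels: np.ndarray, partition: LabelsLike) -> float:
    """Pair-counting Jaccard index TP / (TP + FP + FN) in [0, 1].

    Returns 0 (with a "no index produced" warning) for an empty partition
    or when no pair falls in any of TP/FP/FN — the benchmark convention
    for algorithms that fail to produce a usable result.
    """
    gt = np.asarray(gt_labels).ravel().astype(np.int64)
    labels, empty = _as_partition_labels(partition)
    if empty:
        warnings.warn("empty partition: no Jaccard index produced, reporting 0", stacklevel=2)
        return 0.0
    _check_lengths(gt, labels)
    if len(gt) < 2:
        raise ValueError("Jaccard index needs at least 2 points")
    tp, fp, fn, _ = _pair_counts(gt, labels)
    denom = tp + fp + fn
    if denom == 0:
        warnings.warn("degenerate pair counts: no Jaccard index produced, reporting 0", stacklevel=2)
        return 0.0
    return tp / denom


# ---------------------------------------------------------------------------
# internal indices


def _feature_matrix(fs: Union[FeatureSet, np.ndarray]) -> np.ndarray:
    return fs.matrix if isinstance(fs, FeatureSet) else np.atleast_2d(np.asarray(fs, dtype=float))


def _cluster_members(labels: np.ndarray) -> List[np.ndarray]:
    return [np.nonzero(labels == c)[0] for c in np.unique(labels)]


def _require_nonempty(partition: LabelsLike, X: np.ndarray) -> np.ndarray:
    labels, empty = _as_partition_labels(partition)
    if empty:
        raise ValueError("internal index undefined for an empty partition")
    if len(labels) != len(X):
        raise ValueError(f"length mismatch: {len(labels)} labels vs {len(X)} points")
    return labels


def ball_hall(fs: Union[FeatureSet, np.ndarray], partition: LabelsLike) -> float:
    """Ball-Hall index: mean over clusters of the mean squared Euclidean
    distance from members to their cluster barycentre."""
    X = _feature_matrix(fs)
    labels = _require_nonempty(partition, X)
    per_cluster = []
    for members in _cluster_members(labels):
        pts = X[members]
        center = pts.mean(axis=0)
        per_cluster.append(float(np.mean(np.sum((pts - center) ** 2, axis=1))))
    return float(np.mean(per_cluster))


def trace_w(fs: Union[FeatureSet, np.ndarray], partition: LabelsLike) -> float:
    """Trace of the pooled within-cluster scatter matrix: the sum over all
    points of the squared Euclidean distance to their cluster barycentre.
    Unnormalized, so it grows with the spike count M."""
    X = _feature_matrix(fs)
    labels = _require_nonempty(partition, X)
    total = 0.0
    for members in _cluster_members(labels):
        pts = X[members]
        center = pts.mean(axis=0)
        total += float(np.sum((pts - center) ** 2))
    return total


def davies_bouldin(fs: Union[FeatureSet, np.ndarray], partition: LabelsLike) -> float:
    """Davies-Bouldin index (lower is better): mean over clusters of the
    worst ratio (delta_c + delta_c') / d(center_c, center_c'), with delta
    the mean member-to-centroid Euclidean distance.

    Requires k >= 2 clusters and pairwise distinct centroids.
    """
    X = _feature_matrix(fs)
    labels = _require_nonempty(partition, X)
    members = _cluster_members(labels)
    k = len(members)
    if k < 2:
        raise ValueError(f"Davies-Bouldin requires at least 2 clusters, got {k}")
    centers = np.stack([X[m].mean(axis=0) for m in members])
    deltas = np.array([float(np.mean(np.linalg.norm(X[m] - centers[i], axis=1))) for i, m in enumerate(members)])
    center_dist = cdist(centers, centers)
    if np.any(center_dist[~np.eye(k, dtype=bool)] == 0):
        raise ValueError("coincident cluster centroids: Davies-Bouldin undefined")
    ratios = np.zeros(k)
    for i in range(k):
        r = [(deltas[i] + deltas[j]) / center_dist[i, j] for j in range(k) if j != i]
        ratios[i] = max(r)
    return float(np.mean(ratios))


def normalize_internal(values: Mapping[str, float], reference: float) -> Dict[str, float]:
    """NII rescaling of one (criterion, feature-set) column of raw indices.

    NII(i) = 1 - |r - i| / (max(I) - min(I)), with the reference value r
    (the ground-truth index) included in the range set I so that every
    score lands in [0, 1] and the ground truth scores exactly 1.  When the
    range degenerates (all values equal), scores are 1 where i == r and 0
    otherwise.
    """
    if len(values) == 0:
        raise ValueError("no index values to normalize")
    finite = {k: v for k, v in values.items() if np.isfinite(v)}
    pool = np.asarray(list(finite.values()) + [reference], dtype=float)
    span = float(pool.max() - pool.min())
    out: Dict[str, float] = {}
    for name, v in values.items():
        if not np.isfinite(v):
            out[name] = float("nan")
        elif span == 0:
            out[name] = 1.0 if v == reference else 0.0
        else:
            out[name] = 1.0 - abs(reference - v) / span
    return out


@dataclass
class ConsistencyScore:
    """Cross-feature-set consistency of one algorithm's external indices."""

    algorithm: str
    rmse: float
    inverted: float
    n_feature_sets: int
    external: Dict[str, float] = field(default_factory=dict)  # feature-set label -> e
    category: Optional[str] = None


def inverted_rmse(
    e: Sequence[float],
    targets: Optional[Sequence[float]] = None,
) -> Tuple[float, float]:
    """(rmse, inverted) for one algorithm's external indices across
    feature-sets: rmse = sqrt(mean((g - e)^2)) against the ideal targets
    g = 1, inverted = 1 - rmse."""
    e = np.asarray(e, dtype=float)
    g = np.ones_like(e) if targets is None else np.asarray(targets, dtype=float)
    if e.shape != g.shape:
        raise ValueError(f"length mismatch: {e.shape} indices vs {g.shape} targets")
    if np.any((e < 0) | (e > 1)):
        raise ValueError("external indices must lie in [0, 1]")
    rmse = float(np.sqrt(np.mean((g - e) ** 2)))
    return rmse, 1.0 - rmse


def categorize(
    inverted_scores: Mapping[str, float],
    *,
    ground_truth: str = GROUND_TRUTH,
    scheme: str = "quintile",
    thresholds: Optional[Sequence[float]] = None,
) -> Dict[str, str]:
    """Map inverted-RMSE scores to the six compatibility categories.

    The ground-truth pseudo-algorithm is always "ideal".  The remaining
    algorithms are ranked by descending score and binned into the five
    other categories, by rank quintiles (default) or by fixed descending
    ``thresholds`` (5 values; score >= thresholds[j] lands in category j+1).
    """
    out: Dict[str, str] = {}
    rest = {a: s for a, s in inverted_scores.items() if a != ground_truth}
    if ground_truth in inverted_scores:
        out[ground_truth] = CATEGORIES[0]
    if not rest:
        return out
    if scheme == "thresholds":
        if thresholds is None or len(thresholds) != 5:
            raise ValueError("thresholds scheme needs 5 descending cut-offs")
        for a, s in rest.items():
            cat = CATEGORIES[5]
            for j, cut in enumerate(thresholds):
                if s >= cut:
                    cat = CATEGORIES[j + 1]
                    break
            out[a] = cat
        return out
    if scheme != "quintile":
        raise ValueError(f"unknown binning scheme {scheme!r}")
    ranked = sorted(rest.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(ranked)
    for rank, (a, _s) in enumerate(ranked):
        out[a] = CATEGORIES[1 + (rank * 5) // n]
    return out


def index_consistency(nii: Sequence[float]) -> float:
    """Population variance of the three NII values (DB, BH, TrW) for one
    algorithm-featureset pair.  Low variance marks a compatible algorithm;
    a missing (NaN) criterion flags the diagnostic as absent (NaN)."""
    nii = np.asarray(nii, dtype=float)
    if nii.shape != (3,):
        raise ValueError(f"need exactly 3 NII values, got {nii.shape}")
    if np.any(~np.isfinite(nii)):
        warnings.warn("missing NII criterion: consistency diagnostic flagged absent", stacklevel=2)
        return float("nan")
    return float(np.var(nii))


SELECTION_RULES = (
    "minimum",
    "maximum",
    "max_second_difference",
    "min_second_difference",
    "max_difference_left",
)

#: Default partition-selection rule per internal criterion.
DEFAULT_SELECTION_RULES = {"DB": "minimum", "BH": "max_second_difference", "TrW": "max_second_difference"}


def select_partition(index_series: Mapping[int, float], rule: str) -> int:
    """Choose a partition count from an internal-index series.

    ``index_series`` maps candidate partition counts to index values.
    Second-difference rules need at least 3 candidates and score interior
    points by s[i-1] - 2 s[i] + s[i+1]; "max_difference_left" scores
    points from the second onward by s[i-1] - s[i].  Ties resolve to the
    smaller partition count.
    """
    if rule not in SELECTION_RULES:
        raise ValueError(f"unknown rule {rule!r}; available: {list(SELECTION_RULES)}")
    counts = np.asarray(sorted(index_series), dtype=np.int64)
    values = np.asarray([index_series[c] for c in counts], dtype=float)
    if rule in ("minimum", "maximum"):
        if len(counts) < 1:
            raise ValueError("empty index series")
        score = -values if rule == "minimum" else values
        return int(counts[int(np.argmax(score))])  # argmax is first-of-ties -> smaller count
    if rule == "max_difference_left":
        if len(counts) < 2:
            raise ValueError("max_difference_left needs at least 2 candidates")
        diffs = values[:-1] - values[1:]
        return int(counts[1 + int(np.argmax(diffs))])
    if len(counts) < 3:
        raise ValueError(f"{rule} needs at least 3 candidates")
    second = values[:-2] - 2 * values[1:-1] + values[2:]
    score = second if rule == "max_second_difference" else -second
    return int(counts[1 + int(np.argmax(score))])


# ---------------------------------------------------------------------------
# grid evaluation


@dataclass
class ScoreTable:
    """Long-format algorithm x feature-set x criterion score grid.

    ``scores`` columns: algorithm, featureset, criterion, raw, normalized
    (NII, internal criteria only), reference (ground-truth raw value), flag.
    ``consistency``: one row per algorithm (rmse, inverted, category).
    ``nii_variance``: the index-consistency diagnostic per pair.
    """

    scores: pd.DataFrame
    consistency: pd.DataFrame
    nii_variance: pd.DataFrame
    metadata: dict = field(default_factory=dict)


@dataclass
class EvalConfig:
    """Grid-evaluation settings.

    n_partitions: partition count handed to supervised algorithms, either
    one integer for all feature-sets or a mapping from feature-set label
    (3 for the synthetic testbeds, 4 for the real one).  rmse_criteria:
    which external indices enter the inverted-RMSE consistency score
    (Rand only by default; Jaccard can fail to produce values).
    """

    n_partitions: Union[int, Mapping[str, int]] = 3
    rmse_criteria: Tuple[str, ...] = ("rand",)
    binning: str = "quintile"
    thresholds: Optional[Sequence[float]] = None
    include_ground_truth: bool = True
    matching: str = "greedy"  # or "optimal"

    def n_for(self, label: str) -> int:
        if isinstance(self.n_partitions, int):
            return self.n_partitions
        return self.n_partitions.get(label, self.n_partitions.get("default", 3))


@dataclass
class EvaluationResult:
    table: ScoreTable
    confusion: Dict[Tuple[str, str], ConfusionMatrix]
    partitions: Dict[Tuple[str, str], Partition]
    consistency_scores: List[ConsistencyScore]


def _score_partition(
    fs: FeatureSet, partition: Partition, config: EvalConfig
) -> Tuple[Dict[str, float], Dict[str, str], ConfusionMatrix]:
    """Raw external + internal scores for one (algorithm, feature-set) cell."""
    gt = fs.gt_labels
    matcher = optimal_confusion_matrix if config.matching == "optimal" else match_confusion_matrix
    cm = matcher(gt, partition)
    raw: Dict[str, float] = {}
    flags: Dict[str, str] = {}
    raw["rand"] = rand_index(gt, partition)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        raw["jaccard"] = jaccard_index(gt, partition)
    if caught:
        flags["jaccard"] = "no-index"
    raw["accuracy"] = accuracy(cm, fs.M)
    for crit, fn in (("DB", davies_bouldin), ("BH", ball_hall), ("TrW", trace_w)):
        try:
            raw[crit] = fn(fs, partition)
        except ValueError as exc:
            raw[crit] = float("nan")
            flags[crit] = f"undefined: {exc}"
    return raw, flags, cm


def evaluate_all(
    feature_sets: Sequence[FeatureSet],
    specs: Sequence[AlgorithmSpec],
    config: Optional[EvalConfig] = None,
) -> EvaluationResult:
    """Run every algorithm on every feature-set and score the full grid.

    The ground-truth labeling is scored as a pseudo-algorithm (the "ideal"
    row: Rand 1, accuracy 100, NII 1,1,1).  Individual algorithm failures
    degrade to empty-partition scores; they never abort the grid.
    Deterministic given the specs' seeds.
    """
    config = config or EvalConfig()
    for fs in feature_sets:
        if fs.gt_labels is None:
            raise ValueError(f"feature-set {fs.label!r} carries no ground truth")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate algorithm names in spec list")

    partitions: Dict[Tuple[str, str], Partition] = {}
    confusion: Dict[Tuple[str, str], ConfusionMatrix] = {}
    raw_scores: Dict[Tuple[str, str], Dict[str, float]] = {}
    flags: Dict[Tuple[str, str], Dict[str, str]] = {}

    algorithms = list(names)
    if config.include_ground_truth:
        algorithms = [GROUND_TRUTH] + algorithms

    for fs in feature_sets:
        if config.include_ground_truth:
            part = Partition(labels=fs.gt_labels)
            key = (GROUND_TRUTH, fs.label)
            raw_scores[key], flags[key], confusion[key] = _score_partition(fs, part, config)
            partitions[key] = part
        for spec in specs:
            if spec.mode == SUPERVISED:
                part = run_supervised(spec, fs, config.n_for(fs.label))
            else:
                part = run_unsupervised(spec, fs)
            key = (spec.name, fs.label)
            partitions[key] = part
            raw_scores[key], flags[key], confusion[key] = _score_partition(fs, part, config)
            if part.empty:
                flags[key]["partition"] = "empty-partition"

    # NII normalization per (criterion, feature-set), reference = ground truth
    normalized: Dict[Tuple[str, str, str], float] = {}
    if config.include_ground_truth:
        for fs in feature_sets:
            for crit in INTERNAL_CRITERIA:
                column = {a: raw_scores[(a, fs.label)][crit] for a in algorithms}
                r = column[GROUND_TRUTH]
                if not np.isfinite(r):
                    continue
                nii = normalize_internal(column, r)
                for a, v in nii.items():
                    normalized[(a, fs.label, crit)] = v

    rows = []
    for fs in feature_sets:
        for a in algorithms:
            key = (a, fs.label)
            for crit in EXTERNAL_CRITERIA + INTERNAL_CRITERIA:
                ref = raw_scores[(GROUND_TRUTH, fs.label)][crit] if config.include_ground_truth else float("nan")
                rows.append(
                    {
                        "algorithm": a,
                        "featureset": fs.label,
                        "criterion": crit,
                        "raw": raw_scores[key][crit],
                        "normalized": normalized.get((a, fs.label, crit), float("nan")),
                        "reference": ref if crit in INTERNAL_CRITERIA else float("nan"),
                        "flag": flags[key].get(crit, ""),
                    }
                )
    scores = pd.DataFrame(rows, columns=["algorithm", "featureset", "criterion", "raw", "normalized", "reference", "flag"])

    # inverted-RMSE consistency across feature-sets
    consistency_scores: List[ConsistencyScore] = []
    inverted_by_alg: Dict[str, float] = {}
    for a in algorithms:
        e: List[float] = []
        external: Dict[str, float] = {}
        for fs in feature_sets:
            vals = [raw_scores[(a, fs.label)][c] for c in config.rmse_criteria]
            e.extend(vals)
            external[fs.label] = float(np.mean(vals))
        rmse, inverted = inverted_rmse(e)
        inverted_by_alg[a] = inverted
        consistency_scores.append(
            ConsistencyScore(
                algorithm=a, rmse=rmse, inverted=inverted, n_feature_sets=len(feature_sets), external=external
            )
        )
    categories = categorize(inverted_by_alg, scheme=config.binning, thresholds=config.thresholds)
    for cs in consistency_scores:
        cs.category = categories.get(cs.algorithm)

    consistency = pd.DataFrame(
        [
            {
                "algorithm": cs.algorithm,
                "rmse": cs.rmse,
                "inverted": cs.inverted,
                "n_feature_sets": cs.n_feature_sets,
                "category": cs.category,
            }
            for cs in consistency_scores
        ],
        columns=["algorithm", "rmse", "inverted", "n_feature_sets", "category"],
    )

    nii_rows = []
    for fs in feature_sets:
        for a in algorithms:
            triple = [normalized.get((a, fs.label, crit), float("nan")) for crit in INTERNAL_CRITERIA]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                var = index_consistency(triple) if len(triple) == 3 else float("nan")
            nii_rows.append({"algorithm": a, "featureset": fs.label, "variance": var})
    nii_variance = pd.DataFrame(nii_rows, columns=["algorithm", "featureset", "variance"])

    metadata = {
        "algorithms": algorithms,
        "feature_sets": [fs.label for fs in feature_sets],
        "seeds": {s.name: s.seed for s in specs},
        "n_partitions": {fs.label: config.n_for(fs.label) for fs in feature_sets},
        "rmse_criteria": list(config.rmse_criteria),
        "matching": config.matching,
        "binning": config.binning,
        "flags": {f"{a}|{f}": fl for (a, f), fl in flags.items() if fl},
        "discarded": {f"{a}|{f}": cm.discarded for (a, f), cm in confusion.items() if cm.discarded},
    }
    table = ScoreTable(scores=scores, consistency=consistency, nii_variance=nii_variance, metadata=metadata)
    return EvaluationResult(
        table=table, confusion=confusion, partitions=partitions, consistency_scores=consistency_scores
    )
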