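"""Downstream analyses on Sholl pseudo-metrics.

Detection rates (how well a single descriptor isolates one class inside
a ball of its pseudo-metric), grid-search combination of several
descriptor metrics, fixed-length vectorization of descriptor functions,
hierarchical clustering, large-margin nearest-neighbor (LMNN) metric
learning with a KNN cross-validation protocol, and empirical stability
probes of the descriptors under coordinate jitter.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.utils.validation import check_is_fitted, validate_data

from .descriptors import ShollFunction, compute_descriptor
from .metrics import DistanceMatrix, function_distance, sholl_tmd_distance
from .neuron import Neuron

__all__ = [
    "DetectionResult",
    "CombinationResult",
    "AccuracyReport",
    "ClusterResult",
    "LMNN",
    "detection_rate",
    "score_ball",
    "combine_distances",
    "vectorize",
    "feature_table",
    "DEFAULT_VECTOR_DESCRIPTORS",
    "hierarchical_cluster",
    "learn_metric",
    "classify_with_cv",
    "stability_probe",
]


def _align_labels(ids: Sequence[str], labels) -> np.ndarray:
    """Labels as an array aligned with ``ids`` (dict/Series or sequence)."""
    if isinstance(labels, Mapping):
        missing = [i for i in ids if i not in labels]
        if missing:
            raise ValueError(f"labels missing for ids {missing}")
        return np.asarray([labels[i] for i in ids], dtype=object)
    if isinstance(labels, pd.Series):
        return _align_labels(ids, labels.to_dict())
    arr = np.asarray(labels, dtype=object)
    if len(arr) != len(ids):
        raise ValueError(f"{len(arr)} labels for {len(ids)} ids")
    return arr


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectionResult:
    """Best min(recall, precision) ball for one class under one metric."""

    label: object
    rate: float  # percentage in [0, 100]
    center_id: str
    radius: float
    member_ids: tuple[str, ...]


def score_ball(
    D: DistanceMatrix, labels, target_label, center_id: str, radius: float
) -> float:
    """min(recall, precision) of the closed ball, as a percentage.

    Independent re-scoring of a detection witness: recomputes class
    recall and ball purity directly from the matrix row.
    """
    y = _align_labels(D.ids, labels)
    ci = D.ids.index(center_id)
    inside = D.matrix[ci] <= radius
    n_target = int(np.sum(y == target_label))
    hits = int(np.sum(inside & (y == target_label)))
    if inside.sum() == 0 or n_target == 0:
        return 0.0
    recall = hits / n_target
    precision = hits / int(inside.sum())
    return 100.0 * min(recall, precision)


def detection_rate(D: DistanceMatrix, labels, target_label) -> DetectionResult:
    """Maximal detection rate for a class under a descriptor pseudo-metric.

    Searches exhaustively over every dataset point as the ball center
    and every distinct distance from that center as the radius, scoring
    each closed ball with 100 * min(recall, precision) for the target
    label, and returns the maximum with its witness ball.  A rate of
    100 means some ball contains the entire class and nothing else.
    """
    y = _align_labels(D.ids, labels)
    if target_label not in set(y):
        raise ValueError(f"label {target_label!r} not present")
    n = len(D)
    n_target = int(np.sum(y == target_label))
    is_target = (y == target_label).astype(int)
    best = (-1.0, 0, 0.0)  # score, center index, radius
    for ci in range(n):
        row = D.matrix[ci]
        order = np.argsort(row, kind="stable")
        sorted_d = row[order]
        hits = np.cumsum(is_target[order])
        members = np.arange(1, n + 1)
        # closed balls: a radius tied across several points includes all of
        # them, so only the last index of each tie group is a valid ball
        last_of_group = np.append(sorted_d[1:] != sorted_d[:-1], True)
        recall = hits / n_target
        precision = hits / members
        scores = np.minimum(recall, precision)
        scores[~last_of_group] = -1.0
        k = int(np.argmax(scores))
        if scores[k] > best[0]:
            best = (float(scores[k]), ci, float(sorted_d[k]))
    score, ci, radius = best
    inside = D.matrix[ci] <= radius
    return DetectionResult(
        label=target_label,
        rate=100.0 * score,
        center_id=D.ids[ci],
        radius=radius,
        member_ids=tuple(np.asarray(D.ids)[inside]),
    )


# --------------------------------------------------------------------------
# combination with weights
# --------------------------------------------------------------------------


@dataclass
class CombinationResult:
    """Optimal simplex-grid combination of descriptor distance matrices."""

    weights: tuple[float, ...]
    combined: DistanceMatrix
    objective: float
    descriptor_names: tuple[str, ...]


def _simplex_grid(n: int, k: int):
    """All nonnegative integer compositions of k into n parts, lexicographic."""
    for cuts in itertools.combinations(range(k + n - 1), n - 1):
        parts = []
        prev = -1
        for c in cuts:
            parts.append(c - prev - 1)
            prev = c
        parts.append(k + n - 2 - prev)
        yield tuple(parts)


def combine_distances(
    matrices: Sequence[DistanceMatrix], labels, grid_step: float = 0.1
) -> CombinationResult:
    """Grid-search a convex combination of normalized distance matrices.

    Each matrix is normalized by its mean off-diagonal entry, then the
    weights alpha (nonnegative, summing to 1, stepped on an equispaced
    simplex grid) maximize the ratio of the mean inter-class to the mean
    intra-class combined distance.  Since the objective is a ratio of
    two linear functions of alpha, per-matrix inter/intra means are
    precomputed and each grid point costs O(n_matrices).  Ties resolve
    to the lexicographically smallest weight vector.
    """
    if not matrices:
        raise ValueError("need at least one distance matrix")
    ids = matrices[0].ids
    for m in matrices[1:]:
        if m.ids != ids:
            raise ValueError("all matrices must share the same ids in order")
    y = _align_labels(ids, labels)
    if len(set(y)) < 2:
        raise ValueError("combination objective undefined for a single class")
    k = round(1.0 / grid_step)
    if abs(k * grid_step - 1.0) > 1e-9:
        raise ValueError(f"grid_step {grid_step} must divide 1")

    n = len(ids)
    iu = np.triu_indices(n, k=1)
    same = (y[:, None] == y[None, :])[iu]
    normed = []
    inter = np.empty(len(matrices))
    intra = np.empty(len(matrices))
    for i, m in enumerate(matrices):
        off = m.matrix[iu]
        scale = off.mean()
        nm = m.matrix / scale if scale > 0 else m.matrix.copy()
        normed.append(nm)
        offn = nm[iu]
        inter[i] = offn[~same].mean()
        intra[i] = offn[same].mean()

    best_alpha: tuple[float, ...] | None = None
    best_obj = -np.inf
    for comp in _simplex_grid(len(matrices), k):
        alpha = np.array(comp, dtype=float) / k
        num = float(alpha @ inter)
        den = float(alpha @ intra)
        obj = np.inf if den == 0 and num > 0 else (1.0 if den == 0 else num / den)
        if obj > best_obj:
            best_obj = obj
            best_alpha = tuple(alpha)
    assert best_alpha is not None
    combined = sum(a * nm for a, nm in zip(best_alpha, normed))
    return CombinationResult(
        weights=best_alpha,
        combined=DistanceMatrix(
            ids=ids,
            matrix=combined,
            descriptor_name="combined",
            metric_params={
                "weights": list(best_alpha),
                "components": [m.descriptor_name for m in matrices],
            },
        ),
        objective=float(best_obj),
        descriptor_names=tuple(m.descriptor_name for m in matrices),
    )


# --------------------------------------------------------------------------
# vectorization
# --------------------------------------------------------------------------

#: Six real-valued descriptors summarized into 4 features each -> R^24.
DEFAULT_VECTOR_DESCRIPTORS = (
    "energy",
    "flux",
    "leaf_index",
    "branching",
    "wiring",
    "tortuosity",
)

_SUMMARIES = ("integral", "max", "argmax", "value_at_1")


def _summaries(f: ShollFunction) -> dict[str, float]:
    widths = np.diff(np.append(f.breakpoints, 1.0))
    integral = float(f.values @ widths)
    imax = int(np.argmax(f.values))
    return {
        "integral": integral,
        "max": float(f.values[imax]),
        "argmax": float(f.breakpoints[imax]),
        "value_at_1": float(f.values[-1]),
    }


def vectorize(
    neuron: Neuron,
    descriptors: Sequence[str] = DEFAULT_VECTOR_DESCRIPTORS,
    descriptor_params: Mapping[str, dict] | None = None,
) -> dict[str, float]:
    """Fixed-length feature vector of a neuron's Sholl functions.

    For each real-valued descriptor, four summaries of its normalized
    function: exact integral over [0, 1], maximum, argmax (first
    breakpoint attaining the maximum), and the value at t = 1.  With the
    default six descriptors this gives the 24-dimensional morphology
    vector used for clustering and classification.
    """
    params = descriptor_params or {}
    out: dict[str, float] = {}
    for name in descriptors:
        f = compute_descriptor(neuron, name, **params.get(name, {}))
        for key, val in _summaries(f).items():
            out[f"{name}_{key}"] = val
    return out


def feature_table(
    neurons: Sequence[Neuron] | Mapping[str, Neuron],
    descriptors: Sequence[str] = DEFAULT_VECTOR_DESCRIPTORS,
    standardize: bool = True,
    ids: Sequence[str] | None = None,
    descriptor_params: Mapping[str, dict] | None = None,
) -> pd.DataFrame:
    """Feature matrix for a neuron set, z-scored per column by default.

    Zero-variance columns standardize to 0 (degenerate case of the
    z-score).
    """
    if isinstance(neurons, Mapping):
        items = [(str(k), v) for k, v in neurons.items()]
    else:
        if ids is None:
            ids = [f"n{i}" for i in range(len(neurons))]
        items = list(zip([str(i) for i in ids], neurons))
    rows = {nid: vectorize(n, descriptors, descriptor_params) for nid, n in items}
    df = pd.DataFrame.from_dict(rows, orient="index")
    if standardize:
        mu = df.mean(axis=0)
        sd = df.std(axis=0, ddof=0)
        sd[sd == 0] = np.inf  # zero-variance feature -> 0 after centering
        df = (df - mu) / sd
    return df


# --------------------------------------------------------------------------
# hierarchical clustering
# --------------------------------------------------------------------------

_LINKAGES = ("single", "complete", "average", "ward")


@dataclass
class ClusterResult:
    """Agglomerative merge tree over a neuron set."""

    ids: tuple[str, ...]
    merge_tree: np.ndarray  # scipy linkage matrix (n-1) x 4
    linkage: str

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat labeling with ``n_clusters`` clusters (1-based labels)."""
        return hierarchy.fcluster(self.merge_tree, t=n_clusters, criterion="maxclust")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merge_tree, columns=["left", "right", "height", "size"]
        )


def hierarchical_cluster(
    data: DistanceMatrix | np.ndarray | pd.DataFrame,
    linkage: str = "ward",
    ids: Sequence[str] | None = None,
) -> ClusterResult:
    """Agglomerative clustering of a precomputed matrix or feature table.

    A :class:`DistanceMatrix` is clustered directly on its entries
    (Lance-Williams updates; for Ward on a non-Euclidean pseudo-metric
    this is the standard precomputed-matrix extension).  A feature array
    or DataFrame is clustered under the Euclidean metric.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}, got {linkage!r}")
    if isinstance(data, DistanceMatrix):
        condensed = squareform(data.matrix, checks=True)
        out_ids = data.ids
    else:
        if isinstance(data, pd.DataFrame):
            out_ids = tuple(str(i) for i in data.index)
            X = data.to_numpy(dtype=float)
        else:
            X = np.asarray(data, dtype=float)
            if X.ndim != 2:
                raise ValueError("feature input must be 2-D")
            out_ids = tuple(ids) if ids is not None else tuple(
                f"n{i}" for i in range(X.shape[0])
            )
        condensed = None
        Z = hierarchy.linkage(X, method=linkage, metric="euclidean")
        return ClusterResult(out_ids, Z, linkage)
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterResult(out_ids, Z, linkage)


# --------------------------------------------------------------------------
# LMNN metric learning
# --------------------------------------------------------------------------


class LMNN(TransformerMixin, BaseEstimator):
    """Large-margin nearest-neighbor metric learning.

    Learns a linear transform ``L`` (so distances become
    ``||L (x - y)||``, a Mahalanobis pseudo-metric) by gradient descent
    from the identity, pulling each point's ``n_neighbors`` same-class
    target neighbors close while pushing differently-labeled impostors
    beyond a unit margin.  If the optimized transform does not improve
    training KNN accuracy over the Euclidean metric, the identity is
    kept, so the learned space never degrades training KNN performance.

    Parameters
    ----------
    n_neighbors : int
        Target neighbors per point (same class).
    push_weight : float in (0, 1)
        Weight of the impostor (push) term against the pull term.
    margin : float
        Margin added to the target-neighbor distance inside the hinge.
    max_iter : int
        Gradient-descent iteration cap.
    tol : float
        Relative loss-improvement stopping threshold.
    knn_k : int
        Neighborhood size of the KNN accuracy guard.
    random_state : int or None
        Unused by the deterministic solver; kept for API compatibility.

    Attributes
    ----------
    components_ : ndarray of shape (n_features, n_features)
        The learned linear transform L.
    n_iter_ : int
    """

    def __init__(
        self,
        n_neighbors: int = 3,
        push_weight: float = 0.5,
        margin: float = 1.0,
        max_iter: int = 100,
        tol: float = 1e-7,
        knn_k: int = 5,
        random_state: int | None = None,
    ):
        self.n_neighbors = n_neighbors
        self.push_weight = push_weight
        self.margin = margin
        self.max_iter = max_iter
        self.tol = tol
        self.knn_k = knn_k
        self.random_state = random_state

    def _loss_grad(self, L, X, targets, impostor_mask):
        """LMNN loss and gradient w.r.t. the transform L."""
        Xt = X @ L.T
        sq = np.sum((Xt[:, None, :] - Xt[None, :, :]) ** 2, axis=-1)
        pull = 0.0
        grad_M = np.zeros((X.shape[1], X.shape[1]))  # gradient w.r.t. M = L^T L
        mu = self.push_weight
        for i, js in enumerate(targets):
            for j in js:
                dij = X[i] - X[j]
                pull += sq[i, j]
                grad_M += (1 - mu) * np.outer(dij, dij)
        push = 0.0
        for i, js in enumerate(targets):
            imp = np.flatnonzero(impostor_mask[i])
            if imp.size == 0:
                continue
            for j in js:
                viol = self.margin + sq[i, j] - sq[i, imp]
                active = imp[viol > 0]
                if active.size == 0:
                    continue
                push += float(np.sum(viol[viol > 0]))
                dij = X[i] - X[j]
                grad_M += mu * active.size * np.outer(dij, dij)
                dil = X[i][None, :] - X[active]
                grad_M -= mu * dil.T @ dil
        loss = (1 - mu) * pull + mu * push
        grad_L = 2.0 * L @ grad_M
        return loss, grad_L

    def fit(self, X, y):
        X = validate_data(self, X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("LMNN needs at least 2 classes")
        if counts.min() <= self.n_neighbors:
            raise ValueError(
                f"every class must have more than n_neighbors={self.n_neighbors} "
                f"members; smallest class has {counts.min()}"
            )
        n = X.shape[0]
        eu_sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
        targets = []
        for i in range(n):
            same = np.flatnonzero((y == y[i]) & (np.arange(n) != i))
            order = same[np.argsort(eu_sq[i, same], kind="stable")]
            targets.append(order[: self.n_neighbors])
        impostor_mask = y[None, :] != y[:, None]

        L = np.eye(X.shape[1])
        loss, grad = self._loss_grad(L, X, targets, impostor_mask)
        init_loss = loss
        lr = 1e-3 / max(np.abs(grad).max(), 1e-12)
        it = 0
        for it in range(1, self.max_iter + 1):
            cand = L - lr * grad
            cand_loss, cand_grad = self._loss_grad(cand, X, targets, impostor_mask)
            if cand_loss < loss:
                if loss - cand_loss < self.tol * max(abs(loss), 1.0):
                    L, loss = cand, cand_loss
                    break
                L, loss, grad = cand, cand_loss, cand_grad
                lr *= 1.1
            else:
                lr *= 0.5
                if lr < 1e-15:
                    break

        # never regress training KNN accuracy below the Euclidean baseline
        k = min(self.knn_k, n - 1)
        knn = KNeighborsClassifier(n_neighbors=k)
        acc_eu = knn.fit(X, y).score(X, y)
        acc_learned = knn.fit(X @ L.T, y).score(X @ L.T, y)
        if acc_learned < acc_eu:
            L = np.eye(X.shape[1])
            loss = init_loss
        self.components_ = L
        self.n_iter_ = it
        self.loss_ = float(loss)
        self.classes_ = classes
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, dtype=float, reset=False)
        return X @ self.components_.T


def learn_metric(
    vectors: np.ndarray | pd.DataFrame,
    labels,
    k: int = 3,
    seed: int | None = None,
    **lmnn_params,
) -> LMNN:
    """Fit an LMNN transform on a feature table; returns the fitted model."""
    if isinstance(vectors, pd.DataFrame):
        y = _align_labels(tuple(str(i) for i in vectors.index), labels)
        X = vectors.to_numpy(dtype=float)
    else:
        X = np.asarray(vectors, dtype=float)
        y = np.asarray(labels)
    model = LMNN(n_neighbors=k, random_state=seed, **lmnn_params)
    return model.fit(X, y)


# --------------------------------------------------------------------------
# cross-validated classification
# --------------------------------------------------------------------------


@dataclass
class AccuracyReport:
    """Cross-validated and held-out accuracy of KNN in the learned space."""

    cv_mean: float
    cv_sd: float
    test_accuracy: float
    fold_scores: np.ndarray = field(repr=False)
    n_folds: int = 10
    n_repeats: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "cv_mean": self.cv_mean,
            "cv_sd": self.cv_sd,
            "test_accuracy": self.test_accuracy,
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
        }


def classify_with_cv(
    vectors: np.ndarray | pd.DataFrame,
    labels,
    seed: int = 0,
    n_folds: int = 10,
    n_repeats: int = 3,
    knn_k: int = 5,
    lmnn_k: int = 3,
    test_size: float = 0.3,
) -> AccuracyReport:
    """KNN classification protocol with LMNN metric learning.

    A stratified 70/30 train/test split (seeded) is drawn; the LMNN
    transform is learned on the training set; repeated stratified k-fold
    cross validation (10 folds, 3 repeats by default) of a KNN
    classifier in the learned space yields the mean +/- sd accuracy; a
    final KNN fit on the full training set is scored on the held-out
    test set.  If the smallest training class is below the fold count,
    folds are reduced with a warning.  Reproducible bit-for-bit given
    the seed.
    """
    if isinstance(vectors, pd.DataFrame):
        y = _align_labels(tuple(str(i) for i in vectors.index), labels)
        X = vectors.to_numpy(dtype=float)
    else:
        X = np.asarray(vectors, dtype=float)
        y = np.asarray(labels)
    y = np.asarray([str(v) for v in y])

    if len(set(y)) < 2:
        warnings.warn("single class: classification is degenerate", stacklevel=2)
        scores = np.ones(n_folds * n_repeats)
        return AccuracyReport(1.0, 0.0, 1.0, scores, n_folds, n_repeats, seed)

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    _, tr_counts = np.unique(y_tr, return_counts=True)
    min_class = int(tr_counts.min())
    if min_class < n_folds:
        warnings.warn(
            f"smallest training class has {min_class} members; reducing folds "
            f"from {n_folds} to {max(min_class, 2)}",
            stacklevel=2,
        )
        n_folds = max(min_class, 2)
    eff_lmnn_k = min(lmnn_k, min_class - 1)

    lmnn = LMNN(n_neighbors=eff_lmnn_k, knn_k=knn_k, random_state=seed)
    Xt_tr = lmnn.fit(X_tr, y_tr).transform(X_tr)

    cv = RepeatedStratifiedKFold(
        n_splits=n_folds, n_repeats=n_repeats, random_state=seed
    )
    scores = []
    for fit_idx, val_idx in cv.split(Xt_tr, y_tr):
        k = min(knn_k, len(fit_idx))
        knn = KNeighborsClassifier(n_neighbors=k)
        knn.fit(Xt_tr[fit_idx], y_tr[fit_idx])
        scores.append(knn.score(Xt_tr[val_idx], y_tr[val_idx]))
    scores = np.asarray(scores)

    final = KNeighborsClassifier(n_neighbors=min(knn_k, len(X_tr)))
    final.fit(Xt_tr, y_tr)
    test_acc = float(final.score(lmnn.transform(X_te), y_te))
    return AccuracyReport(
        cv_mean=float(scores.mean()),
        cv_sd=float(scores.std(ddof=1)),
        test_accuracy=test_acc,
        fold_scores=scores,
        n_folds=n_folds,
        n_repeats=n_repeats,
        seed=seed,
    )


# --------------------------------------------------------------------------
# stability probes
# --------------------------------------------------------------------------


def _jitter(neuron: Neuron, eps: float, rng: np.random.Generator) -> Neuron:
    """Perturb every non-soma node uniformly in a ball of radius eps."""
    if eps == 0:
        return neuron
    positions = {}
    for nid, node in neuron.nodes.items():
        if nid == neuron.root:
            continue
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = eps * rng.uniform() ** (1.0 / 3.0)
        positions[nid] = node.position + radius * direction
    return neuron.with_positions(positions)


def stability_probe(
    neuron: Neuron,
    descriptor_name: str,
    epsilons: Sequence[float],
    seed: int = 0,
    n_jitter: int = 5,
    p: float | None = None,
    descriptor_params: dict | None = None,
) -> np.ndarray:
    """Empirical stability curve d_phi(N, N_eps) vs jitter radius eps.

    For each eps, node positions (soma fixed) are jittered uniformly in
    a ball of radius eps and the descriptor pseudo-distance between the
    original and jittered neuron is averaged over ``n_jitter`` draws.
    For the stable descriptors (branching, wiring, leaf index, energy,
    flux) the curve tends to 0 as eps tends to 0; tortuosity is known to
    violate this (a tiny jitter can create a short, highly tortuous
    branch).
    """
    rng = np.random.default_rng(seed)
    params = descriptor_params or {}
    base = compute_descriptor(neuron, descriptor_name, **params)
    if p is None:
        p = 2.0 if descriptor_name == "sholl_tmd" else 1.0
    out = []
    for eps in epsilons:
        if eps < 0:
            raise ValueError("epsilons must be nonnegative")
        dists = []
        for _ in range(n_jitter):
            pert = compute_descriptor(
                _jitter(neuron, float(eps), rng), descriptor_name, **params
            )
            if descriptor_name == "sholl_tmd":
                dists.append(sholl_tmd_distance(base, pert, p=p))
            else:
                dists.append(function_distance(base, pert, p=p))
        out.append(float(np.mean(dists)))
    return np.asarray(out)
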