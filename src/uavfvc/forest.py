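"""Random-forest classification of image objects, with full accuracy metrics.

The forest is a bagged ensemble of binary CART trees: each tree trains on a
with-replacement bootstrap of the n labeled rows and grows by recursively
choosing, among a random subset of ceil(max_features * n_features) features,
the midpoint threshold that minimizes the sample-weighted Gini impurity

    Gini(t) = 1 - sum_j p(j|t)^2
    Gini(split) = sum_i (n_i / n) Gini(i)

Growth stops at max_depth, below min_samples_split, at purity, or when no
feature varies. Prediction is a plain majority vote over the K trees; vote
ties resolve to the first class in the canonical class order, which keeps the
whole model deterministic for a given seed. Default hyperparameters
(K=75, max_depth=16, max_features=0.1, min_samples_split=3) are the
grid-search optimum reported for object-based tailings-site classification.

Accuracy follows the standard confusion-matrix conventions with rows as
classified (mapped) labels and columns as reference labels:

    PA_i = a_ii / a_ti        (producer's accuracy; column totals a_ti)
    UA_i = a_ii / a_it        (user's accuracy; row totals a_it)
    OA   = sum_i a_ii / N
    kappa = (N * sum_i a_ii - sum_i a_ti * a_it) / (N^2 - sum_i a_ti * a_it)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def gini(counts) -> float:
    """Gini impurity 1 - sum p_j^2 of a node with the given class counts."""
    counts = np.asarray(counts, dtype=np.float64)
    if (counts < 0).any():
        raise ValueError("class counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty node has no impurity")
    p = counts / total
    return float(1.0 - np.sum(p * p))


def split_gini(child_counts) -> float:
    """Sample-weighted impurity of a candidate split (list of child count vectors)."""
    child_counts = [np.asarray(c, dtype=np.float64) for c in child_counts]
    totals = np.array([c.sum() for c in child_counts])
    n = totals.sum()
    if n <= 0:
        raise ValueError("split has no samples")
    out = 0.0
    for c, t in zip(child_counts, totals):
        if t > 0:
            out += (t / n) * gini(c)
    return float(out)


@dataclass
class ForestConfig:
    n_estimators: int = 75
    max_depth: int = 16
    max_features: float = 0.1     # fraction of features per node, floor 1
    min_samples_split: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not 0 < self.max_features <= 1:
            raise ValueError("max_features must lie in (0, 1]")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")


@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    left: int = -1
    right: int = -1
    leaf_class: int = -1

    @property
    def is_leaf(self) -> bool:
        return self.leaf_class >= 0


@dataclass
class CARTTree:
    nodes: list[_Node]

    def apply(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(len(X), dtype=np.int64)
        for r in range(len(X)):
            k = 0
            node = self.nodes[k]
            while not node.is_leaf:
                k = node.left if X[r, node.feature] <= node.threshold else node.right
                node = self.nodes[k]
            out[r] = node.leaf_class
        return out


def _best_split(X, y, feat_ids, n_classes):
    """Minimal weighted-Gini midpoint split over the candidate features.

    Returns (feature, threshold, impurity) or None if no feature varies.
    Ties go to the lower feature index, then the lower threshold.
    """
    best = None
    n = len(y)
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    for f in np.sort(feat_ids):
        x = X[:, f]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        distinct = xs[1:] > xs[:-1]
        if not distinct.any():
            continue
        cum = np.cumsum(onehot[order], axis=0)     # class counts left of cut k+1
        total = cum[-1]
        pos = np.nonzero(distinct)[0]              # split after sorted index pos
        left = cum[pos]
        right = total[None, :] - left
        nl = left.sum(axis=1)
        nr = right.sum(axis=1)
        gl = 1.0 - np.sum((left / nl[:, None]) ** 2, axis=1)
        gr = 1.0 - np.sum((right / nr[:, None]) ** 2, axis=1)
        imp = (nl * gl + nr * gr) / n
        k = int(np.argmin(imp))                    # first minimum = lowest threshold
        thr = 0.5 * (xs[pos[k]] + xs[pos[k] + 1])
        cand = (float(imp[k]), int(f), float(thr))
        if best is None or cand[0] < best[0] - 1e-15:
            best = cand
    if best is None:
        return None
    return best[1], best[2], best[0]


def _grow_tree(X, y, cfg: ForestConfig, n_classes: int, rng: np.random.Generator) -> CARTTree:
    n_features = X.shape[1]
    m = max(1, int(np.ceil(cfg.max_features * n_features)))
    nodes: list[_Node] = []

    def leaf(yy) -> int:
        counts = np.bincount(yy, minlength=n_classes)
        nodes.append(_Node(leaf_class=int(np.argmax(counts))))
        return len(nodes) - 1

    def build(idx, depth) -> int:
        yy = y[idx]
        counts = np.bincount(yy, minlength=n_classes)
        if (
            depth >= cfg.max_depth
            or len(idx) < cfg.min_samples_split
            or (counts > 0).sum() <= 1
        ):
            return leaf(yy)
        feat_ids = rng.choice(n_features, size=m, replace=False)
        found = _best_split(X[idx], yy, feat_ids, n_classes)
        if found is None:
            return leaf(yy)
        f, thr, _ = found
        go_left = X[idx, f] <= thr
        nodes.append(_Node(feature=f, threshold=thr))
        here = len(nodes) - 1
        nodes[here].left = build(idx[go_left], depth + 1)
        nodes[here].right = build(idx[~go_left], depth + 1)
        return here

    root = build(np.arange(len(y)), 0)
    assert root == 0
    return CARTTree(nodes)


@dataclass
class ForestModel:
    trees: list[CARTTree]
    bootstrap_indices: list[np.ndarray]
    classes: tuple
    feature_names: tuple
    config: ForestConfig

    def vote_counts(self, features) -> np.ndarray:
        X = _feature_matrix(features, self.feature_names)
        votes = np.zeros((len(X), len(self.classes)), dtype=np.int64)
        for tree in self.trees:
            pred = tree.apply(X)
            votes[np.arange(len(X)), pred] += 1
        return votes


def _feature_matrix(features, feature_names) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"feature columns missing: {missing}")
        X = features.loc[:, list(feature_names)].to_numpy(dtype=np.float64)
    else:
        X = np.asarray(features, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != len(feature_names):
            raise ValueError(
                f"expected {len(feature_names)} feature columns, got shape {X.shape}"
            )
    if not np.isfinite(X).all():
        raise ValueError("features contain missing or non-finite values")
    return X


def train(
    features,
    labels=None,
    cfg: ForestConfig = ForestConfig(),
    classes=None,
    label_column: str = "label",
) -> ForestModel:
    """Train a bagged CART forest.

    ``features`` is a DataFrame (optionally holding the labels in
    ``label_column``) or a 2-D array with ``labels`` given separately. The
    canonical class order is ``classes`` if provided, else the sorted unique
    labels; it fixes every tie-break downstream.
    """
    cfg.validate()
    if isinstance(features, pd.DataFrame) and labels is None:
        if label_column not in features.columns:
            raise ValueError(f"no labels given and no {label_column!r} column present")
        labels = features[label_column].to_numpy()
        features = features.drop(columns=[label_column])
    if labels is None:
        raise ValueError("labels are required for training")
    labels = np.asarray(labels)
    if isinstance(features, pd.DataFrame):
        feature_names = tuple(features.columns)
    else:
        features = np.asarray(features, dtype=np.float64)
        feature_names = tuple(f"f{c}" for c in range(features.shape[1]))
    X = _feature_matrix(features, feature_names)
    if len(X) != len(labels):
        raise ValueError("features and labels disagree in length")
    if len(X) < cfg.min_samples_split:
        raise ValueError("not enough labeled rows to split")
    if classes is None:
        classes = tuple(sorted(pd.unique(labels), key=str))
    else:
        classes = tuple(classes)
        unknown = set(labels) - set(classes)
        if unknown:
            raise ValueError(f"labels outside the declared classes: {unknown}")
    if len(set(labels)) < 2:
        raise ValueError("training set has a single class; forest is degenerate")
    class_index = {c: k for k, c in enumerate(classes)}
    y = np.array([class_index[v] for v in labels], dtype=np.int64)

    trees: list[CARTTree] = []
    boots: list[np.ndarray] = []
    n = len(y)
    for t in range(cfg.n_estimators):
        # per-tree stream at a fixed offset from the master seed
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, t)))
        idx = rng.integers(0, n, size=n)
        boots.append(idx)
        trees.append(_grow_tree(X[idx], y[idx], cfg, len(classes), rng))
    return ForestModel(trees, boots, classes, feature_names, cfg)


def predict(model: ForestModel, features) -> np.ndarray:
    """Majority-vote class per row; vote ties break to the first class in order."""
    votes = model.vote_counts(features)
    winners = np.argmax(votes, axis=1)      # argmax takes the first maximum
    return np.asarray([model.classes[k] for k in winners])


@dataclass
class ConfusionMatrix:
    """Counts a_ij with rows = classified labels, columns = reference labels."""

    counts: np.ndarray
    classes: tuple

    @property
    def row_totals(self) -> np.ndarray:      # a_it
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:      # a_ti
        return self.counts.sum(axis=0)

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))
        df.index.name = "classified"
        df.columns.name = "reference"
        return df


@dataclass
class AccuracyReport:
    pa: dict                      # producer's accuracy per class (NaN if no reference)
    ua: dict                      # user's accuracy per class (NaN if never predicted)
    oa: float
    kappa: float

    def to_dict(self) -> dict:
        return {"PA": self.pa, "UA": self.ua, "OA": self.oa, "kappa": self.kappa}


def accuracy_from_matrix(cm: ConfusionMatrix) -> AccuracyReport:
    counts = cm.counts.astype(np.float64)
    N = counts.sum()
    if N <= 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts)
    a_it = counts.sum(axis=1)
    a_ti = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(a_ti > 0, diag / a_ti, np.nan)
        ua = np.where(a_it > 0, diag / a_it, np.nan)
    oa = float(diag.sum() / N)
    chance = float(np.sum(a_ti * a_it))
    denom = N * N - chance
    kappa = float((N * diag.sum() - chance) / denom) if denom != 0 else 1.0
    return AccuracyReport(
        pa={c: float(v) for c, v in zip(cm.classes, pa)},
        ua={c: float(v) for c, v in zip(cm.classes, ua)},
        oa=oa,
        kappa=kappa,
    )


def evaluate(predicted, reference, classes=None) -> tuple[ConfusionMatrix, AccuracyReport]:
    """Confusion matrix and PA/UA/OA/kappa for paired label vectors."""
    predicted = np.asarray(predicted)
    reference = np.asarray(reference)
    if predicted.shape != reference.shape or predicted.size == 0:
        raise ValueError("predicted and reference labels must be equal-length and non-empty")
    if classes is None:
        classes = tuple(sorted(set(predicted) | set(reference), key=str))
    else:
        classes = tuple(classes)
    index = {c: k for k, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for p, r in zip(predicted, reference):
        counts[index[p], index[r]] += 1
    cm = ConfusionMatrix(counts, classes)
    return cm, accuracy_from_matrix(cm)
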