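"""Random forest with conditional permutation importance and LOOCV.

Trees are CART-style (Gini criterion) grown on subsamples drawn *without*
replacement, with a non-exhaustive ``mtry`` candidate draw at each node.
Variable importance is the mean out-of-bag accuracy decrease after permuting
a variable's OOB values; the *conditional* variant permutes within strata
defined by the in-tree split points of variables correlated with the target
variable, which removes the importance a variable inherits purely through
correlation with a truly informative one.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .kpca import QuadrantLabeling
from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)


class ForestError(ValueError):
    pass


@dataclass(frozen=True)
class ForestConfig:
    ntree: int = 80
    mtry: Optional[int] = None  # default: ceil(sqrt(p))
    subsample: float = 0.632  # fraction drawn without replacement per tree
    min_node_size: int = 2  # smallest node that may still be split
    max_depth: Optional[int] = None
    seed: int = 0
    corr_threshold: float = 0.2  # |Pearson r| above which variables condition each other

    def resolve_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else math.ceil(math.sqrt(p))
        return max(1, min(p, m))


#: the published high-dimensional preset (ntree 80, mtry 900)
SPECTRAL_PROFILE = ForestConfig(ntree=80, mtry=900)


@dataclass
class _Tree:
    feature: np.ndarray  # split variable per node, -1 at leaves
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_class: np.ndarray  # majority class index per node
    used_features: np.ndarray  # unique split variables, sorted

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.feature[node] >= 0
        while active.any():
            idx = np.nonzero(active)[0]
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.left[nd], self.right[nd])
            active = self.feature[node] >= 0
        return self.leaf_class[node]

    def thresholds_of(self, var: int) -> np.ndarray:
        return np.sort(self.threshold[self.feature == var])


@dataclass
class ForestModel:
    trees: list[_Tree]
    in_bag: list[np.ndarray]
    out_of_bag: list[np.ndarray]
    classes: np.ndarray  # original class labels, ascending
    config: ForestConfig
    n_samples: int
    n_features: int
    variable_names: Optional[list[str]] = None
    modalities: Optional[list[str]] = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority vote over trees; ties go to the lowest class label."""
        votes = np.zeros((X.shape[0], len(self.classes)), dtype=np.int64)
        for tree in self.trees:
            pred = tree.predict(X)
            votes[np.arange(X.shape[0]), pred] += 1
        return self.classes[np.argmax(votes, axis=1)]

    def oob_accuracy(self) -> float:
        """OOB accuracy of the ensemble (each sample voted on by the trees
        that did not train on it)."""
        votes = np.zeros((self.n_samples, len(self.classes)), dtype=np.int64)
        for tree, oob in zip(self.trees, self.out_of_bag):
            if oob.size:
                pred = tree.predict(self._X[oob])
                votes[oob, pred] += 1
        covered = votes.sum(axis=1) > 0
        pred = self.classes[np.argmax(votes, axis=1)]
        return float(np.mean(pred[covered] == self._y_labels[covered]))

    # training data retained for OOB computations
    _X: np.ndarray = field(default=None, repr=False)
    _y: np.ndarray = field(default=None, repr=False)  # class indices

    @property
    def _y_labels(self) -> np.ndarray:
        return self.classes[self._y]


@dataclass
class CvReport:
    accuracy: float
    confusion: pd.DataFrame  # rows = true class, columns = predicted class
    class_counts: dict

    def to_frame(self) -> pd.DataFrame:
        df = self.confusion.copy()
        df.index.name = "true"
        df.columns.name = "predicted"
        return df


def _as_matrix(X: Union[FeatureMatrix, np.ndarray]):
    if isinstance(X, FeatureMatrix):
        return (
            X.values,
            list(X.variable_names),
            list(X.modalities),
            list(X.sample_ids),
        )
    X = np.asarray(X, dtype=float)
    return X, None, None, None


def _as_labels(labels: Union[QuadrantLabeling, np.ndarray, Sequence[int]]) -> np.ndarray:
    if isinstance(labels, QuadrantLabeling):
        return np.asarray(labels.classes, dtype=int)
    return np.asarray(labels, dtype=int)


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    mtry: int,
    min_node_size: int,
    max_depth: Optional[int],
    rng: np.random.Generator,
) -> _Tree:
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    leaf_class: list[int] = []

    onehot = np.eye(n_classes, dtype=np.float64)[y]

    def new_node(idx: np.ndarray) -> int:
        node = len(feature)
        counts = np.bincount(y[idx], minlength=n_classes)
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        leaf_class.append(int(np.argmax(counts)))  # argmax ties -> lowest class
        return node

    def best_split(idx: np.ndarray):
        n = idx.size
        cand = rng.choice(X.shape[1], size=mtry, replace=False)
        total = onehot[idx].sum(axis=0)
        best = (np.inf, -1, np.nan)  # (weighted impurity, feature, threshold)
        for f in cand:
            x = X[idx, f]
            order = np.argsort(x, kind="stable")
            xs = x[order]
            boundary = xs[1:] > xs[:-1]
            if not boundary.any():
                continue
            cum = np.cumsum(onehot[idx][order], axis=0)[:-1]
            n_l = np.arange(1, n, dtype=np.float64)
            n_r = n - n_l
            gini_l = n_l - (cum**2).sum(axis=1) / n_l
            rc = total - cum
            gini_r = n_r - (rc**2).sum(axis=1) / n_r
            score = np.where(boundary, gini_l + gini_r, np.inf)
            pos = int(np.argmin(score))
            if score[pos] < best[0]:
                best = (float(score[pos]), int(f), float((xs[pos] + xs[pos + 1]) / 2.0))
        return best

    root = new_node(np.arange(X.shape[0]))
    # stack of (node id, sample indices, depth)
    stack = [(root, np.arange(X.shape[0]), 0)]
    while stack:
        node, idx, depth = stack.pop()
        classes_here = np.unique(y[idx])
        if (
            classes_here.size <= 1
            or idx.size < min_node_size
            or (max_depth is not None and depth >= max_depth)
        ):
            continue
        imp, f, th = best_split(idx)
        if f < 0:
            continue
        go_left = X[idx, f] <= th
        li, ri = idx[go_left], idx[~go_left]
        feature[node] = f
        threshold[node] = th
        ln = new_node(li)
        rn = new_node(ri)
        left[node] = ln
        right[node] = rn
        stack.append((rn, ri, depth + 1))
        stack.append((ln, li, depth + 1))

    farr = np.asarray(feature, dtype=np.int64)
    return _Tree(
        feature=farr,
        threshold=np.asarray(threshold, dtype=np.float64),
        left=np.asarray(left, dtype=np.int64),
        right=np.asarray(right, dtype=np.int64),
        leaf_class=np.asarray(leaf_class, dtype=np.int64),
        used_features=np.unique(farr[farr >= 0]),
    )


def fit_forest(
    X: Union[FeatureMatrix, np.ndarray],
    labels: Union[QuadrantLabeling, np.ndarray, Sequence[int]],
    config: ForestConfig = ForestConfig(),
) -> ForestModel:
    """Grow ``config.ntree`` trees on without-replacement subsamples.

    Per-tree random streams are derived from ``(seed, tree_index)`` so the
    result is independent of execution order and bit-reproducible.
    """
    values, names, modalities, _ = _as_matrix(X)
    y_labels = _as_labels(labels)
    n, p = values.shape
    if y_labels.shape[0] != n:
        raise ForestError("labels length must equal the number of samples")
    if n < 10:
        raise ForestError("need at least 10 samples")
    classes, y = np.unique(y_labels, return_inverse=True)
    if classes.size < 2:
        raise ForestError("need at least 2 classes")
    counts = np.bincount(y)
    if counts.min() < 2:
        small = classes[counts < 2].tolist()
        raise ForestError(f"classes with fewer than 2 samples cannot be stratified: {small}")
    mtry = config.resolve_mtry(p)
    n_sub = max(2, int(round(config.subsample * n)))
    trees: list[_Tree] = []
    in_bag: list[np.ndarray] = []
    out_of_bag: list[np.ndarray] = []
    all_idx = np.arange(n)
    for t in range(config.ntree):
        rng = np.random.default_rng([config.seed, 1, t])
        bag = np.sort(rng.choice(n, size=n_sub, replace=False))
        oob = np.setdiff1d(all_idx, bag, assume_unique=True)
        tree = _grow_tree(
            values[bag], y[bag], classes.size, mtry,
            config.min_node_size, config.max_depth, rng,
        )
        trees.append(tree)
        in_bag.append(bag)
        out_of_bag.append(oob)
    return ForestModel(
        trees=trees,
        in_bag=in_bag,
        out_of_bag=out_of_bag,
        classes=classes,
        config=config,
        n_samples=n,
        n_features=p,
        variable_names=names,
        modalities=modalities,
        _X=values,
        _y=y,
    )


def _correlation_sets(X: np.ndarray, threshold: float) -> list[np.ndarray]:
    """Per variable: indices of other variables with |Pearson r| > threshold."""
    sd = X.std(axis=0)
    ok = sd > 0
    corr = np.zeros((X.shape[1], X.shape[1]))
    if ok.sum() >= 2:
        sub = np.corrcoef(X[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = sub
    np.fill_diagonal(corr, 0.0)
    return [np.nonzero(np.abs(corr[j]) > threshold)[0] for j in range(X.shape[1])]


def _strata_codes(
    X_oob: np.ndarray, tree: _Tree, cond_vars: np.ndarray
) -> Optional[np.ndarray]:
    """OOB stratum id per sample from the tree's cut points of ``cond_vars``.

    Returns None when no conditioning variable is split on in this tree
    (the permutation then runs globally over the OOB set).
    """
    columns = []
    for z in cond_vars:
        cuts = tree.thresholds_of(int(z))
        if cuts.size:
            columns.append(np.searchsorted(cuts, X_oob[:, z]))
    if not columns:
        return None
    stacked = np.stack(columns, axis=1)
    _, codes = np.unique(stacked, axis=0, return_inverse=True)
    return codes


def _permute_within(values: np.ndarray, codes: Optional[np.ndarray], rng) -> np.ndarray:
    out = values.copy()
    if codes is None:
        rng.shuffle(out)
        return out
    for c in np.unique(codes):
        pos = np.nonzero(codes == c)[0]
        if pos.size > 1:
            out[pos] = values[pos[rng.permutation(pos.size)]]
    return out


def permutation_importance(
    model: ForestModel,
    X: Union[FeatureMatrix, np.ndarray, None] = None,
    labels: Union[QuadrantLabeling, np.ndarray, None] = None,
    conditional: bool = True,
    corr_threshold: Optional[float] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Mean OOB accuracy decrease per variable, conditional or global.

    A variable never split on by a tree leaves that tree's predictions
    untouched, so such trees contribute exactly 0; variables used by no tree
    therefore get importance 0.  Returns a table sorted by descending
    importance (ties broken by variable name).
    """
    values = model._X if X is None else _as_matrix(X)[0]
    y = model._y if labels is None else np.searchsorted(model.classes, _as_labels(labels))
    p = model.n_features
    thr = model.config.corr_threshold if corr_threshold is None else corr_threshold
    base_seed = model.config.seed if seed is None else seed
    cond_sets = _correlation_sets(values, thr) if conditional else [None] * p
    total = np.zeros(p)
    for t, (tree, oob) in enumerate(zip(model.trees, model.out_of_bag)):
        if oob.size == 0:
            continue
        X_oob = values[oob]
        y_oob = y[oob]
        acc_orig = float(np.mean(tree.predict(X_oob) == y_oob))
        rng = np.random.default_rng([base_seed, 2, t])
        for j in tree.used_features:
            codes = None
            if conditional and cond_sets[j].size:
                codes = _strata_codes(X_oob, tree, cond_sets[j])
            Xp = X_oob.copy()
            Xp[:, j] = _permute_within(X_oob[:, j], codes, rng)
            acc_perm = float(np.mean(tree.predict(Xp) == y_oob))
            total[j] += acc_orig - acc_perm
    importance = total / len(model.trees)
    names = model.variable_names or [f"var_{j}" for j in range(p)]
    modalities = model.modalities or ["nmr"] * p
    table = pd.DataFrame(
        {"variable": names, "modality": modalities, "importance": importance}
    )
    table = table.sort_values(
        ["importance", "variable"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, p + 1)
    return table


def conditional_importance(
    model: ForestModel,
    X: Union[FeatureMatrix, np.ndarray, None] = None,
    labels: Union[QuadrantLabeling, np.ndarray, None] = None,
    **kwargs,
) -> pd.DataFrame:
    return permutation_importance(model, X, labels, conditional=True, **kwargs)


def rank_report(importance: pd.DataFrame, top: int) -> pd.DataFrame:
    """Top-N slice of an importance table (ranks, names, modality, value)."""
    if top < 1:
        raise ForestError("top must be >= 1")
    p = len(importance)
    if top > p:
        logger.warning("rank_report: top=%d exceeds %d variables; truncating", top, p)
        top = p
    return importance.iloc[:top].reset_index(drop=True)


def _fold_seed(master: int, sample_id: str) -> list[int]:
    digest = hashlib.blake2b(str(sample_id).encode(), digest_size=8).digest()
    return [master, int.from_bytes(digest, "big")]


def loocv(
    X: Union[FeatureMatrix, np.ndarray],
    labels: Union[QuadrantLabeling, np.ndarray, Sequence[int]],
    config: ForestConfig = ForestConfig(),
) -> CvReport:
    """Leave-one-out cross-validation of the forest classifier.

    Each fold trains on the remaining samples (ordered by sample id, with a
    per-fold seed derived from the held-out id, so the result is invariant to
    row order) and predicts the held-out sample by majority vote.
    """
    values, names, modalities, sample_ids = _as_matrix(X)
    y_labels = _as_labels(labels)
    n = values.shape[0]
    classes = np.unique(y_labels)
    if n < classes.size + 1:
        raise ForestError("LOOCV needs n >= number of classes + 1")
    if sample_ids is None:
        sample_ids = [f"s{i:06d}" for i in range(n)]
    order = np.argsort(np.asarray(sample_ids, dtype=object))
    predictions = np.zeros(n, dtype=int)
    for pos in order:
        train = order[order != pos]
        fold_classes = np.unique(y_labels[train])
        if fold_classes.size < classes.size:
            logger.info("loocv: fold %s lacks a class in training", sample_ids[pos])
        # per-fold seed derived from (master seed, held-out sample id)
        fm = fit_forest(
            values[train],
            y_labels[train],
            replace(config, seed=_seed_scalar(config.seed, sample_ids[pos])),
        )
        predictions[pos] = fm.predict(values[pos][None, :])[0]
    accuracy = float(np.mean(predictions == y_labels))
    confusion = pd.crosstab(
        pd.Series(y_labels, name="true"),
        pd.Series(predictions, name="predicted"),
    ).reindex(index=classes, columns=classes, fill_value=0)
    class_counts = {int(c): int((y_labels == c).sum()) for c in classes}
    return CvReport(accuracy=accuracy, confusion=confusion, class_counts=class_counts)


def _seed_scalar(master: int, sample_id: str) -> int:
    digest = hashlib.blake2b(
        f"{master}:{sample_id}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % (2**63)
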