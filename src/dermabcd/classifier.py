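"""CART decision tree over asymmetry feature vectors.

A binary classification tree grown by greedy Gini-impurity minimization,
expanded until every leaf is pure (or contains duplicated feature vectors
with conflicting labels, in which case the leaf takes the majority label and
is flagged).  Determinism is pinned down explicitly: candidate thresholds
are midpoints between consecutive sorted unique feature values, impurity
ties break toward the lowest feature index then the lowest threshold, and a
sample routes left when ``feature <= threshold``.

Trees serialize to/from plain JSON so a trained asymmetry model can ship as
a text artifact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = [
    "LabeledSample",
    "CartNode",
    "CartTree",
    "SplitEvaluation",
    "fit_cart",
    "predict",
    "evaluate_split",
]


@dataclass(frozen=True)
class LabeledSample:
    """An asymmetry feature vector with its symmetric/asymmetric label."""

    features: np.ndarray
    label: str


@dataclass
class CartNode:
    """Internal node (feature, threshold, children) or leaf (label)."""

    label: str | None = None
    feature: int | None = None
    threshold: float | None = None
    left: "CartNode | None" = None
    right: "CartNode | None" = None
    n_samples: int = 0
    impure: bool = False  # leaf holds duplicated conflicting samples

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": self.label, "n": self.n_samples, "impure": self.impure}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "n": self.n_samples,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CartNode":
        if "leaf" in d:
            return cls(label=d["leaf"], n_samples=d.get("n", 0),
                       impure=d.get("impure", False))
        return cls(
            feature=int(d["feature"]),
            threshold=float(d["threshold"]),
            n_samples=d.get("n", 0),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass
class CartTree:
    """A fitted CART model: root node, feature arity, class names, seed."""

    root: CartNode
    n_features: int
    classes: tuple
    seed: int = 0
    single_class: bool = False  # training data had one class: trivial tree

    def predict_one(self, x: np.ndarray) -> str:
        node = self.root
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.label

    def leaves(self) -> list:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.left, node.right])
        return out

    @property
    def depth(self) -> int:
        def _d(node):
            return 0 if node.is_leaf else 1 + max(_d(node.left), _d(node.right))
        return _d(self.root)

    def to_json(self, path=None) -> str:
        payload = {
            "model": "cart",
            "n_features": self.n_features,
            "classes": list(self.classes),
            "seed": self.seed,
            "single_class": self.single_class,
            "tree": self.root.to_dict(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CartTree":
        if isinstance(source, dict):
            payload = source
        else:
            text = source if isinstance(source, str) and source.lstrip().startswith("{") \
                else open(source).read()
            payload = json.loads(text)
        return cls(
            root=CartNode.from_dict(payload["tree"]),
            n_features=int(payload["n_features"]),
            classes=tuple(payload["classes"]),
            seed=payload.get("seed", 0),
            single_class=payload.get("single_class", False),
        )


def _gini(labels: np.ndarray, classes) -> float:
    n = len(labels)
    g = 1.0
    for c in classes:
        p = np.count_nonzero(labels == c) / n
        g -= p * p
    return g


def _coerce(samples, labels=None):
    if labels is not None:
        X = np.asarray(samples, dtype=np.float64)
        y = np.asarray(labels)
    else:
        X = np.asarray([np.asarray(s.features, dtype=np.float64).ravel()
                        for s in samples])
        y = np.asarray([s.label for s in samples])
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("need a non-empty 2-D feature matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature values must be finite")
    return X, y


def fit_cart(samples, labels=None, seed: int = 0) -> CartTree:
    """Grow a CART tree to purity on labeled asymmetry samples.

    ``samples`` is either a list of :class:`LabeledSample` or a feature
    matrix with ``labels`` given separately.  The seed is recorded for
    provenance; the greedy growth itself is fully deterministic.
    """
    X, y = _coerce(samples, labels)
    classes = tuple(sorted(set(y.tolist())))

    def _grow(idx: np.ndarray) -> CartNode:
        sub_y = y[idx]
        uniq = set(sub_y.tolist())
        if len(uniq) == 1:
            return CartNode(label=sub_y[0], n_samples=len(idx))
        best = None  # (impurity, feature, threshold, left_mask)
        for f in range(X.shape[1]):
            vals = np.unique(X[idx, f])
            if len(vals) < 2:
                continue
            for t in (vals[:-1] + vals[1:]) / 2.0:
                left = X[idx, f] <= t
                nl = int(left.sum())
                if nl == 0 or nl == len(idx):
                    continue
                imp = (nl * _gini(sub_y[left], classes)
                       + (len(idx) - nl) * _gini(sub_y[~left], classes)) / len(idx)
                key = (imp, f, t)
                if best is None or key < (best[0], best[1], best[2]):
                    best = (imp, f, t, left)
        if best is None:
            # identical feature vectors with conflicting labels
            counts = {c: int(np.count_nonzero(sub_y == c)) for c in classes}
            majority = max(classes, key=lambda c: (counts[c], c))
            return CartNode(label=majority, n_samples=len(idx), impure=True)
        _, f, t, left = best
        node = CartNode(feature=f, threshold=float(t), n_samples=len(idx))
        node.left = _grow(idx[left])
        node.right = _grow(idx[~left])
        return node

    tree = CartTree(
        root=_grow(np.arange(len(X))),
        n_features=X.shape[1],
        classes=classes,
        seed=seed,
        single_class=len(classes) == 1,
    )
    return tree


def predict(tree: CartTree, features) -> np.ndarray | str:
    """Route feature vectors through the tree; ties at thresholds go left."""
    arr = np.asarray(features, dtype=np.float64)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != tree.n_features:
        raise ValueError(
            f"feature arity {arr.shape[1]} does not match training arity {tree.n_features}"
        )
    out = np.asarray([tree.predict_one(x) for x in arr])
    return out[0] if single else out


@dataclass
class SplitEvaluation:
    """Held-out evaluation of a single stratified train/test split."""

    accuracy: float
    per_class_correct: dict  # class -> (correct, total) on the test set
    n_train: int
    n_test: int
    seed: int
    tree: CartTree = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class_correct": {k: list(v) for k, v in self.per_class_correct.items()},
            "n_train": self.n_train,
            "n_test": self.n_test,
            "seed": self.seed,
        }


def evaluate_split(samples, labels=None, train_frac: float = 0.8,
                   seed: int = 0) -> SplitEvaluation:
    """Stratified random train/test evaluation of the CART tree.

    Splits 80:20 by default, stratified by class under the given seed, fits
    to purity on the training part and reports held-out accuracy with
    per-class correct counts.
    """
    X, y = _coerce(samples, labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("evaluation requires both classes present")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples to stratify")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_frac, stratify=y, random_state=seed
    )
    tree = fit_cart(X_tr, y_tr, seed=seed)
    pred = predict(tree, X_te)
    per_class = {
        str(c): (int(np.count_nonzero((pred == c) & (y_te == c))),
                 int(np.count_nonzero(y_te == c)))
        for c in classes
    }
    return SplitEvaluation(
        accuracy=float(np.mean(pred == y_te)),
        per_class_correct=per_class,
        n_train=len(X_tr),
        n_test=len(X_te),
        seed=seed,
        tree=tree,
    )
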