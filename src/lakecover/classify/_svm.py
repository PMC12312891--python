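"""One-vs-rest kernel SVM decision tree.

A sequence of K-1 soft-margin binary SVMs peels classes off one at a
time: node t separates its positive class from the pooled remaining
classes, and a pixel takes the positive class of the first node whose
decision value is non-negative (the last class in the order catches
everything else).

The quadratic program is solved by libsvm via scikit-learn; the retained
model keeps only the dual weights ``a_i * y_i``, the support vectors and
the bias, and the decision function ``f(x) = sum_i a_i y_i k(x_i, x) + b``
is evaluated by this module directly so predictions do not depend on the
solver's own prediction path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from ..grids import (
    ClassMap,
    NODATA,
    ShapeError,
    SpectralImage,
    TrainingSet,
    ValidationError,
)


@dataclass(frozen=True)
class KernelSpec:
    """Kernel configuration: 'rbf' (with gamma) or 'linear'.

    ``gamma=None`` means 1 / (n_features * mean feature variance), the
    conventional scale-aware default.
    """

    kind: str = "rbf"
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("rbf", "linear"):
            raise ValidationError(f"unknown kernel kind {self.kind!r}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValidationError("gamma must be positive")

    def resolve_gamma(self, x: np.ndarray) -> float:
        if self.kind == "linear":
            return 0.0
        if self.gamma is not None:
            return float(self.gamma)
        var = float(x.var())
        return 1.0 / (x.shape[1] * var) if var > 0 else 1.0


def _kernel_matrix(kind: str, gamma: float, a: np.ndarray,
                   b: np.ndarray) -> np.ndarray:
    """k(a_i, b_j) for all pairs; a is (n, M), b is (m, M)."""
    if kind == "linear":
        return a @ b.T
    sq = (np.sum(a * a, axis=1)[:, None] + np.sum(b * b, axis=1)[None, :]
          - 2.0 * (a @ b.T))
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-gamma * sq)


@dataclass
class SVMBinary:
    """Trained soft-margin binary SVM in dual form."""

    kernel: KernelSpec
    gamma: float
    support_vectors: np.ndarray
    dual_weights: np.ndarray  # a_i * y_i per retained support sample
    bias: float
    C: float

    def __post_init__(self) -> None:
        self.support_vectors = np.asarray(self.support_vectors, dtype=np.float64)
        self.dual_weights = np.asarray(self.dual_weights, dtype=np.float64).ravel()
        if self.support_vectors.ndim != 2:
            raise ShapeError("support vectors must be a 2-D matrix")
        if self.dual_weights.size != self.support_vectors.shape[0]:
            raise ShapeError("one dual weight per support vector required")
        if np.any(np.abs(self.dual_weights) > self.C * (1 + 1e-8)):
            raise ValidationError("dual weights must satisfy |a_i| <= C")

    @property
    def band_count(self) -> int:
        return self.support_vectors.shape[1]

    def decide(self, x: np.ndarray) -> np.ndarray:
        """Decision values for rows of ``x``."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.band_count:
            raise ShapeError(
                f"expected {self.band_count}-band vectors, got {x.shape[1]}")
        k = _kernel_matrix(self.kernel.kind, self.gamma,
                           self.support_vectors, x)
        return self.dual_weights @ k + self.bias


def svm_decision(svm: SVMBinary, x: np.ndarray) -> float | np.ndarray:
    """Kernel-expansion decision value(s) for one vector or a sample matrix."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    out = svm.decide(x)
    return float(out[0]) if single else out


def train_svm_binary(pos: np.ndarray, neg: np.ndarray,
                     kernel: KernelSpec | None = None,
                     C: float = 1.0) -> SVMBinary:
    """Solve the soft-margin dual (0 <= a_i <= C, sum a_i y_i = 0) for
    positives vs negatives and return the dual-form model."""
    kernel = kernel or KernelSpec()
    pos = np.atleast_2d(np.asarray(pos, dtype=np.float64))
    neg = np.atleast_2d(np.asarray(neg, dtype=np.float64))
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both sample sets must be non-empty")
    if pos.shape[1] != neg.shape[1]:
        raise ShapeError("positive and negative samples must share band count")
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(neg))):
        raise ValidationError("training samples must be finite")
    if C <= 0:
        raise ValidationError("C must be positive")
    x = np.vstack([pos, neg])
    y = np.concatenate([np.ones(len(pos)), -np.ones(len(neg))])
    gamma = kernel.resolve_gamma(x)
    clf = SVC(C=C, kernel=kernel.kind,
              gamma=gamma if kernel.kind == "rbf" else "scale")
    clf.fit(x, y)
    # libsvm orders binary classes ascending (-1, +1) and reports
    # dual_coef_ as a_i * y_i with the decision function positive for the
    # second class (+1), matching our sign convention.
    return SVMBinary(kernel=kernel, gamma=gamma,
                     support_vectors=clf.support_vectors_.copy(),
                     dual_weights=clf.dual_coef_[0].copy(),
                     bias=float(clf.intercept_[0]), C=C)


@dataclass
class SVMTree:
    """Sequential one-vs-rest tree: node t separates order[t] from the rest."""

    order: list[int]
    nodes: list[SVMBinary] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValidationError("class order must not repeat classes")
        if len(self.nodes) != max(len(self.order) - 1, 0):
            raise ValidationError("a K-class tree needs K-1 nodes")


def default_class_order(train: TrainingSet) -> list[int]:
    """Descending training-sample count, ties broken by class code."""
    return sorted(train.classes, key=lambda c: (-train.samples[c].shape[0], c))


def train_svm_tree(train: TrainingSet, order: list[int] | None = None,
                   kernel: KernelSpec | None = None, C: float = 1.0) -> SVMTree:
    """Train the K-1 one-vs-rest nodes along ``order``."""
    kernel = kernel or KernelSpec()
    if order is None:
        order = default_class_order(train)
    if sorted(order) != train.classes:
        raise ValidationError("order must be a permutation of the training classes")
    nodes = []
    for t, code in enumerate(order[:-1]):
        pos = train.samples[code]
        neg = np.vstack([train.samples[c] for c in order[t + 1:]])
        nodes.append(train_svm_binary(pos, neg, kernel=kernel, C=C))
    return SVMTree(order=list(order), nodes=nodes)


def _tree_predict(tree: SVMTree, x: np.ndarray) -> np.ndarray:
    labels = np.zeros(x.shape[0], dtype=np.uint8)
    undecided = np.ones(x.shape[0], dtype=bool)
    for code, node in zip(tree.order, tree.nodes):
        if not undecided.any():
            break
        f = node.decide(x[undecided])
        hit = f >= 0.0
        idx = np.flatnonzero(undecided)[hit]
        labels[idx] = code
        undecided[idx] = False
    labels[undecided] = tree.order[-1]
    return labels


def svm_tree_classify(image: SpectralImage, tree: SVMTree) -> ClassMap:
    """Walk the tree per pixel; nodata propagates."""
    if tree.nodes and image.band_count != tree.nodes[0].band_count:
        raise ShapeError("image band count does not match the tree")
    valid_idx, x = image.flat_valid()
    labels = np.zeros(image.shape[0] * image.shape[1], dtype=np.uint8)
    labels[valid_idx] = _tree_predict(tree, x)
    out = labels.reshape(image.shape)
    out[image.mask] = NODATA
    return ClassMap(out, date=image.date,
                    header=image.header.with_bands(1, "uint8"))
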