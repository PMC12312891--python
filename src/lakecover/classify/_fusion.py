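"""Agreement fusion of the Gaussian and SVM-tree classifiers.

Pixels where both classifiers agree keep their label and are treated as
correctly classified; the SVM tree is then retrained on the original
training samples augmented with a bounded, seeded sample of those agreed
pixels, and only the disagreeing pixels are relabeled with the retrained
tree.
"""

from __future__ import annotations

import logging

import numpy as np

from ..grids import ClassMap, NODATA, SpectralImage, TrainingSet
from ._mlc import fit_mlc, mlc_classify
from ._svm import KernelSpec, SVMTree, train_svm_tree, svm_tree_classify

logger = logging.getLogger(__name__)


def fuse_classify(image: SpectralImage, train: TrainingSet,
                  kernel: KernelSpec | None = None, C: float = 1.0,
                  epsilon: float | None = None,
                  max_extra_train: int = 2000,
                  seed: int = 0,
                  order: list[int] | None = None,
                  ) -> tuple[ClassMap, np.ndarray]:
    """Fused classification; returns (fused map, agreement mask).

    The agreement mask is True where the two first-pass classifiers gave
    the same label (such pixels are never altered) and False where the
    retrained tree relabeled the pixel.  Nodata pixels are False.
    """
    kernel = kernel or KernelSpec()
    models = fit_mlc(train, epsilon=epsilon)
    tree = train_svm_tree(train, order=order, kernel=kernel, C=C)
    mlc_map = mlc_classify(image, models)
    svm_map = svm_tree_classify(image, tree)

    agreed = (mlc_map.labels == svm_map.labels) & ~image.mask
    fused = mlc_map.labels.copy()
    disagree = ~agreed & ~image.mask
    if not disagree.any():
        return (ClassMap(fused, date=image.date, header=mlc_map.header),
                agreed)

    retrain = _augment_training(image, train, mlc_map.labels, agreed,
                                max_extra_train, seed)
    retrained = train_svm_tree(retrain, order=order or tree.order,
                               kernel=kernel, C=C)
    flat = image.values.reshape(-1, image.band_count)
    idx = np.flatnonzero(disagree.ravel())
    relabeled = _predict_subset(retrained, flat[idx])
    fused.ravel()[idx] = relabeled
    fused[image.mask] = NODATA
    return (ClassMap(fused, date=image.date, header=mlc_map.header), agreed)


def _predict_subset(tree: SVMTree, x: np.ndarray) -> np.ndarray:
    from ._svm import _tree_predict
    return _tree_predict(tree, x)


def _augment_training(image: SpectralImage, train: TrainingSet,
                      labels: np.ndarray, agreed: np.ndarray,
                      max_extra_train: int, seed: int) -> TrainingSet:
    """Original samples plus a seeded per-class sample of agreed pixels."""
    rng = np.random.default_rng(seed)
    flat_labels = labels.ravel()
    flat_agreed = agreed.ravel()
    flat_values = image.values.reshape(-1, image.band_count)
    samples: dict[int, np.ndarray] = {}
    for code in train.classes:
        pool = np.flatnonzero(flat_agreed & (flat_labels == code))
        base = train.samples[code]
        if pool.size == 0:
            logger.warning(
                "class %d has no agreed pixels; retraining falls back to the "
                "original samples for it", code)
            samples[code] = base
            continue
        take = min(pool.size, max_extra_train)
        chosen = rng.choice(pool, size=take, replace=False)
        samples[code] = np.vstack([base, flat_values[chosen]])
    return TrainingSet(samples=samples)
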