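"""Gaussian maximum-likelihood classification.

Each class is fitted with a sample mean and a population covariance
(divisor ``n``); pixels are labeled with the class of highest Gaussian
log-density, optionally weighted by log priors.  The log-space
discriminant avoids underflow on well-separated classes.  A
Jeffries-Matusita separability between two fitted classes is provided for
ROI screening (values near 2 mean near-perfect separability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from ..grids import (
    ClassMap,
    NODATA,
    ShapeError,
    SpectralImage,
    TrainingSet,
    ValidationError,
)


class SingularCovarianceError(ValidationError):
    """Covariance not invertible; re-fit with a positive regularization."""


@dataclass
class GaussianClassModel:
    """Fitted per-class Gaussian: mean, regularized covariance, label."""

    label: int
    mean: np.ndarray
    cov: np.ndarray
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64).ravel()
        self.cov = np.asarray(self.cov, dtype=np.float64)
        m = self.mean.size
        if self.cov.shape != (m, m):
            raise ShapeError("covariance shape must match the mean length")
        if not np.allclose(self.cov, self.cov.T):
            raise ValidationError("covariance must be symmetric")
        try:
            self._chol = np.linalg.cholesky(self.cov)
        except np.linalg.LinAlgError as exc:
            raise SingularCovarianceError(
                "covariance is not positive definite; refit with epsilon > 0"
            ) from exc
        self._log_det = 2.0 * np.sum(np.log(np.diag(self._chol)))

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """Multivariate normal log-density at rows of ``x``."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        m = self.mean.size
        if x.shape[1] != m:
            raise ShapeError(f"expected {m}-band vectors, got {x.shape[1]}")
        diff = x - self.mean
        z = solve_triangular(self._chol, diff.T, lower=True).T
        maha = np.einsum("ij,ij->i", z, z)
        return -0.5 * (m * np.log(2.0 * np.pi) + self._log_det + maha)


def _auto_epsilon(cov: np.ndarray) -> float:
    diag_mean = float(np.mean(np.diag(cov)))
    return 1e-6 * diag_mean if diag_mean > 0 else 1e-12


def fit_mlc(train: TrainingSet,
            epsilon: float | None = None) -> list[GaussianClassModel]:
    """Fit one Gaussian per class: sample mean and population covariance
    (divisor ``n``) with ``epsilon`` added to the diagonal.

    ``epsilon=None`` uses 1e-6 times the mean covariance diagonal per
    class; ``epsilon=0`` fails loudly if a covariance is singular.
    """
    models = []
    for code in train.classes:
        x = train.samples[code]
        mu = x.mean(axis=0)
        diff = x - mu
        cov = diff.T @ diff / x.shape[0]
        eps = _auto_epsilon(cov) if epsilon is None else float(epsilon)
        if eps < 0:
            raise ValidationError("epsilon must be >= 0")
        cov = cov + eps * np.eye(cov.shape[0])
        models.append(GaussianClassModel(label=code, mean=mu, cov=cov,
                                         epsilon=eps))
    return models


def mlc_classify(image: SpectralImage, models: list[GaussianClassModel],
                 priors: dict[int, float] | None = None) -> ClassMap:
    """Label every valid pixel with the argmax-density class.

    Ties break to the lowest class code; nodata propagates.
    """
    if len(models) < 2:
        raise ValidationError("need at least 2 class models")
    models = sorted(models, key=lambda m: m.label)
    m = models[0].mean.size
    if image.band_count != m:
        raise ShapeError(
            f"image has {image.band_count} bands but models expect {m}")
    if priors is not None:
        total = sum(priors.get(mod.label, 0.0) for mod in models)
        if total <= 0:
            raise ValidationError("priors must have positive total weight")
    valid_idx, x = image.flat_valid()
    scores = np.empty((x.shape[0], len(models)), dtype=np.float64)
    for k, mod in enumerate(models):
        s = mod.log_density(x)
        if priors is not None:
            p = priors.get(mod.label, 0.0)
            s = s + (np.log(p) if p > 0 else -np.inf)
        scores[:, k] = s
    best = np.argmax(scores, axis=1)  # first max -> lowest class code
    labels = np.zeros(image.shape[0] * image.shape[1], dtype=np.uint8)
    labels[valid_idx] = np.array([mod.label for mod in models],
                                 dtype=np.uint8)[best]
    out = labels.reshape(image.shape)
    out[image.mask] = NODATA
    return ClassMap(out, date=image.date, header=image.header.with_bands(1, "uint8"))


def separability(train: TrainingSet, class_a: int, class_b: int,
                 epsilon: float | None = None) -> float:
    """Jeffries-Matusita distance between the Gaussian fits of two classes.

    ``JM = 2 (1 - exp(-B))`` with ``B`` the Bhattacharyya distance; the
    result lies in [0, 2], where values above ~1.9 indicate training
    classes separable enough for reliable supervised classification.
    """
    fits = {m.label: m for m in fit_mlc(train, epsilon=epsilon)}
    for c in (class_a, class_b):
        if c not in fits:
            raise ValidationError(f"class {c} not present in the training set")
    a, b = fits[class_a], fits[class_b]
    cov = 0.5 * (a.cov + b.cov)
    diff = a.mean - b.mean
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "pooled covariance singular; use epsilon > 0") from exc
    z = solve_triangular(chol, diff, lower=True)
    term1 = 0.125 * float(z @ z)
    log_det_pool = 2.0 * np.sum(np.log(np.diag(chol)))
    term2 = 0.5 * (log_det_pool - 0.5 * (a._log_det + b._log_det))
    bhatt = term1 + term2
    return float(2.0 * (1.0 - np.exp(-bhatt)))
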