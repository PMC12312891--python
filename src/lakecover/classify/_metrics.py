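"""Accuracy assessment: confusion matrices, McNemar comparison and the
per-scene method-selection rule."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..grids import ClassMap, ValidationError


@dataclass
class ConfusionMatrix:
    """Cross-tabulation of predicted (rows) vs reference (columns) labels.

    Undefined per-class accuracies (empty row or column) are NaN, never 0.
    """

    labels: list[int]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValidationError("counts must be K x K for K labels")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValidationError("empty confusion matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    @property
    def users_accuracy(self) -> dict[int, float]:
        rows = self.counts.sum(axis=1)
        diag = np.diag(self.counts)
        return {lab: (float(diag[i] / rows[i]) if rows[i] else float("nan"))
                for i, lab in enumerate(self.labels)}

    @property
    def producers_accuracy(self) -> dict[int, float]:
        cols = self.counts.sum(axis=0)
        diag = np.diag(self.counts)
        return {lab: (float(diag[i] / cols[i]) if cols[i] else float("nan"))
                for i, lab in enumerate(self.labels)}

    @property
    def mean_users_accuracy(self) -> float:
        vals = [v for v in self.users_accuracy.values() if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def kappa(self) -> float:
        n = self.total
        po = self.overall_accuracy
        pe = float(self.counts.sum(axis=1) @ self.counts.sum(axis=0)) / (n * n)
        if pe == 1.0:
            return 1.0 if po == 1.0 else 0.0
        return float((po - pe) / (1.0 - pe))

    def summary(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "kappa": self.kappa,
            "users_accuracy": self.users_accuracy,
            "producers_accuracy": self.producers_accuracy,
            "mean_users_accuracy": self.mean_users_accuracy,
            "total": self.total,
        }


def _paired_labels(pred: ClassMap | np.ndarray,
                   reference: ClassMap | np.ndarray,
                   ) -> tuple[np.ndarray, np.ndarray]:
    p = pred.labels if isinstance(pred, ClassMap) else np.asarray(pred)
    r = reference.labels if isinstance(reference, ClassMap) else np.asarray(reference)
    if p.shape != r.shape:
        raise ValidationError("prediction and reference shapes differ")
    valid = (p != 0) & (r != 0)
    return p[valid].ravel(), r[valid].ravel()


def confusion(pred: ClassMap | np.ndarray,
              reference: ClassMap | np.ndarray,
              labels: list[int] | None = None) -> ConfusionMatrix:
    """Confusion matrix over pixels valid in both maps (code 0 excluded)."""
    p, r = _paired_labels(pred, reference)
    if p.size == 0:
        raise ValidationError("no valid reference pixels")
    if labels is None:
        labels = sorted(set(np.unique(p)) | set(np.unique(r)))
    labels = [int(lab) for lab in labels]
    index = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (np.vectorize(index.get)(p), np.vectorize(index.get)(r)), 1)
    return ConfusionMatrix(labels=list(labels), counts=counts)


@dataclass
class McNemarResult:
    statistic: float
    p_value: float
    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    exact: bool
    degenerate: bool = False


def mcnemar(pred_a: ClassMap | np.ndarray, pred_b: ClassMap | np.ndarray,
            reference: ClassMap | np.ndarray) -> McNemarResult:
    """Paired-correctness McNemar test between two classifications.

    Uses the continuity-corrected chi-square (df = 1) when the discordant
    count b + c >= 25, otherwise the exact two-sided binomial test.
    """
    a, r = _paired_labels(pred_a, reference)
    b_lab, r2 = _paired_labels(pred_b, reference)
    if a.size != b_lab.size or not np.array_equal(r, r2):
        raise ValidationError("both maps must cover the same reference pixels")
    a_ok = a == r
    b_ok = b_lab == r
    b = int(np.count_nonzero(a_ok & ~b_ok))
    c = int(np.count_nonzero(~a_ok & b_ok))
    if b + c == 0:
        return McNemarResult(statistic=0.0, p_value=1.0, b=0, c=0,
                             exact=False, degenerate=True)
    stat = (abs(b - c) - 1.0) ** 2 / (b + c)
    if b + c >= 25:
        p = float(stats.chi2.sf(stat, df=1))
        return McNemarResult(statistic=float(stat), p_value=p, b=b, c=c,
                             exact=False)
    p = float(stats.binomtest(min(b, c), b + c, 0.5).pvalue)
    return McNemarResult(statistic=float(stat), p_value=p, b=b, c=c,
                         exact=True)


@dataclass
class MethodChoice:
    chosen: str
    rationale: str


def select_method(metrics_a: dict, metrics_b: dict,
                  mcnemar_p: float | None = None,
                  name_a: str = "A", name_b: str = "B") -> MethodChoice:
    """Choose between two classifier metric summaries.

    Dominance on both OA and kappa wins outright.  When OA and kappa
    disagree and the McNemar difference is not significant (p > 0.05),
    the higher kappa wins; remaining ties go to higher mean UA, then to
    the first method.
    """
    oa_a, oa_b = metrics_a["overall_accuracy"], metrics_b["overall_accuracy"]
    k_a, k_b = metrics_a["kappa"], metrics_b["kappa"]
    if oa_a >= oa_b and k_a >= k_b and (oa_a > oa_b or k_a > k_b):
        return MethodChoice(name_a, f"{name_a} dominates on OA and kappa")
    if oa_b >= oa_a and k_b >= k_a and (oa_b > oa_a or k_b > k_a):
        return MethodChoice(name_b, f"{name_b} dominates on OA and kappa")
    if mcnemar_p is not None and mcnemar_p <= 0.05 and oa_a != oa_b:
        winner = name_a if oa_a > oa_b else name_b
        return MethodChoice(
            winner, "significant paired difference; choosing the higher OA")
    if k_a != k_b:
        winner, why = ((name_a, k_a) if k_a > k_b else (name_b, k_b))
        return MethodChoice(
            winner,
            "OA and kappa disagree and the difference is not significant; "
            f"choosing the higher kappa ({why:.3f})")
    ua_a = metrics_a.get("mean_users_accuracy", float("nan"))
    ua_b = metrics_b.get("mean_users_accuracy", float("nan"))
    if not np.isnan(ua_a) and not np.isnan(ua_b) and ua_a != ua_b:
        winner = name_a if ua_a > ua_b else name_b
        return MethodChoice(winner, "tie on OA/kappa broken by mean UA")
    return MethodChoice(name_a, "full tie; defaulting to the first method")
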