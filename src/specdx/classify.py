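"""PCA dimensionality reduction and LDA classification under k-fold CV.

Spectra are projected onto the leading principal components of the
mean-centred band covariance (bands share units — percent reflectance —
so no per-band standardisation by default), and symptoms are classified
with a linear discriminant model: Gaussian classes with a pooled
within-class covariance, giving the discriminant scores

    δ_k(x) = xᵀ Σ⁻¹ μ_k − ½ μ_kᵀ Σ⁻¹ μ_k + log π_k .

Five-fold cross-validation is stratified by class (unstratified folds
can drop a class from training entirely), with PCA fitted inside each
training fold by default (``fold_safe``); ``paper_mimic`` fits PCA once
on all data first, reproducing the common fit-then-validate reading of
the procedure at the cost of mild information leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SpectraSet

logger = logging.getLogger(__name__)


def _class_mask(y: np.ndarray, c) -> np.ndarray:
    """Elementwise label equality (numpy coerces str-Enum scalars, so == is unreliable)."""
    return np.fromiter((yi == c for yi in y), dtype=bool, count=len(y))

__all__ = [
    "PCAModel",
    "LDAModel",
    "ConfusionMatrix",
    "CVResult",
    "fit_pca",
    "pca_transform",
    "dimensionality_reduction_percent",
    "fit_lda",
    "predict_lda",
    "stratified_folds",
    "crossvalidate",
    "overall_accuracy",
    "per_class_accuracy",
]


@dataclass
class PCAModel:
    """Principal components of a mean-centred data matrix.

    ``loadings`` rows are orthonormal band-space directions ordered by
    explained variance; the sign convention makes each component's
    largest-magnitude entry positive so fits are reproducible.
    """

    band_means: np.ndarray
    loadings: np.ndarray  # (n_components, n_bands)
    explained_variance: np.ndarray
    n_components: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.explained_variance) > 1e-10):
            raise ValueError("explained_variance must be non-increasing")


@dataclass
class LDAModel:
    """Linear discriminant model: class means, pooled covariance, priors."""

    classes: list
    class_means: np.ndarray  # (K, d)
    pooled_covariance: np.ndarray  # (d, d)
    priors: np.ndarray  # (K,)
    _sigma_inv: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if abs(float(self.priors.sum()) - 1.0) > 1e-12:
            raise ValueError("priors must sum to 1")
        if np.any(self.priors < 0):
            raise ValueError("priors must be non-negative")
        sym_err = np.max(np.abs(self.pooled_covariance - self.pooled_covariance.T))
        if sym_err > 1e-10:
            raise ValueError("pooled covariance must be symmetric")


@dataclass
class ConfusionMatrix:
    """K×K true-vs-predicted counts: rows = true class, columns = predicted."""

    classes: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        k = len(self.classes)
        if c.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        self.counts = c.astype(int)

    @classmethod
    def from_predictions(cls, classes: list, y_true, y_pred) -> "ConfusionMatrix":
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred, strict=True):
            counts[index[t], index[p]] += 1
        return cls(classes=classes, counts=counts)

    def to_frame(self) -> pd.DataFrame:
        names = [getattr(c, "value", c) for c in self.classes]
        return pd.DataFrame(self.counts, index=names, columns=names)


@dataclass
class CVResult:
    """Aggregate outcome of a k-fold cross-validation run."""

    fold_assignment: np.ndarray  # fold index per sample, 1..k
    predictions: np.ndarray  # predicted label per sample (from its test fold)
    confusion: ConfusionMatrix
    overall_accuracy: float  # percent
    per_class_accuracy: dict  # class -> percent (NaN when no test samples)
    seed: int
    scope: str


def fit_pca(matrix: np.ndarray, n_components: int = 10) -> PCAModel:
    """Principal components via SVD of the mean-centred matrix.

    Eigenvalues of the sample covariance (divisor n−1) are reported as
    explained variances.  Requires ``n_components`` ≤ min(n_samples − 1,
    n_bands).
    """
    x = np.asarray(matrix, dtype=float)
    n, p = x.shape
    if n < 2:
        raise ValueError("fit_pca requires at least 2 samples")
    limit = min(n - 1, p)
    if not 1 <= n_components <= limit:
        raise ValueError(
            f"n_components={n_components} out of range [1, {limit}] "
            f"for a {n}x{p} matrix"
        )
    means = x.mean(axis=0)
    _, s, vt = np.linalg.svd(x - means, full_matrices=False)
    loadings = vt[:n_components]
    # sign convention: largest-magnitude entry of each component positive
    for row in loadings:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    explained = (s[:n_components] ** 2) / (n - 1)
    return PCAModel(
        band_means=means,
        loadings=loadings,
        explained_variance=explained,
        n_components=n_components,
    )


def pca_transform(model: PCAModel, matrix: np.ndarray) -> np.ndarray:
    """Project (mean-centred) rows onto the model's components."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.band_means.size:
        raise ValueError(
            f"matrix has {x.shape[1]} bands but model expects {model.band_means.size}"
        )
    return (x - model.band_means) @ model.loadings.T


def dimensionality_reduction_percent(n_bands: int, n_components: int) -> float:
    """Percent reduction achieved by keeping ``n_components`` of ``n_bands``."""
    if not 1 <= n_components <= n_bands:
        raise ValueError(
            f"need 1 <= n_components ({n_components}) <= n_bands ({n_bands})"
        )
    return 100.0 * (1.0 - n_components / n_bands)


def fit_lda(scores: np.ndarray, labels, regularization: float = 0.0) -> LDAModel:
    """Fit a linear discriminant model with empirical priors.

    The pooled within-class covariance uses divisor n − K, plus
    ``regularization``·I on the diagonal.  A singular pooled covariance
    with zero regularization is an error advising regularization.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    classes = sorted(set(y.tolist()), key=lambda c: getattr(c, "value", c))
    k = len(classes)
    if k < 2:
        raise ValueError("fit_lda requires at least 2 classes")
    n, d = x.shape
    means = np.empty((k, d))
    priors = np.empty(k)
    scatter = np.zeros((d, d))
    for i, c in enumerate(classes):
        xi = x[_class_mask(y, c)]
        if xi.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        means[i] = xi.mean(axis=0)
        priors[i] = xi.shape[0] / n
        centred = xi - means[i]
        scatter += centred.T @ centred
    if n - k < d and regularization == 0.0:
        raise ValueError(
            f"pooled covariance is rank-deficient ({n} samples, {k} classes, "
            f"{d} dims); pass regularization > 0"
        )
    cov = scatter / (n - k) + regularization * np.eye(d)
    cov = (cov + cov.T) / 2.0
    try:
        sigma_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled covariance; pass regularization > 0"
        ) from exc
    if regularization == 0.0 and np.linalg.cond(cov) > 1e12:
        raise ValueError(
            "pooled covariance is numerically singular; pass regularization > 0"
        )
    return LDAModel(
        classes=classes,
        class_means=means,
        pooled_covariance=cov,
        priors=priors,
        _sigma_inv=sigma_inv,
    )


def _discriminant_scores(model: LDAModel, x: np.ndarray) -> np.ndarray:
    si = model._sigma_inv
    if si is None:
        si = np.linalg.inv(model.pooled_covariance)
    a = model.class_means @ si  # (K, d)
    const = -0.5 * np.einsum("kd,kd->k", a, model.class_means) + np.log(model.priors)
    return x @ a.T + const


def predict_lda(model: LDAModel, scores: np.ndarray):
    """Class predictions and posterior probabilities.

    Posterior rows are the softmax of the discriminant scores (the
    shared −½xᵀΣ⁻¹x term cancels in normalisation); argmax ties break
    by class declaration order.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.class_means.shape[1]:
        raise ValueError(
            f"scores have {x.shape[1]} dims but model expects {model.class_means.shape[1]}"
        )
    delta = _discriminant_scores(model, x)
    delta_shifted = delta - delta.max(axis=1, keepdims=True)
    expd = np.exp(delta_shifted)
    posterior = expd / expd.sum(axis=1, keepdims=True)
    labels = np.array([model.classes[i] for i in np.argmax(delta, axis=1)], dtype=object)
    return labels, posterior


def stratified_folds(labels, k: int, seed: int) -> np.ndarray:
    """Seeded stratified fold assignment, 1..k per sample.

    Within each class, samples are shuffled and dealt round-robin, so
    per-class fold sizes differ by at most one.  Classes with fewer
    than k samples are an error naming the class.
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.zeros(y.size, dtype=int)
    for c in sorted(set(y.tolist()), key=lambda c: getattr(c, "value", c)):
        idx = np.flatnonzero(_class_mask(y, c))
        if idx.size < k:
            raise ValueError(
                f"class {getattr(c, 'value', c)!r} has {idx.size} samples; "
                f"{k}-fold CV needs at least {k}"
            )
        rng.shuffle(idx)
        folds[idx] = (np.arange(idx.size) % k) + 1
    return folds


def crossvalidate(
    s: SpectraSet,
    k: int = 5,
    n_components: int = 10,
    scope: str = "fold_safe",
    seed: int = 0,
    regularization: float = 0.0,
    labels=None,
) -> CVResult:
    """Stratified k-fold PCA→LDA cross-validation on a spectra set.

    Each fold serves once as the test set; predictions are aggregated
    into a single confusion matrix.  ``scope='fold_safe'`` refits PCA on
    every training fold; ``scope='paper_mimic'`` fits PCA once on all
    samples before splitting.  Deterministic given the seed.
    """
    if scope not in ("fold_safe", "paper_mimic"):
        raise ValueError(f"scope must be 'fold_safe' or 'paper_mimic', got {scope!r}")
    y = np.asarray(labels if labels is not None else s.labels())
    folds = stratified_folds(y, k, seed)
    classes = sorted(set(y.tolist()), key=lambda c: getattr(c, "value", c))
    x = s.reflectance
    predictions = np.empty(y.size, dtype=object)
    shared_pca = fit_pca(x, n_components) if scope == "paper_mimic" else None
    for f in range(1, k + 1):
        test = folds == f
        train = ~test
        pca = shared_pca if shared_pca is not None else fit_pca(x[train], n_components)
        lda = fit_lda(pca_transform(pca, x[train]), y[train], regularization)
        pred, _ = predict_lda(lda, pca_transform(pca, x[test]))
        predictions[test] = pred
    cm = ConfusionMatrix.from_predictions(classes, y, predictions)
    return CVResult(
        fold_assignment=folds,
        predictions=predictions,
        confusion=cm,
        overall_accuracy=overall_accuracy(cm),
        per_class_accuracy=per_class_accuracy(cm),
        seed=seed,
        scope=scope,
    )


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Percent of all test observations on the confusion-matrix diagonal."""
    total = int(cm.counts.sum())
    if total < 1:
        raise ValueError("confusion matrix is empty")
    return 100.0 * float(np.trace(cm.counts)) / total


def per_class_accuracy(cm: ConfusionMatrix) -> dict:
    """Recall per true class, in percent (NaN for classes with no test samples)."""
    out = {}
    for i, c in enumerate(cm.classes):
        row = cm.counts[i].sum()
        out[c] = 100.0 * cm.counts[i, i] / row if row else float("nan")
    return out
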