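"""Supervised and unsupervised chemometrics.

Ordination
----------
``pca`` eigendecomposes either the correlation or the covariance matrix of
the variables (correlation is the convention for mass-spectral feature
tables, where abundances span orders of magnitude); ``kpca`` performs the
kernelized analogue on the double-centered Gram matrix.

Classification
--------------
``train_discriminant`` fits Fisher's linear discriminant (LDA) or its
kernelized form (KDA, kernel Fisher discriminant).  Both maximise the
between-class over within-class scatter ratio; KDA does so in the feature
space induced by a linear or Gaussian (rbf) kernel, expressing the
discriminant directions through dual coefficients over the training
samples.  A ridge term ``lambda * I`` on the within-class scatter
stabilises the p >> n regime typical of spectral fingerprints.
Classification is by the nearest class centroid (Euclidean) in
discriminant space, with ties broken toward the lexicographically
smallest label.

``loocv`` runs leave-one-out cross-validation with the full pipeline —
per-variable standardization included — refitted inside every fold, so no
information leaks from the held-out sample.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import scipy.linalg

from .errors import ConfigError, DataError
from .fingerprint import FeatureTable, FingerprintMatrix

ArrayLike = Union[FeatureTable, FingerprintMatrix, np.ndarray]

#: Ridge scale: default lambda = RIDGE_SCALE * trace(within-scatter) / dim.
RIDGE_SCALE = 1e-3


def _as_matrix(x: ArrayLike) -> np.ndarray:
    if isinstance(x, (FeatureTable, FingerprintMatrix)):
        return np.asarray(x.values, dtype=float)
    return np.asarray(x, dtype=float)


def _get_labels(x: ArrayLike, labels) -> list[str]:
    if labels is None and isinstance(x, (FeatureTable, FingerprintMatrix)):
        labels = x.labels
    if labels is None:
        raise ConfigError("class labels are required")
    return [str(l) for l in labels]


class PCAMode(str, enum.Enum):
    CORRELATION = "correlation"
    COVARIANCE = "covariance"


class Method(str, enum.Enum):
    LDA = "lda"
    KDA = "kda"


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and scale.

    ``rbf`` is the Gaussian kernel ``exp(-||x - y||^2 / (2 b^2))`` with
    bandwidth ``b`` in the units of feature-space Euclidean distance;
    ``bandwidth=None`` requests the median-heuristic bandwidth (median
    pairwise distance of the training features) at fit time.
    """

    name: str = "rbf"
    bandwidth: Optional[float] = None

    def __post_init__(self):
        if self.name not in ("linear", "rbf"):
            raise ConfigError(f"unknown kernel {self.name!r}")
        if self.name == "rbf" and self.bandwidth is not None and self.bandwidth <= 0:
            raise ConfigError("rbf bandwidth must be positive")

    def gram(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        if self.name == "linear":
            return a @ b.T
        if self.bandwidth is None:
            raise ConfigError("rbf bandwidth not resolved; fit the model first")
        sq = (
            np.sum(a**2, axis=1)[:, None]
            + np.sum(b**2, axis=1)[None, :]
            - 2.0 * (a @ b.T)
        )
        np.maximum(sq, 0.0, out=sq)
        return np.exp(-sq / (2.0 * self.bandwidth**2))


def median_pairwise_distance(x: np.ndarray) -> float:
    """Median of the strictly-upper-triangle pairwise Euclidean distances."""
    from scipy.spatial.distance import pdist

    d = pdist(np.asarray(x, float))
    d = d[d > 0]
    if len(d) == 0:
        return 1.0
    return float(np.median(d))


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray


@dataclass
class Standardizer:
    """Per-variable location/scale remembered from training data."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "Standardizer":
        mean = x.mean(axis=0)
        scale = x.std(axis=0, ddof=1)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean, scale)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.mean) / self.scale


@dataclass
class DiscriminantModel:
    """Trained LDA/KDA state with a nearest-centroid predict contract."""

    method: Method
    classes: list[str]
    scaling: Standardizer
    regularization: float
    eigenvalues: np.ndarray
    # lda
    projection_vectors: Optional[np.ndarray] = None  # variables x directions
    # kda
    kernel: Optional[KernelSpec] = None
    training_features: Optional[np.ndarray] = None  # standardized
    dual_coefficients: Optional[np.ndarray] = None  # n_train x directions
    class_centroids: np.ndarray = field(default=None)  # classes x directions

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Project (raw-scale) samples into discriminant space."""
        x = np.atleast_2d(np.asarray(x, float))
        z = self.scaling(x)
        if self.method is Method.LDA:
            return z @ self.projection_vectors
        k = self.kernel.gram(z, self.training_features)
        return k @ self.dual_coefficients

    def predict(self, sample: np.ndarray):
        """Classify one sample; returns ``(label, distances)``.

        ``distances`` maps every class label to the Euclidean distance
        between the projected sample and that class's centroid.  Ties go
        to the lexicographically smallest label.
        """
        sample = np.asarray(sample, float)
        if sample.ndim != 1:
            raise DataError("predict takes a single 1-D feature vector")
        if len(sample) != len(self.scaling.mean):
            raise DataError(
                f"sample has {len(sample)} variables, model was trained on "
                f"{len(self.scaling.mean)}"
            )
        y = self.transform(sample[None, :])[0]
        dist = np.linalg.norm(self.class_centroids - y[None, :], axis=1)
        order = sorted(range(len(self.classes)),
                       key=lambda i: (dist[i], self.classes[i]))
        best = order[0]
        return self.classes[best], dict(zip(self.classes, dist))


@dataclass
class LoocvResult:
    predicted: list[str]
    truth: list[str]
    percent_correct: float
    confusion: np.ndarray
    classes: list[str]


# ---------------------------------------------------------------------------
# PCA / KPCA
# ---------------------------------------------------------------------------

def pca(x: ArrayLike, mode: PCAMode | str = PCAMode.CORRELATION,
        k: Optional[int] = None) -> PCAResult:
    """Principal component analysis on the correlation or covariance matrix.

    Scores are the centered (and, in correlation mode, standardized) data
    projected onto the loadings; ``variance_explained`` is each eigenvalue
    over the total.  Implemented by SVD of the prepared data matrix, which
    is the eigendecomposition of the chosen matrix of column statistics.
    """
    mode = PCAMode(mode)
    data = _as_matrix(x)
    n, p = data.shape
    if n < 2:
        raise DataError("pca needs at least 2 samples")
    kmax = min(n - 1, p)
    if k is None:
        k = kmax
    if not (1 <= k <= kmax):
        raise ConfigError(f"k must be in [1, {kmax}], got {k}")
    centered = data - data.mean(axis=0)
    if mode is PCAMode.CORRELATION:
        sd = data.std(axis=0, ddof=1)
        dead = np.flatnonzero(sd == 0)
        if len(dead):
            raise DataError(
                f"zero-variance variable(s) at column index {dead.tolist()} "
                "cannot be standardized in correlation mode"
            )
        centered = centered / sd
    # SVD route: eigenvalues of X'X/(n-1) are singular values squared / (n-1)
    u, sing, vt = np.linalg.svd(centered, full_matrices=False)
    eig = sing**2 / (n - 1)
    total = eig.sum()
    loadings = vt.T[:, :k]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    scores = centered @ loadings
    return PCAResult(
        scores=scores,
        loadings=loadings,
        eigenvalues=eig[:k],
        variance_explained=eig[:k] / total,
    )


def kpca(x: ArrayLike, kernel: KernelSpec | None = None,
         k: Optional[int] = None) -> PCAResult:
    """Kernel PCA: eigendecomposition of the double-centered Gram matrix.

    Scores are eigenvector columns scaled by the square root of their
    eigenvalue; variance fractions are relative to the centered-kernel
    trace.  Small negative eigenvalues from numerical round-off are
    clipped to zero with a warning.
    """
    data = _as_matrix(x)
    n = data.shape[0]
    if n < 2:
        raise DataError("kpca needs at least 2 samples")
    if kernel is None:
        kernel = KernelSpec("rbf", None)
    if kernel.name == "rbf" and kernel.bandwidth is None:
        kernel = KernelSpec("rbf", median_pairwise_distance(data))
    kmax = n - 1
    if k is None:
        k = kmax
    if not (1 <= k <= kmax):
        raise ConfigError(f"k must be in [1, {kmax}], got {k}")
    gram = kernel.gram(data, data)
    one = np.full((n, n), 1.0 / n)
    kc = gram - one @ gram - gram @ one + one @ gram @ one
    eig, vec = np.linalg.eigh(kc)
    eig, vec = eig[::-1].copy(), vec[:, ::-1].copy()
    if np.any(eig < -1e-8 * max(1.0, abs(eig[0]))):
        warnings.warn(
            "kernel matrix has negative eigenvalues beyond round-off; "
            "clipping to zero", RuntimeWarning, stacklevel=2,
        )
    eig = np.clip(eig, 0.0, None)
    total = eig.sum()
    for j in range(vec.shape[1]):
        i = np.argmax(np.abs(vec[:, j]))
        if vec[i, j] < 0:
            vec[:, j] *= -1
    scores = vec[:, :k] * np.sqrt(eig[:k])[None, :]
    return PCAResult(
        scores=scores,
        loadings=vec[:, :k],
        eigenvalues=eig[:k],
        variance_explained=eig[:k] / total if total > 0 else np.zeros(k),
    )


# ---------------------------------------------------------------------------
# discriminant analysis
# ---------------------------------------------------------------------------

def _class_partition(labels: Sequence[str]):
    classes = sorted(set(labels))
    idx = {c: np.flatnonzero(np.array(labels) == c) for c in classes}
    return classes, idx


def _check_classes(classes, idx, allow_drop_singletons=False):
    kept = []
    for c in classes:
        if len(idx[c]) < 2:
            if allow_drop_singletons:
                warnings.warn(
                    f"class {c!r} has a single sample in this training set; "
                    "dropped from the fold", RuntimeWarning, stacklevel=3,
                )
                continue
            raise DataError(
                f"class {c!r} has {len(idx[c])} sample(s); discriminant "
                "training needs at least 2 per class"
            )
        kept.append(c)
    if len(kept) < 2:
        raise DataError("discriminant training needs at least 2 usable classes")
    return kept


def _solve_gevp(between: np.ndarray, within: np.ndarray, n_dirs: int):
    """Top eigenpairs of between @ v = eig * within @ v (within SPD)."""
    eig, vec = scipy.linalg.eigh(between, within)
    order = np.argsort(eig)[::-1][:n_dirs]
    return np.clip(eig[order], 0.0, None), vec[:, order]


def train_discriminant(
    x: ArrayLike,
    labels: Optional[Sequence[str]] = None,
    method: Method | str = Method.LDA,
    kernel: Optional[KernelSpec] = None,
    regularization: Optional[float] = None,
    _allow_drop_singletons: bool = False,
) -> DiscriminantModel:
    """Fit Fisher LDA or kernel discriminant analysis (KDA).

    Features are standardized (zero mean, unit variance per variable) and
    the standardization is stored in the model so prediction applies it
    identically.  ``regularization`` defaults to
    ``1e-3 * trace(within-scatter) / dim``; pass 0 to disable (requires a
    non-singular within-class scatter).
    """
    method = Method(method)
    data = _as_matrix(x)
    labels = _get_labels(x, labels)
    if len(labels) != data.shape[0]:
        raise DataError("labels length must equal sample count")
    classes, idx = _class_partition(labels)
    classes = _check_classes(classes, idx, _allow_drop_singletons)
    keep_rows = np.concatenate([idx[c] for c in classes])
    keep_rows.sort()
    data = data[keep_rows]
    labels = [labels[i] for i in keep_rows]
    classes, idx = _class_partition(labels)
    if regularization is not None and regularization < 0:
        raise ConfigError("regularization must be >= 0")

    scaler = Standardizer.fit(data)
    z = scaler(data)
    n, p = z.shape
    n_dirs = len(classes) - 1

    if method is Method.LDA:
        grand = z.mean(axis=0)
        sw = np.zeros((p, p))
        sb = np.zeros((p, p))
        for c in classes:
            zc = z[idx[c]]
            mc = zc.mean(axis=0)
            d = zc - mc
            sw += d.T @ d
            diff = (mc - grand)[:, None]
            sb += len(zc) * (diff @ diff.T)
        lam = (RIDGE_SCALE * np.trace(sw) / p
               if regularization is None else regularization)
        if lam == 0:
            try:
                np.linalg.cholesky(sw)
            except np.linalg.LinAlgError:
                raise DataError(
                    "within-class scatter is singular with regularization 0; "
                    "set regularization > 0"
                )
        eig, vec = _solve_gevp(sb, sw + lam * np.eye(p), min(n_dirs, p))
        model = DiscriminantModel(
            method=method, classes=classes, scaling=scaler,
            regularization=lam, eigenvalues=eig, projection_vectors=vec,
        )
        proj = z @ vec
    else:
        if kernel is None:
            kernel = KernelSpec("rbf", None)
        if kernel.name == "rbf" and kernel.bandwidth is None:
            kernel = KernelSpec("rbf", median_pairwise_distance(z))
        gram = kernel.gram(z, z)
        # between-class scatter of kernel row-means; within = K L K with
        # L = I - block-diagonal(1/n_c) (class-wise centering)
        m_all = gram.mean(axis=1)
        between = np.zeros((n, n))
        ell = np.eye(n)
        for c in classes:
            rows = idx[c]
            mc = gram[:, rows].mean(axis=1)
            diff = (mc - m_all)[:, None]
            between += len(rows) * (diff @ diff.T)
            ell[np.ix_(rows, rows)] -= 1.0 / len(rows)
        within = gram @ ell @ gram
        lam = (RIDGE_SCALE * np.trace(within) / n
               if regularization is None else regularization)
        if lam == 0:
            raise DataError(
                "kernel within-class scatter is always rank-deficient; "
                "set regularization > 0"
            )
        eig, alpha = _solve_gevp(between, within + lam * np.eye(n), n_dirs)
        model = DiscriminantModel(
            method=method, classes=classes, scaling=scaler,
            regularization=lam, eigenvalues=eig, kernel=kernel,
            training_features=z, dual_coefficients=alpha,
        )
        proj = gram @ alpha

    centroids = np.vstack([proj[idx[c]].mean(axis=0) for c in classes])
    model.class_centroids = centroids
    return model


def predict(model: DiscriminantModel, sample: np.ndarray):
    """Functional alias for :meth:`DiscriminantModel.predict`."""
    return model.predict(sample)


def loocv(
    x: ArrayLike,
    labels: Optional[Sequence[str]] = None,
    method: Method | str = Method.KDA,
    kernel: Optional[KernelSpec] = None,
    regularization: Optional[float] = None,
) -> LoocvResult:
    """Leave-one-out cross-validation of the discriminant classifier.

    Every fold refits the entire model — standardization, kernel bandwidth
    and discriminant directions — on the remaining ``n - 1`` samples, then
    classifies the held-out one.  When removing a sample leaves its class
    with a single member, that fold trains without the singleton class
    (with a warning) and the held-out sample is predicted from the
    remaining classes' model.
    """
    data = _as_matrix(x)
    labels = _get_labels(x, labels)
    if len(labels) != data.shape[0]:
        raise DataError("labels length must equal sample count")
    classes, idx = _class_partition(labels)
    _check_classes(classes, idx)
    n = data.shape[0]
    predicted = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = train_discriminant(
            data[mask], [l for j, l in enumerate(labels) if j != i],
            method=method, kernel=kernel, regularization=regularization,
            _allow_drop_singletons=True,
        )
        label, _ = model.predict(data[i])
        predicted.append(label)
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    pos = {c: j for j, c in enumerate(classes)}
    correct = 0
    for t, p_ in zip(labels, predicted):
        confusion[pos[t], pos[p_]] += 1
        if t == p_:
            correct += 1
    return LoocvResult(
        predicted=predicted,
        truth=list(labels),
        percent_correct=100.0 * correct / n,
        confusion=confusion,
        classes=classes,
    )
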