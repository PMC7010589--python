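"""Kernel PCA on the SPD manifold of regularized connectome Laplacians.

The Riemann kernel between two subjects is a Gaussian function of the
log-Euclidean distance between their regularized graph Laplacians,

    K_ij = exp(-d_logE(Li, Lj)^2 / (2 sigma^2)),

which is a valid (PSD) kernel because the matrix-log embedding is an isometry
into Euclidean space.  Kernel PCA eigendecomposes the double-centered kernel
matrix K_c = J K J (J = I - 1/m), keeps the n' leading components, and scores
subjects by projecting onto the unit-norm feature-space axes (coefficients
alpha_tilde = alpha / sqrt(lambda) with alpha an orthonormal eigenvector).

Two baselines with the identical fit/transform contract are provided for
method comparison: plain linear PCA on vectorized (upper-triangle) FC entries
and a Euclidean-Gaussian kernel PCA on the same vectors.  The Gaussian
baseline shares this module's kernel-PCA code path — only the embedding in
which distances are measured differs.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .core import (ConnectivityMatrix, RegularizedLaplacian,
                   laplacian_from_fc, matrix_log)

__all__ = [
    "RiemannKernelPCA",
    "EuclideanGaussianKernelPCA",
    "LinearPCAModel",
    "kernel_matrix",
    "default_sigma",
    "upper_triangle",
    "save_model",
    "load_model",
]

EIGENVALUE_FLOOR_RATIO = 1e-10


def upper_triangle(matrix: np.ndarray) -> np.ndarray:
    """Strict upper-triangle entries of a square matrix as a vector."""
    matrix = np.asarray(matrix, dtype=float)
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def _as_spd_array(item) -> np.ndarray:
    if isinstance(item, RegularizedLaplacian):
        return item.values
    return np.asarray(item, dtype=float)


def _logs_from_inputs(inputs, gamma: float, weight_transform: str
                      ) -> np.ndarray:
    """Matrix logs of the inputs' regularized Laplacians, shape (m, k, k).

    Accepts ConnectivityMatrix (FC -> Laplacian -> log), RegularizedLaplacian,
    or plain SPD arrays (logged directly).
    """
    logs = []
    for item in inputs:
        if isinstance(item, ConnectivityMatrix):
            item = laplacian_from_fc(item, gamma, weight_transform)
        logs.append(matrix_log(_as_spd_array(item)))
    return np.stack(logs)


def _spread_sigma(stacked: np.ndarray) -> float:
    """Spread of a set of matrices: sqrt of summed per-entry variances.

    Equals the RMS Frobenius distance of the matrices to their mean (up to
    the ddof=1 correction), so typical pairwise squared distances are about
    2 sigma^2 and the Gaussian kernel stays well scaled whatever the
    embedding's overall magnitude.
    """
    flat = stacked.reshape(stacked.shape[0], -1)
    sigma = float(np.sqrt(flat.var(axis=0, ddof=1).sum()))
    # identical inputs can still leave O(eps) variance; treat as degenerate
    if sigma <= 1e-12 * (np.abs(flat).max() + 1.0):
        return 0.0
    return sigma


def default_sigma(inputs, gamma: float = 1.0, weight_transform: str = "abs",
                  space: str = "log") -> float:
    """Default kernel bandwidth: the standard deviation of the matrix set.

    The best bandwidth sits near the spread of the distribution of matrices;
    that spread is measured as the square root of the summed across-subject
    entry variances (the RMS distance of subjects to the mean matrix), by
    default in the matrix-log embedding where the kernel's distances live
    (``space="raw"`` uses the raw matrices instead).
    """
    if len(inputs) < 2:
        raise ValueError("need at least 2 subjects to estimate sigma")
    if space == "log":
        stacked = _logs_from_inputs(inputs, gamma, weight_transform)
    elif space == "raw":
        stacked = np.stack([
            item.values if isinstance(item,
                                      (ConnectivityMatrix,
                                       RegularizedLaplacian))
            else np.asarray(item, dtype=float)
            for item in inputs
        ])
    else:
        raise ValueError("space must be 'log' or 'raw'")
    sigma = _spread_sigma(stacked)
    if sigma <= 0:
        raise ValueError(
            "all matrices are identical (zero entry variance); set sigma "
            "manually"
        )
    return sigma


def kernel_matrix(inputs, sigma: float, gamma: float = 1.0,
                  weight_transform: str = "abs") -> np.ndarray:
    """Riemann kernel matrix K_ij = exp(-d_logE^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    logs = _logs_from_inputs(inputs, gamma, weight_transform)
    flat = logs.reshape(len(logs), -1)
    d2 = cdist(flat, flat, metric="sqeuclidean")
    K = np.exp(-d2 / (2.0 * sigma ** 2))
    np.fill_diagonal(K, 1.0)
    return 0.5 * (K + K.T)


class _GaussianKernelPCABase:
    """Gaussian-kernel PCA on an embedding supplied by subclasses.

    Subclasses implement :meth:`_embed`, mapping a list of subjects to an
    (m, d) array in which squared Euclidean distances equal the model's
    squared kernel distances.
    """

    def __init__(self, sigma: float | str = "auto",
                 n_components: int | str = "auto",
                 variance_fraction: float = 0.95):
        if isinstance(sigma, (int, float)) and sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {sigma}")
        self.sigma = sigma
        self.n_components = n_components
        self.variance_fraction = variance_fraction

    def _embed(self, inputs, training: bool = False
               ) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def is_fitted(self) -> bool:
        return hasattr(self, "alphas_")

    def fit(self, inputs) -> "_GaussianKernelPCABase":
        X = self._embed(inputs, training=True)
        m = X.shape[0]
        if m < 2:
            raise ValueError("need at least 2 subjects to fit")
        self.train_embeddings_ = X
        if self.sigma == "auto":
            sigma = _spread_sigma(X)
            if sigma <= 0:
                raise ValueError(
                    "all training matrices are identical; set sigma manually"
                )
        else:
            sigma = float(self.sigma)
        self.sigma_ = sigma

        d2 = cdist(X, X, metric="sqeuclidean")
        K = np.exp(-d2 / (2.0 * sigma ** 2))
        K = 0.5 * (K + K.T)
        self.kernel_row_means_ = K.mean(axis=0)
        self.kernel_grand_mean_ = float(K.mean())
        Kc = (K - self.kernel_row_means_[None, :]
              - self.kernel_row_means_[:, None] + self.kernel_grand_mean_)

        w, V = np.linalg.eigh(Kc)
        w, V = w[::-1], V[:, ::-1]
        floor = EIGENVALUE_FLOOR_RATIO * max(w[0], 0.0)
        available = int(np.sum(w > floor))
        if available == 0:
            raise ValueError(
                "centered kernel has no positive eigenvalues (all training "
                "matrices identical?)"
            )
        if self.n_components == "auto":
            total = w[:available].sum()
            cum = np.cumsum(w[:available]) / total
            n_comp = int(np.searchsorted(cum, self.variance_fraction) + 1)
            n_comp = min(n_comp, m - 1, available)
        else:
            n_comp = int(self.n_components)
            if not 1 <= n_comp <= m - 1:
                raise ValueError(
                    f"n_components must be in [1, m-1] = [1, {m - 1}]"
                )
            if n_comp > available:
                warnings.warn(
                    f"requested {n_comp} components but only {available} "
                    f"have eigenvalue > {EIGENVALUE_FLOOR_RATIO:g} * max; "
                    f"reducing to {available}",
                    stacklevel=2,
                )
                n_comp = available
        self.eigenvalues_ = w[:n_comp].copy()
        self.alphas_ = V[:, :n_comp] / np.sqrt(w[:n_comp])
        self.n_components_ = n_comp
        self.training_scores_ = Kc @ self.alphas_
        return self

    def _kernel_to_train(self, X_new: np.ndarray) -> np.ndarray:
        d2 = cdist(X_new, self.train_embeddings_, metric="sqeuclidean")
        return np.exp(-d2 / (2.0 * self.sigma_ ** 2))

    def transform(self, inputs) -> np.ndarray:
        """Project subjects onto the fitted components; (n, n') scores."""
        if not self.is_fitted:
            raise RuntimeError("model is not fitted")
        X_new = self._embed(inputs)
        if X_new.shape[1] != self.train_embeddings_.shape[1]:
            raise ValueError(
                f"dimension mismatch: new subjects embed to "
                f"{X_new.shape[1]} entries, training used "
                f"{self.train_embeddings_.shape[1]}"
            )
        K_new = self._kernel_to_train(X_new)
        Kc = (K_new - K_new.mean(axis=1, keepdims=True)
              - self.kernel_row_means_[None, :] + self.kernel_grand_mean_)
        return Kc @ self.alphas_


class RiemannKernelPCA(_GaussianKernelPCABase):
    """Kernel PCA with the log-Euclidean Riemann kernel on Laplacians.

    Parameters
    ----------
    sigma:
        Kernel bandwidth, or ``"auto"`` for the SD of all matrix-log entries
        of the training set.
    gamma:
        SPD regularization added to each graph Laplacian (> 0).
    n_components:
        Number of components to keep, or ``"auto"`` for the smallest number
        capturing ``variance_fraction`` of the centered-kernel trace (capped
        at m - 1).
    weight_transform:
        How signed correlations become nonnegative edge weights
        (``"abs"`` or ``"clip_negative"``).
    """

    def __init__(self, sigma: float | str = "auto", gamma: float = 1.0,
                 n_components: int | str = "auto",
                 weight_transform: str = "abs",
                 variance_fraction: float = 0.95):
        super().__init__(sigma, n_components, variance_fraction)
        if gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {gamma}")
        self.gamma = gamma
        self.weight_transform = weight_transform

    def _embed(self, inputs, training: bool = False) -> np.ndarray:
        logs = _logs_from_inputs(inputs, self.gamma, self.weight_transform)
        if training:
            self.train_logs_ = logs
        return logs.reshape(len(logs), -1)

    @property
    def matrix_dim(self) -> int:
        return self.train_logs_.shape[1]


class EuclideanGaussianKernelPCA(_GaussianKernelPCABase):
    """Baseline: Gaussian-kernel PCA on vectorized upper-triangle FC entries.

    Identical code path to :class:`RiemannKernelPCA`; only the embedding (and
    hence the distance) differs.
    """

    def _embed(self, inputs, training: bool = False) -> np.ndarray:
        return np.stack([
            upper_triangle(item.values if isinstance(item, ConnectivityMatrix)
                           else item)
            for item in inputs
        ])


class LinearPCAModel:
    """Baseline: linear PCA on vectorized upper-triangle FC entries.

    Same fit/transform contract as the kernel models; backed by
    :class:`sklearn.decomposition.PCA`.
    """

    def __init__(self, n_components: int | str = "auto",
                 variance_fraction: float = 0.95):
        self.n_components = n_components
        self.variance_fraction = variance_fraction

    def _embed(self, inputs, training: bool = False) -> np.ndarray:
        return np.stack([
            upper_triangle(item.values if isinstance(item, ConnectivityMatrix)
                           else item)
            for item in inputs
        ])

    def fit(self, inputs) -> "LinearPCAModel":
        X = self._embed(inputs)
        if self.n_components == "auto":
            n_comp = self.variance_fraction  # sklearn: variance fraction
        else:
            n_comp = int(self.n_components)
        self.pca_ = PCA(n_components=n_comp, svd_solver="full").fit(X)
        self.n_components_ = self.pca_.n_components_
        self.eigenvalues_ = self.pca_.explained_variance_.copy()
        self.training_scores_ = self.pca_.transform(X)
        return self

    def transform(self, inputs) -> np.ndarray:
        return self.pca_.transform(self._embed(inputs))

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return self.pca_.inverse_transform(scores)


MODEL_FORMAT_VERSION = 1


def save_model(path: str | Path, model: RiemannKernelPCA) -> Path:
    """Serialize a fitted Riemann kernel-PCA model to a ``.npz`` archive."""
    if not model.is_fitted:
        raise RuntimeError("cannot save an unfitted model")
    path = Path(path)
    np.savez(
        path,
        format_version=MODEL_FORMAT_VERSION,
        train_logs=model.train_logs_,
        alphas=model.alphas_,
        eigenvalues=model.eigenvalues_,
        training_scores=model.training_scores_,
        kernel_row_means=model.kernel_row_means_,
        kernel_grand_mean=model.kernel_grand_mean_,
        sigma=model.sigma_,
        gamma=model.gamma,
        weight_transform=model.weight_transform,
    )
    return path if path.suffix == ".npz" else Path(str(path) + ".npz")


def load_model(path: str | Path) -> RiemannKernelPCA:
    """Load a model saved by :func:`save_model`."""
    with np.load(path, allow_pickle=False) as data:
        version = int(data["format_version"])
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {version}; expected "
                f"{MODEL_FORMAT_VERSION}"
            )
        model = RiemannKernelPCA(
            sigma=float(data["sigma"]),
            gamma=float(data["gamma"]),
            weight_transform=str(data["weight_transform"]),
        )
        model.train_logs_ = data["train_logs"]
        model.train_embeddings_ = model.train_logs_.reshape(
            len(model.train_logs_), -1)
        model.alphas_ = data["alphas"]
        model.eigenvalues_ = data["eigenvalues"]
        model.training_scores_ = data["training_scores"]
        model.kernel_row_means_ = data["kernel_row_means"]
        model.kernel_grand_mean_ = float(data["kernel_grand_mean"])
        model.sigma_ = float(data["sigma"])
        model.n_components_ = model.alphas_.shape[1]
    return model
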