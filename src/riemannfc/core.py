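"""Connectome geometry: Pearson FC, graph Laplacians, SPD regularization,
matrix logarithms and the log-Euclidean metric.

A subject's functional connectome is a symmetric k x k matrix of Pearson
correlations between ROI time series.  The classification pipeline does not
operate on these matrices directly: each connectome is first turned into a
graph Laplacian L = D - W (W the nonnegative edge-weight matrix, D its degree
matrix), then shifted to L + gamma*I so it is symmetric positive definite
(SPD).  SPD matrices form a Riemannian manifold on which the log-Euclidean
distance

    d(S1, S2) = || logm(S1) - logm(S2) ||_F

is a true metric; every kernel downstream is a Gaussian function of this
distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "RegularizedLaplacian",
    "NotSPDError",
    "fc_from_timeseries",
    "graph_laplacian",
    "regularize",
    "laplacian_from_fc",
    "matrix_log",
    "matrix_exp",
    "log_euclidean_distance",
]

SYMMETRY_TOL = 1e-10

WEIGHT_TRANSFORMS = ("abs", "clip_negative")


class NotSPDError(ValueError):
    """Input matrix is not symmetric positive definite."""


def _check_square(values: np.ndarray, name: str = "matrix") -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{name} must be square, got shape {values.shape}")
    return values


def _check_symmetric(values: np.ndarray, tol: float = SYMMETRY_TOL,
                     name: str = "matrix") -> np.ndarray:
    values = _check_square(values, name)
    asym = np.abs(values - values.T).max() if values.size else 0.0
    if asym > tol:
        raise ValueError(
            f"{name} is not symmetric: max |S - S^T| = {asym:.3e} > {tol:g}"
        )
    return 0.5 * (values + values.T)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric k x k Pearson correlation matrix with unit diagonal.

    ``roi_labels`` defaults to generic ``ROI_000 ...`` names sized to the
    matrix; pass :data:`riemannfc.atlas.AAL116_LABELS` for AAL-parcellated
    data.
    """

    values: np.ndarray
    roi_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = _check_symmetric(np.asarray(self.values, dtype=float),
                                  name="connectivity matrix")
        if np.abs(np.diag(values) - 1.0).max() > 1e-8:
            raise ValueError("connectivity matrix diagonal must be 1")
        np.fill_diagonal(values, 1.0)
        if np.abs(values).max() > 1.0 + 1e-8:
            raise ValueError(
                "correlations must lie in [-1, 1]; max |r| = "
                f"{np.abs(values).max():.6f}"
            )
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        labels = tuple(self.roi_labels) or tuple(
            f"ROI_{i:03d}" for i in range(values.shape[0])
        )
        if len(labels) != values.shape[0]:
            raise ValueError(
                f"{len(labels)} ROI labels for a {values.shape[0]}-ROI matrix"
            )
        object.__setattr__(self, "roi_labels", labels)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class RegularizedLaplacian:
    """SPD matrix L + gamma*I derived from a connectivity matrix.

    ``weight_transform`` records how negative correlations were made
    nonnegative before the Laplacian was formed ("abs" or "clip_negative").
    """

    values: np.ndarray
    gamma: float
    weight_transform: str = "abs"

    def __post_init__(self) -> None:
        values = _check_symmetric(np.asarray(self.values, dtype=float),
                                  name="regularized Laplacian")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.weight_transform not in WEIGHT_TRANSFORMS:
            raise ValueError(
                f"weight_transform must be one of {WEIGHT_TRANSFORMS}"
            )
        lam_min = float(np.linalg.eigvalsh(values)[0])
        if lam_min < self.gamma - 1e-8:
            raise NotSPDError(
                f"smallest eigenvalue {lam_min:.3e} below gamma - 1e-8 "
                f"(gamma = {self.gamma})"
            )
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def fc_from_timeseries(series: np.ndarray,
                       roi_labels: tuple[str, ...] | list[str] = (),
                       ) -> ConnectivityMatrix:
    """Pearson functional connectivity of a T x k ROI time-series array.

    Raises
    ------
    ValueError
        If T < 3 or any ROI's series is constant (correlation undefined).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError(f"expected a T x k array, got shape {series.shape}")
    T, k = series.shape
    if T < 3:
        raise ValueError(f"need at least 3 time points, got {T}")
    sd = series.std(axis=0)
    constant = np.nonzero(sd == 0)[0]
    if constant.size:
        raise ValueError(
            f"constant time series for ROI index {int(constant[0])}: "
            "Pearson correlation undefined"
        )
    r = np.corrcoef(series, rowvar=False)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, tuple(roi_labels))


def graph_laplacian(A: ConnectivityMatrix | np.ndarray,
                    weight_transform: str = "abs") -> np.ndarray:
    """Graph Laplacian L = D - W of a connectivity matrix.

    Self-loops are removed (diagonal zeroed) and signed correlations are made
    nonnegative: ``"abs"`` takes |r| (keeps connection magnitude),
    ``"clip_negative"`` sets negative r to 0.  The result is symmetric
    positive semidefinite with zero row sums.
    """
    if weight_transform not in WEIGHT_TRANSFORMS:
        raise ValueError(f"weight_transform must be one of {WEIGHT_TRANSFORMS}")
    values = A.values if isinstance(A, ConnectivityMatrix) else \
        _check_symmetric(np.asarray(A, dtype=float), name="adjacency")
    W = np.array(values, dtype=float)
    np.fill_diagonal(W, 0.0)
    W = np.abs(W) if weight_transform == "abs" else np.clip(W, 0.0, None)
    L = np.diag(W.sum(axis=1)) - W
    return 0.5 * (L + L.T)


def regularize(L: np.ndarray, gamma: float = 1.0,
               weight_transform: str = "abs") -> RegularizedLaplacian:
    """Shift a PSD Laplacian to the SPD matrix L + gamma*I (gamma > 0)."""
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    L = _check_symmetric(np.asarray(L, dtype=float), name="Laplacian")
    return RegularizedLaplacian(L + gamma * np.eye(L.shape[0]), gamma,
                                weight_transform)


def laplacian_from_fc(A: ConnectivityMatrix, gamma: float = 1.0,
                      weight_transform: str = "abs") -> RegularizedLaplacian:
    """FC matrix -> graph Laplacian -> SPD regularization, in one step."""
    return regularize(graph_laplacian(A, weight_transform), gamma,
                      weight_transform)


def matrix_log(S: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Principal matrix logarithm of an SPD matrix via eigendecomposition."""
    S = _check_symmetric(np.asarray(S, dtype=float), name="SPD matrix")
    w, U = np.linalg.eigh(S)
    if w[0] <= tol:
        raise NotSPDError(
            f"matrix is not positive definite: smallest eigenvalue "
            f"{w[0]:.3e} <= {tol:g}"
        )
    out = (U * np.log(w)) @ U.T
    return 0.5 * (out + out.T)


def matrix_exp(S: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix via eigendecomposition."""
    S = _check_symmetric(np.asarray(S, dtype=float), name="symmetric matrix")
    w, U = np.linalg.eigh(S)
    out = (U * np.exp(w)) @ U.T
    return 0.5 * (out + out.T)


def log_euclidean_distance(S1: np.ndarray | RegularizedLaplacian,
                           S2: np.ndarray | RegularizedLaplacian) -> float:
    """Log-Euclidean distance ||logm(S1) - logm(S2)||_F between SPD matrices."""
    a = S1.values if isinstance(S1, RegularizedLaplacian) else np.asarray(S1)
    b = S2.values if isinstance(S2, RegularizedLaplacian) else np.asarray(S2)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(matrix_log(a) - matrix_log(b), "fro"))
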