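"""Pre-image reconstruction: classifier importance back to brain edges.

The boosted-tree importances live in kernel-PCA component space; mapping
them back to an importance over ROI-ROI connections is a kernel-PCA
pre-image problem.  The component importances beta define a feature-space
element through the retained principal axes; its pre-image is found by the
classical Gaussian-kernel fixed-point iteration, transported to the SPD
manifold: the iterate is a weighted log-Euclidean Frechet mean of the
training Laplacians,

    log L_new = sum_i c_i k_i log L_i / sum_i c_i k_i,
    k_i = exp(-||log L_old - log L_i||_F^2 / (2 sigma^2)),

exponentiated once at convergence.  The expansion coefficients are
c_i = delta_i + (1 - sum(delta)) / m with delta = alpha_tilde @ beta; the
additive term re-attaches the feature-space mean removed by kernel
centering, which is what makes reconstruction from a training subject's own
feature vector return that subject's Laplacian at full rank.

Because the reconstruction is a weighted mean of subject Laplacians it sits
near the cohort's common connectivity structure; the discriminative signal
is its *deviation* from the unweighted Frechet mean, which is what
``baseline="mean"`` reports (and what edge ranking should consume).  Tree
importances are nonnegative, so the direction of each group difference is
lost in reconstruction; :func:`rank_edges` re-attaches it as the empirical
patient-minus-control mean FC difference per edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ComponentImportance
from .core import ConnectivityMatrix, matrix_exp
from .kpca import RiemannKernelPCA

__all__ = [
    "ImportanceMap",
    "importance_to_beta",
    "reconstruct",
    "edge_importance",
    "rank_edges",
]


@dataclass(frozen=True)
class ImportanceMap:
    """Symmetric k x k edge-importance matrix (diagonal 0 by convention)."""

    values: np.ndarray
    roi_labels: tuple[str, ...] = ()
    converged: bool = True
    n_iterations: int = 0
    objective: float = float("nan")
    baseline: str = "none"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("importance map must be square")
        if not np.isfinite(values).all():
            raise ValueError("importance map contains non-finite entries")
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 0.0)
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        labels = tuple(self.roi_labels) or tuple(
            f"ROI_{i:03d}" for i in range(values.shape[0])
        )
        if len(labels) != values.shape[0]:
            raise ValueError("one ROI label per row required")
        object.__setattr__(self, "roi_labels", labels)


def importance_to_beta(comp_importance: ComponentImportance | np.ndarray,
                       model: RiemannKernelPCA | None = None,
                       signed: bool = False,
                       labels: np.ndarray | None = None) -> np.ndarray:
    """Embed per-component importances as the coordinate vector beta.

    The embedding is the identity; with ``signed=True`` each component's
    importance is additionally signed by the point-biserial correlation of
    that component's training scores with the class label (requires ``model``
    and ``labels``), restoring a direction that nonnegative tree importances
    discard.
    """
    beta = np.asarray(
        comp_importance.values
        if isinstance(comp_importance, ComponentImportance)
        else comp_importance, dtype=float).copy()
    if model is not None and len(beta) != model.n_components_:
        raise ValueError(
            f"importance length {len(beta)} != model components "
            f"{model.n_components_}"
        )
    if signed:
        if model is None or labels is None:
            raise ValueError("signed=True requires model and labels")
        y = np.asarray(labels, dtype=float)
        scores = model.training_scores_
        for j in range(scores.shape[1]):
            r = np.corrcoef(scores[:, j], y)[0, 1]
            beta[j] *= np.sign(r) if np.isfinite(r) and r != 0 else 1.0
    return beta


def _frechet_log_mean(logs: np.ndarray, weights: np.ndarray) -> np.ndarray:
    w = weights / weights.sum()
    return np.tensordot(w, logs, axes=1)


def reconstruct(model: RiemannKernelPCA, beta: np.ndarray,
                max_iter: int = 500, tol: float = 1e-6,
                n_restarts: int = 5, seed: int = 0,
                baseline: str = "none",
                centered: bool = True) -> ImportanceMap:
    """Fixed-point pre-image of the feature-space element defined by beta.

    Returns the restart with the best objective (the kernel correlation
    ``sum_i c_i k(z, L_i)`` that the pre-image maximizes).  Off-diagonals of
    the recovered matrix are reported as edge importances with the sign
    flipped to adjacency convention (Laplacian off-diagonals are -w_ij).
    ``baseline="mean"`` subtracts the unweighted log-Euclidean mean
    reconstruction, isolating the component-driven deviation from the
    cohort-common structure.  ``centered=False`` drops the kernel-centering
    correction and uses the raw delta weights (the classical uncentered
    update, which is invariant to rescaling beta).
    """
    if not model.is_fitted:
        raise RuntimeError("model is not fitted")
    if baseline not in ("none", "mean"):
        raise ValueError("baseline must be 'none' or 'mean'")
    beta = np.asarray(beta, dtype=float)
    if beta.ndim != 1 or len(beta) != model.n_components_:
        raise ValueError(
            f"beta must have length n_components = {model.n_components_}"
        )
    if not np.isfinite(beta).all():
        raise ValueError("beta contains non-finite entries")
    if np.all(beta == 0):
        raise ValueError(
            "beta is identically zero; reconstruction is degenerate"
        )

    logs = model.train_logs_
    m = logs.shape[0]
    sigma2 = 2.0 * model.sigma_ ** 2
    delta = model.alphas_ @ beta
    if centered:
        coeff = delta + (1.0 - delta.sum()) / m
    else:
        coeff = delta

    rng = np.random.default_rng(seed)

    def objective(Z: np.ndarray) -> float:
        d2 = ((logs - Z) ** 2).sum(axis=(1, 2))
        return float(coeff @ np.exp(-d2 / sigma2))

    best = None
    for restart in range(max(1, n_restarts)):
        init_w = np.abs(coeff) + 1e-12
        if restart > 0:
            init_w = init_w * np.exp(rng.normal(0.0, 0.5, m))
        Z = _frechet_log_mean(logs, init_w)
        obj = objective(Z)
        converged = False
        iterations = 0
        failed = False
        for iterations in range(1, max_iter + 1):
            d2 = ((logs - Z) ** 2).sum(axis=(1, 2))
            w = coeff * np.exp(-d2 / sigma2)
            s = w.sum()
            if abs(s) < 1e-12:
                failed = True
                break
            Z_new = np.tensordot(w / s, logs, axes=1)
            obj_new = objective(Z_new)
            # damp steps that decrease the objective (fixed point should
            # behave as a contraction; damping guards rare overshoots)
            damp = 0
            while obj_new < obj - 1e-14 and damp < 8:
                Z_new = 0.5 * (Z + Z_new)
                obj_new = objective(Z_new)
                damp += 1
            step = np.linalg.norm(Z_new - Z, "fro")
            scale = max(1.0, np.linalg.norm(Z, "fro"))
            Z, obj = Z_new, obj_new
            if step / scale <= tol:
                converged = True
                break
        if failed:
            continue
        if best is None or obj > best[0]:
            best = (obj, Z, converged, iterations)

    if best is None:
        raise ValueError(
            "all restarts collapsed to a near-zero weight-sum denominator; "
            "the signed expansion coefficients cancel — consider "
            "importance_to_beta(..., signed=True) or fewer components"
        )
    obj, Z, converged, iterations = best
    if not converged:
        import warnings
        warnings.warn(
            f"pre-image iteration did not converge within {max_iter} "
            "iterations; returning the best iterate",
            stacklevel=2,
        )

    recon = matrix_exp(Z)
    adjacency = -recon.copy()
    np.fill_diagonal(adjacency, 0.0)
    if baseline == "mean":
        ref = matrix_exp(_frechet_log_mean(logs, np.ones(m)))
        ref_adj = -ref
        np.fill_diagonal(ref_adj, 0.0)
        adjacency = adjacency - ref_adj
    return ImportanceMap(values=adjacency, converged=converged,
                         n_iterations=iterations, objective=obj,
                         baseline=baseline)


def edge_importance(model: RiemannKernelPCA,
                    comp_importance: ComponentImportance,
                    signed: bool = False,
                    labels: np.ndarray | None = None,
                    roi_labels: tuple[str, ...] = (),
                    **reconstruct_kwargs) -> ImportanceMap:
    """End-to-end: component importances -> edge importance map.

    Reconstructs with ``baseline="mean"`` so the map measures deviation from
    the cohort-common structure along the discriminative components.
    """
    beta = importance_to_beta(comp_importance, model, signed=signed,
                              labels=labels)
    reconstruct_kwargs.setdefault("baseline", "mean")
    imap = reconstruct(model, beta, **reconstruct_kwargs)
    if roi_labels:
        imap = ImportanceMap(values=imap.values, roi_labels=roi_labels,
                             converged=imap.converged,
                             n_iterations=imap.n_iterations,
                             objective=imap.objective,
                             baseline=imap.baseline)
    return imap


def rank_edges(imp_map: ImportanceMap, top_n: int | None = None,
               fc_matrices: list[ConnectivityMatrix] | None = None,
               groups: np.ndarray | None = None,
               positive_label: str = "patient") -> pd.DataFrame:
    """Rank edges by absolute importance (descending, lexicographic ties).

    If per-subject FC matrices and group labels are supplied, each edge also
    carries ``group_delta`` = mean FC(positive group) - mean FC(other), the
    empirical direction of the group difference.
    """
    k = imp_map.values.shape[0]
    deltas = None
    if fc_matrices is not None and groups is not None:
        groups = np.asarray(groups).astype(str)
        stack = np.stack([m.values for m in fc_matrices])
        pos = groups == str(positive_label)
        if pos.sum() == 0 or (~pos).sum() == 0:
            raise ValueError(
                f"group label {positive_label!r} must split subjects into "
                "two nonempty groups"
            )
        deltas = stack[pos].mean(axis=0) - stack[~pos].mean(axis=0)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            rows.append({
                "roi_i": i, "roi_j": j,
                "roi_i_label": imp_map.roi_labels[i],
                "roi_j_label": imp_map.roi_labels[j],
                "importance": imp_map.values[i, j],
                "group_delta": (float(deltas[i, j]) if deltas is not None
                                else float("nan")),
            })
    df = pd.DataFrame(rows)
    df["abs_importance"] = df["importance"].abs()
    df = df.sort_values(["abs_importance", "roi_i", "roi_j"],
                        ascending=[False, True, True], kind="mergesort")
    df = df.drop(columns="abs_importance").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.head(top_n) if top_n is not None else df
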