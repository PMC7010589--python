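"""Seed-based connectivity statistics.

A seed map correlates a seed region's mean time series with every other unit
(ROI or voxel-grid cell) and variance-stabilizes the correlations with the
Fisher-Z transform z = atanh(r).  Group differences are then tested per unit
with an ordinary least-squares model

    z ~ 1 + group + age + sex,

i.e. a two-sided t test on the group coefficient co-varying age and sex
(residual degrees of freedom n - 4 with both covariates).  Symptom-severity effects use the same
design with the severity score in place of the group indicator, by default
restricted to patients.  p-values are reported uncorrected by default, with
Benjamini-Hochberg FDR available.

The closed-form OLS here is deliberately vectorized across units; the test
suite cross-checks it against statsmodels on individual units.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CohortTable

__all__ = [
    "fisher_z",
    "seed_map",
    "seed_maps_for_cohort",
    "group_glm",
    "severity_regression",
]

R_CLIP = 1.0 - 1e-7


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher-Z transform atanh(r), with r clipped to +/-(1 - 1e-7)."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def seed_map(series: np.ndarray, seed_indices,
             fisher: bool = True) -> np.ndarray:
    """Seed-to-unit correlation profile of one subject.

    The seed signal is the mean over the seed columns of the T x k series;
    the returned length-k vector holds the (optionally Fisher-Z transformed)
    Pearson correlation of the seed signal with every unit, with the seed's
    own units set to NaN (self-correlation is uninformative).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError(f"expected a T x k array, got shape {series.shape}")
    seed_indices = np.atleast_1d(np.asarray(seed_indices, dtype=int))
    if seed_indices.size == 0:
        raise ValueError("seed_indices must be nonempty")
    k = series.shape[1]
    if seed_indices.min() < 0 or seed_indices.max() >= k:
        raise ValueError(f"seed indices must lie in [0, {k})")
    seed_signal = series[:, seed_indices].mean(axis=1)
    if seed_signal.std() == 0:
        raise ValueError("seed signal is constant; correlation undefined")
    centered = series - series.mean(axis=0)
    s = seed_signal - seed_signal.mean()
    denom = np.sqrt((centered ** 2).sum(axis=0)) * np.linalg.norm(s)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered.T @ s) / denom
    out = fisher_z(r) if fisher else np.clip(r, -1.0, 1.0)
    out = np.asarray(out, dtype=float)
    out[seed_indices] = np.nan
    return out


def seed_maps_for_cohort(series: np.ndarray, seed_indices,
                         fisher: bool = True) -> np.ndarray:
    """Stack :func:`seed_map` over an (n_subjects, T, k) series array."""
    return np.stack([seed_map(s, seed_indices, fisher) for s in series])


def _design(df: pd.DataFrame, effect_column: np.ndarray, effect_name: str,
            covariates: tuple[str, ...] = ("age", "sex"),
            ) -> tuple[np.ndarray, list[str]]:
    columns = [np.ones(len(df)), np.asarray(effect_column, dtype=float)]
    names = ["intercept", effect_name]
    for cov in covariates:
        if cov == "sex":
            sex = df["sex"].astype(str)
            sex_levels = sorted(sex.unique())
            if len(sex_levels) > 2:
                raise ValueError(
                    f"sex has {len(sex_levels)} levels {sex_levels}; only a "
                    "binary indicator is supported"
                )
            columns.append((sex == sex_levels[-1]).to_numpy(dtype=float))
        else:
            if cov not in df.columns:
                raise ValueError(f"covariate column {cov!r} not in cohort")
            columns.append(df[cov].to_numpy(dtype=float))
        names.append(cov)
    X = np.column_stack(columns)
    for col, name in zip(X.T, names):
        if name != "intercept" and np.ptp(col) == 0:
            raise ValueError(
                f"design column {name!r} is constant; the model is "
                "rank deficient"
            )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


def _ols_tstats(X: np.ndarray, Y: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorized OLS of every column of Y on X; returns (B, T, P, dof)."""
    n, p = X.shape
    dof = n - p
    if dof < 1:
        raise ValueError(f"not enough subjects: n = {n}, parameters = {p}")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    s2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), s2))
    with np.errstate(invalid="ignore", divide="ignore"):
        T = B / se
    P = 2.0 * stats.t.sf(np.abs(T), dof)
    return B, T, P, dof


def group_glm(maps: np.ndarray, cohort: CohortTable, alpha: float = 0.05,
              mc_correction: str = "none",
              covariates: tuple[str, ...] = ("age", "sex"),
              positive_label: str = "patient") -> pd.DataFrame:
    """Per-unit group comparison of seed maps co-varying age and sex.

    ``maps`` is (n_subjects, n_units); units that are NaN for any subject
    (e.g. the seed's own units) are reported as NaN rows.  Returns one row
    per unit with the group coefficient estimate, t statistic, two-sided p,
    raw mean group difference and the significance mask at ``alpha``
    (applied to FDR-adjusted p if ``mc_correction="fdr"``).
    """
    if mc_correction not in ("none", "fdr"):
        raise ValueError("mc_correction must be 'none' or 'fdr'")
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] != len(cohort):
        raise ValueError("one map row per cohort subject required")
    y = cohort.indicator(positive_label).astype(float)
    if min(y.sum(), (1 - y).sum()) < 3:
        raise ValueError("need at least 3 subjects per group")
    X, _ = _design(cohort.table, y, "group", covariates)

    valid = ~np.isnan(maps).any(axis=0)
    out = pd.DataFrame({
        "unit": np.arange(maps.shape[1]),
        "estimate": np.nan, "t": np.nan, "p": np.nan,
        "mean_diff": np.nan,
    })
    if valid.any():
        B, T, P, dof = _ols_tstats(X, maps[:, valid])
        out.loc[valid, "estimate"] = B[1]
        out.loc[valid, "t"] = T[1]
        out.loc[valid, "p"] = P[1]
        out.loc[valid, "mean_diff"] = (maps[y == 1][:, valid].mean(axis=0)
                                       - maps[y == 0][:, valid].mean(axis=0))
        out.attrs["dof"] = dof
    if mc_correction == "fdr":
        padj = np.full(maps.shape[1], np.nan)
        padj[valid] = multipletests(out.loc[valid, "p"].to_numpy(),
                                    method="fdr_bh")[1]
        out["p_adj"] = padj
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    out["significant"] = out["significant"].fillna(False).astype(bool)
    return out


def severity_regression(maps: np.ndarray, cohort: CohortTable,
                        alpha: float = 0.05, patients_only: bool = True,
                        mc_correction: str = "none",
                        covariates: tuple[str, ...] = ("age", "sex"),
                        positive_label: str = "patient") -> pd.DataFrame:
    """Per-unit regression of seed maps on the severity score.

    Fits z ~ 1 + severity + age + sex per unit (patients only by default,
    since control severity scores are near-floor) and reports the severity
    slope, t and two-sided p.
    """
    if mc_correction not in ("none", "fdr"):
        raise ValueError("mc_correction must be 'none' or 'fdr'")
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] != len(cohort):
        raise ValueError("one map row per cohort subject required")
    severity = cohort.severity.to_numpy(dtype=float)
    table = cohort.table
    if patients_only:
        keep = cohort.indicator(positive_label).astype(bool)
        maps = maps[keep]
        severity = severity[keep]
        table = table.loc[keep].reset_index(drop=True)
    if np.isnan(severity).any():
        raise ValueError("severity score missing for some subjects")
    if np.ptp(severity) == 0:
        raise ValueError("severity score is constant; slope undefined")
    X, _ = _design(table, severity, "severity", covariates)

    valid = ~np.isnan(maps).any(axis=0)
    out = pd.DataFrame({
        "unit": np.arange(maps.shape[1]),
        "slope": np.nan, "t": np.nan, "p": np.nan,
    })
    if valid.any():
        B, T, P, dof = _ols_tstats(X, maps[:, valid])
        out.loc[valid, "slope"] = B[1]
        out.loc[valid, "t"] = T[1]
        out.loc[valid, "p"] = P[1]
        out.attrs["dof"] = dof
    if mc_correction == "fdr":
        padj = np.full(maps.shape[1], np.nan)
        padj[valid] = multipletests(out.loc[valid, "p"].to_numpy(),
                                    method="fdr_bh")[1]
        out["p_adj"] = padj
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    out["significant"] = out["significant"].fillna(False).astype(bool)
    return out
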