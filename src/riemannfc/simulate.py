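"""Synthetic resting-state cohorts with planted group differences.

Real case-control FC studies are rarely shareable, so every stage of the
pipeline is exercised on simulated cohorts that have the statistical
structure the method assumes: per-subject ROI time series drawn from a
multivariate normal whose population correlation matrix is a common base for
controls and, for patients, the same base with a configurable set of edges
shifted by a target effect.  A YBOCS-like severity score is linearly coupled
to each patient's realized planted-edge connectivity, so severity regressions
have a known ground truth.

The generator makes no attempt to emulate raw BOLD volumes, head motion or
scanner noise spectra — it produces the post-preprocessing quantities
(time series, correlation matrices, phenotypes) the method consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CohortTable, SEVERITY_COLUMN

__all__ = ["SimulationConfig", "SimulationResult", "simulate_cohort",
           "simulate_null_maps"]

# Severity-score anchors for a YBOCS-like clinical scale: patients centred
# near 25.5 (SD ~7), screened controls near 2.4 (SD ~2.9).
PATIENT_SEVERITY_MEAN = 25.5
CONTROL_SEVERITY_MEAN = 2.4
CONTROL_SEVERITY_SD = 2.9


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a planted-effect cohort simulation.

    ``effect`` is the target between-group difference in population
    correlation on each planted edge; ``severity_coupling`` is the slope (in
    score units per unit correlation) linking a patient's severity score to
    their mean planted-edge sample correlation; ``noise_sd`` is the SD of the
    severity noise term.
    """

    n_per_group: int = 60
    k: int = 20
    T: int = 300
    planted_edges: tuple[tuple[int, int], ...] = (
        (0, 1), (2, 3), (4, 5), (6, 7), (8, 9),
    )
    effect: float = 0.3
    noise_sd: float = 5.0
    severity_coupling: float = -120.0
    seed: int = 0
    base_dof: int | None = None  # Wishart dof for the base matrix; default 5k

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError(f"effect must be in [0, 1], got {self.effect}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        edges = []
        for edge in self.planted_edges:
            i, j = int(edge[0]), int(edge[1])
            if i == j:
                raise ValueError(f"planted edge ({i}, {j}) is a self-loop")
            if not (0 <= i < self.k and 0 <= j < self.k):
                raise ValueError(
                    f"planted edge ({i}, {j}) outside ROI range [0, {self.k})"
                )
            edges.append((min(i, j), max(i, j)))
        if len(set(edges)) != len(edges):
            raise ValueError("planted edges must be distinct")
        object.__setattr__(self, "planted_edges", tuple(edges))
        if self.T <= self.k:
            warnings.warn(
                f"T = {self.T} <= k = {self.k}: sample correlation matrices "
                "will be rank deficient; T > k is recommended",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SimulationResult:
    """Cohort realization plus the ground truth that generated it."""

    series: np.ndarray          # (n_subjects, T, k)
    cohort: CohortTable
    control_corr: np.ndarray    # population correlation, controls
    patient_corr: np.ndarray    # population correlation, patients
    config: SimulationConfig = field(repr=False)

    @property
    def planted_edges(self) -> tuple[tuple[int, int], ...]:
        return self.config.planted_edges


def _base_correlation(rng: np.random.Generator, k: int, dof: int) -> np.ndarray:
    """Random correlation matrix from a normalized Wishart draw.

    The degrees of freedom control heterogeneity: off-diagonal correlations
    have SD roughly 1/sqrt(dof).
    """
    G = rng.standard_normal((dof, k))
    S = G.T @ G / dof
    d = np.sqrt(np.diag(S))
    C = S / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return 0.5 * (C + C.T)


def _repair_correlation(C: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Project a near-correlation matrix back to valid PD form.

    Negative eigenvalues are clipped to ``floor`` and the diagonal is
    rescaled back to 1 — a minimal, deterministic perturbation.
    """
    w, U = np.linalg.eigh(0.5 * (C + C.T))
    if w[0] < floor:
        C = (U * np.clip(w, floor, None)) @ U.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
        C = 0.5 * (C + C.T)
    return C


def _patient_correlation(base: np.ndarray,
                         config: SimulationConfig) -> np.ndarray:
    """Shift planted edges of the base matrix by ``effect`` and repair."""
    C = base.copy()
    for (i, j) in config.planted_edges:
        target = C[i, j] + config.effect
        if abs(target) > 0.999:
            raise ValueError(
                f"planted edge ({i}, {j}): shifted correlation {target:.3f} "
                "leaves [-1, 1]; reduce the effect or re-seed the base matrix"
            )
        C[i, j] = C[j, i] = target
    C = _repair_correlation(C)
    for (i, j) in config.planted_edges:
        drift = abs(C[i, j] - (base[i, j] + config.effect))
        if drift > 0.1:
            raise ValueError(
                f"planted edge ({i}, {j}): positive-definite repair moved the "
                f"correlation by {drift:.3f}; the requested effect is too "
                "large for this base matrix"
            )
    return C


def simulate_cohort(config: SimulationConfig) -> SimulationResult:
    """Draw a two-group cohort of ROI time series plus phenotypes.

    Controls' series are multivariate normal with the base correlation
    matrix; patients' with the planted-edge-shifted matrix.  The same seed
    reproduces the output bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    k, T, n = config.k, config.T, config.n_per_group
    dof = config.base_dof if config.base_dof is not None else 5 * k

    base = _base_correlation(rng, k, dof)
    if config.effect > 0:
        patient = _patient_correlation(base, config)
    else:
        patient = base.copy()

    chol = {"control": np.linalg.cholesky(base),
            "patient": np.linalg.cholesky(_repair_correlation(patient))}

    edges = np.array(config.planted_edges)
    mu_planted = patient[edges[:, 0], edges[:, 1]].mean()

    series = np.empty((2 * n, T, k))
    rows = []
    for s in range(2 * n):
        group = "control" if s < n else "patient"
        series[s] = rng.standard_normal((T, k)) @ chol[group].T
        R = np.corrcoef(series[s], rowvar=False)
        rbar = R[edges[:, 0], edges[:, 1]].mean()
        age = float(np.clip(rng.normal(24.0, 7.0), 18.0, 59.0))
        sex = "M" if rng.random() < 0.5 else "F"
        if group == "patient":
            severity = (PATIENT_SEVERITY_MEAN
                        + config.severity_coupling * (rbar - mu_planted)
                        + rng.normal(0.0, config.noise_sd))
        else:
            severity = max(0.0, CONTROL_SEVERITY_MEAN
                           + rng.normal(0.0, CONTROL_SEVERITY_SD))
        rows.append({"subject_id": f"S{s:03d}", "group": group,
                     "age": round(age, 1), "sex": sex,
                     SEVERITY_COLUMN: round(float(severity), 2)})

    cohort = CohortTable(pd.DataFrame(rows))
    return SimulationResult(series=series, cohort=cohort,
                            control_corr=base, patient_corr=patient,
                            config=config)


def simulate_null_maps(n_subjects: int, n_units: int,
                       seed: int = 0) -> tuple[np.ndarray, CohortTable]:
    """Per-subject unit-wise z-values with no group effect.

    Values are i.i.d. standard normal within subject; the (balanced) group
    label and the age/sex covariates are assigned independently of the data,
    so the true group coefficient is 0 at every unit.  Used to calibrate the
    type-I error of the group GLM.
    """
    if n_subjects < 8:
        raise ValueError("need at least 8 subjects for a null cohort")
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    rng = np.random.default_rng(seed)
    maps = rng.standard_normal((n_subjects, n_units))
    half = n_subjects // 2
    groups = np.array(["control"] * half
                      + ["patient"] * (n_subjects - half))
    rng.shuffle(groups)
    df = pd.DataFrame({
        "subject_id": [f"N{s:03d}" for s in range(n_subjects)],
        "group": groups,
        "age": np.round(np.clip(rng.normal(24.0, 7.0, n_subjects), 18, 59), 1),
        "sex": np.where(rng.random(n_subjects) < 0.5, "M", "F"),
    })
    return maps, CohortTable(df)
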