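"""Penalty-path fitting and BIC tuning.

The penalty lambda is chosen by the Bayesian information criterion

    BIC(lambda) = n L(Omega_hat) + ln(n) * k.

The total negative log-likelihood of the sample is (n/2) L(Omega) up to
constants (L carries the factor-2 convention of the printed objective), so
n L = 2 NLL and this is the standard BIC.  k is the number of nonzero
strictly-upper-triangular entries of the
estimate.  Entries are counted nonzero above 1e-6 in absolute value, the
same threshold the evaluation module uses to call edges, so the penalty
that BIC selects and the network that is scored are consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .blocks import BlockStructure, CompositionDataset
from .likelihood import SampleMoments, compute_moments, neg_log_likelihood
from .solver import PrecisionEstimate, SolverConfig, fit_gmcoda

EDGE_TOL = 1e-6


@dataclass
class FitPath:
    """Estimates over a decreasing lambda grid with per-lambda BIC."""

    lambdas: np.ndarray
    estimates: list[PrecisionEstimate]
    bic: np.ndarray
    selected_index: int

    @property
    def selected(self) -> PrecisionEstimate:
        return self.estimates[self.selected_index]


def lambda_grid(
    moments: SampleMoments, n_lambda: int = 15, ratio: float = 0.01
) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max = max off-diagonal |S|.

    At or above lambda_max the penalized problem admits the all-zero
    off-diagonal solution; lambda_min = ratio * lambda_max.
    """
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    S = moments.S
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = float(off.max())
    if lam_max <= 0:
        warnings.warn("S has no off-diagonal signal; single-point grid")
        return np.array([max(float(np.diag(S).max()), 1.0)])
    return np.geomspace(lam_max, ratio * lam_max, n_lambda)


def count_edges(omega: np.ndarray, tol: float = EDGE_TOL) -> int:
    """Nonzero strictly-upper-triangular entries of Omega."""
    iu = np.triu_indices(len(omega), k=1)
    return int(np.sum(np.abs(omega[iu]) > tol))


def bic_score(
    estimate: PrecisionEstimate,
    moments: SampleMoments,
    structure: BlockStructure,
) -> float:
    """n L(Omega_hat) + ln(n) * (number of estimated edges)."""
    L = neg_log_likelihood(estimate.omega, moments, structure)
    k = count_edges(estimate.omega)
    return float(moments.n * L + np.log(moments.n) * k)


def fit_path(
    data: CompositionDataset | SampleMoments,
    grid: np.ndarray | None = None,
    config: SolverConfig | None = None,
    structure: BlockStructure | None = None,
    n_lambda: int = 15,
    ratio: float = 0.01,
) -> FitPath:
    """Fit from the largest lambda down, warm-starting each fit, and BIC-select.

    Ties in BIC resolve to the larger (sparser) lambda.
    """
    config = config or SolverConfig()
    if isinstance(data, CompositionDataset):
        structure = data.structure
        moments = compute_moments(data)
    else:
        if structure is None:
            raise ValueError("structure required when passing SampleMoments")
        moments = data
    if grid is None:
        grid = lambda_grid(moments, n_lambda=n_lambda, ratio=ratio)
    grid = np.asarray(grid, dtype=float)
    if len(grid) > 1 and not np.all(np.diff(grid) < 0):
        raise ValueError("lambda grid must be strictly decreasing")

    estimates: list[PrecisionEstimate] = []
    bics: list[float] = []
    kept_lambdas: list[float] = []
    omega_prev = None
    for lam in grid:
        try:
            est = fit_gmcoda(
                moments,
                lam,
                config=config,
                structure=structure,
                omega_init=omega_prev,
            )
        except Exception as exc:  # noqa: BLE001 - per-lambda failures are skipped
            warnings.warn(f"fit failed at lambda={lam:g}: {exc}")
            continue
        omega_prev = est.omega
        estimates.append(est)
        bics.append(bic_score(est, moments, structure))
        kept_lambdas.append(float(lam))
    if not estimates:
        raise RuntimeError("every lambda on the grid failed to fit")
    bic_arr = np.asarray(bics)
    selected = int(np.argmin(bic_arr))  # first minimum = largest lambda
    return FitPath(
        lambdas=np.asarray(kept_lambdas),
        estimates=estimates,
        bic=bic_arr,
        selected_index=selected,
    )
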