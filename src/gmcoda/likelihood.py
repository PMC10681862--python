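"""The gmcoda objective.

The model: latent log-abundances lnY ~ N_p(mu, Omega^-1); only per-block
closures X are observed, so the per-block log-totals W are lost.  With
R the block-indicator matrix, marginalizing W out of the joint normal
gives (dropping constants) the negative log-likelihood

    L(Omega) = -ln|Omega| + ln|R' Omega R|
               + Tr(S [Omega - Omega R (R' Omega R)^-1 R' Omega]),

where S is the sample covariance of the log-proportions.  The penalized
objective is f(Omega) = L(Omega) + lam * ||Omega||_1.  The surrogate
covariance S_Omega rewrites L so that the majorizer

    g(Omega | Omega_k) = -ln|Omega| + Tr(Omega S_{Omega_k})
                         + lam*||Omega||_1 + ln|R' Omega_k R| - d

touches f at Omega_k and upper-bounds it everywhere, which is what makes
the MM iteration in `solver` a descent method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .blocks import BlockStructure, CompositionDataset, build_P, build_R


@dataclass
class SampleMoments:
    """Sample covariance of log-proportions plus the centered log rows."""

    S: np.ndarray
    n: int
    centered_logs: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ValueError("S must be symmetric")


def compute_moments(data: CompositionDataset) -> SampleMoments:
    """Log-transform, center, and form the ML (1/n) sample covariance.

    S is the covariance of ln(x) rows with denominator n (the likelihood
    is maximum-likelihood based); `centered_logs` holds P @ ln(x) per
    sample, i.e. logs with each block's within-sample mean removed.
    """
    logs = np.log(data.values)
    n = data.n
    S = np.cov(logs, rowvar=False, bias=True)
    S = np.atleast_2d(S)
    P = build_P(data.structure)
    centered = logs @ P  # P symmetric, so this is (P ln x)' per row
    return SampleMoments(S=S, n=n, centered_logs=centered)


def _chol_logdet(A: np.ndarray, what: str) -> tuple[np.ndarray, float]:
    """Cholesky factor and log-determinant; raises on non-PD input."""
    try:
        L = linalg.cholesky(A, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(f"{what} is not positive definite") from exc
    return L, 2.0 * np.sum(np.log(np.diag(L)))


def neg_log_likelihood(
    omega: np.ndarray, moments: SampleMoments, structure: BlockStructure
) -> float:
    """L(Omega): the marginal negative log-likelihood, constants dropped."""
    R = build_R(structure)
    _, logdet_omega = _chol_logdet(omega, "omega")
    B = omega @ R                      # p x d
    M = R.T @ B                        # d x d = R' Omega R
    Lm, logdet_M = _chol_logdet(M, "R' Omega R")
    # Q = Omega - B M^-1 B'
    MinvBt = linalg.cho_solve((Lm, True), B.T)
    Q = omega - B @ MinvBt
    S = moments.S
    return float(-logdet_omega + logdet_M + np.sum(S * Q))


def surrogate_covariance(
    omega_k: np.ndarray, moments: SampleMoments, structure: BlockStructure
) -> np.ndarray:
    """S_Omega = A S A' + R (R'Omega R)^-1 R' with A = I - R(R'Omega R)^-1 R'Omega."""
    R = build_R(structure)
    p = structure.p
    B = omega_k @ R
    M = R.T @ B
    Lm, _ = _chol_logdet(M, "R' Omega R")
    Minv_Rt = linalg.cho_solve((Lm, True), R.T)      # (R'OR)^-1 R'
    A = np.eye(p) - Minv_Rt.T @ B.T                  # I - R(R'OR)^-1 (OR)'
    S_omega = A @ moments.S @ A.T + R @ Minv_Rt
    return 0.5 * (S_omega + S_omega.T)


def l1_norm(omega: np.ndarray, include_diagonal: bool = True) -> float:
    """Entrywise L1 norm of Omega, optionally excluding the diagonal."""
    total = np.abs(omega).sum()
    if not include_diagonal:
        total -= np.abs(np.diag(omega)).sum()
    return float(total)


def penalized_objective(
    omega: np.ndarray,
    moments: SampleMoments,
    structure: BlockStructure,
    lam: float,
    penalize_diagonal: bool = True,
) -> float:
    """f(Omega) = L(Omega) + lam * ||Omega||_1."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return neg_log_likelihood(omega, moments, structure) + lam * l1_norm(
        omega, include_diagonal=penalize_diagonal
    )


def majorizer(
    omega: np.ndarray,
    omega_k: np.ndarray,
    moments: SampleMoments,
    structure: BlockStructure,
    lam: float,
    penalize_diagonal: bool = True,
) -> float:
    """g(Omega|Omega_k): the MM surrogate; g(.|Omega_k) >= f with equality at Omega_k."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    R = build_R(structure)
    _, logdet_omega = _chol_logdet(omega, "omega")
    M_k = R.T @ omega_k @ R
    _, logdet_Mk = _chol_logdet(M_k, "R' Omega_k R")
    S_k = surrogate_covariance(omega_k, moments, structure)
    return float(
        -logdet_omega
        + np.sum(omega * S_k)
        + lam * l1_norm(omega, include_diagonal=penalize_diagonal)
        + logdet_Mk
        - structure.d
    )
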