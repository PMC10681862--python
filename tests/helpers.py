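"""Independent oracles used by the test suite.

These deliberately re-derive quantities through different algebra and
different solvers than the package: an ADMM solver for the L1-penalized
log-determinant subproblem, and a direct single-composition (d=1)
implementation of the likelihood and MM fit written with explicit
ones-vectors instead of the block matrices R and P.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from sklearn.covariance import graphical_lasso


def admm_glasso(
    S: np.ndarray,
    lam: float,
    penalize_diagonal: bool = True,
    rho: float = 1.0,
    tol: float = 1e-10,
    max_iter: int = 20000,
) -> np.ndarray:
    """ADMM solution of min -ln|X| + Tr(XS) + lam*||X||_1 over PD X."""
    p = len(S)
    Z = np.eye(p)
    U = np.zeros((p, p))
    for _ in range(max_iter):
        # X update: eigen decomposition of rho*(Z - U) - S
        vals, vecs = np.linalg.eigh(rho * (Z - U) - S)
        xvals = (vals + np.sqrt(vals**2 + 4 * rho)) / (2 * rho)
        X = (vecs * xvals) @ vecs.T
        # Z update: soft thresholding
        Z_old = Z
        A = X + U
        thr = lam / rho
        Z = np.sign(A) * np.maximum(np.abs(A) - thr, 0.0)
        if not penalize_diagonal:
            np.fill_diagonal(Z, np.diag(A))
        U = U + X - Z
        r_primal = np.linalg.norm(X - Z)
        r_dual = rho * np.linalg.norm(Z - Z_old)
        if r_primal < tol and r_dual < tol:
            break
    return 0.5 * (Z + Z.T)


def gcoda_neg_loglik(omega: np.ndarray, S: np.ndarray) -> float:
    """Single-composition likelihood written with explicit ones-vectors."""
    p = len(omega)
    ones = np.ones(p)
    a = omega @ ones
    denom = float(ones @ a)
    sign, logdet = np.linalg.slogdet(omega)
    assert sign > 0
    Q = omega - np.outer(a, a) / denom
    return float(-logdet + np.log(denom) + np.sum(S * Q))


def gcoda_surrogate(omega: np.ndarray, S: np.ndarray) -> np.ndarray:
    p = len(omega)
    ones = np.ones(p)
    a = omega @ ones
    denom = float(ones @ a)
    A = np.eye(p) - np.outer(ones, a) / denom
    return A @ S @ A.T + np.ones((p, p)) / denom


def gcoda_fit(
    S: np.ndarray,
    lam: float,
    mm_tol: float = 1e-4,
    max_iter: int = 100,
    inner_tol: float = 1e-7,
    inner_max_iter: int = 500,
) -> np.ndarray:
    """Single-composition MM fit starting from the identity."""
    p = len(S)
    omega = np.eye(p)
    f = gcoda_neg_loglik(omega, S) + lam * np.abs(omega).sum()
    for _ in range(max_iter):
        S_k = gcoda_surrogate(omega, S)
        S_k = 0.5 * (S_k + S_k.T)
        _, omega_new = graphical_lasso(
            S_k + lam * np.eye(p),
            alpha=lam,
            tol=inner_tol,
            enet_tol=inner_tol,
            max_iter=inner_max_iter,
        )[:2]
        omega_new = 0.5 * (omega_new + omega_new.T)
        f_new = gcoda_neg_loglik(omega_new, S) + lam * np.abs(omega_new).sum()
        if f_new > f:
            break
        rel = abs(f - f_new) / (abs(f) + 1.0)
        omega, f = omega_new, f_new
        if rel < mm_tol:
            break
    return omega


def random_pd(p: int, rng: np.random.Generator, cond: float = 5.0) -> np.ndarray:
    """Random symmetric positive definite matrix with moderate conditioning."""
    A = rng.standard_normal((p, p))
    Q, _ = np.linalg.qr(A)
    vals = rng.uniform(1.0, cond, size=p)
    return (Q * vals) @ Q.T


def random_psd(p: int, rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((p + 2, p))
    return A.T @ A / (p + 2)
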