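"""Majorization-minimization solver for the penalized gmcoda objective.

Each MM step replaces the likelihood with its quadratic-in-Omega surrogate
and solves the resulting L1-penalized log-determinant problem

    Omega_{k+1} = argmin_{Omega > 0}  -ln|Omega| + Tr(Omega S_k) + lam*||Omega||_1

with S_k the surrogate covariance at the current iterate.  The subproblem
is the graphical-lasso objective and is delegated to scikit-learn's
coordinate-descent routine; a diagonal penalty (the default, matching the
printed norm) is folded in exactly via S_k + lam*I since the diagonal of a
positive-definite Omega is positive.  The majorization property guarantees
the penalized objective never increases across iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from .blocks import BlockStructure, CompositionDataset
from .likelihood import (
    SampleMoments,
    compute_moments,
    penalized_objective,
    surrogate_covariance,
)


@dataclass
class SolverConfig:
    """Knobs of the MM loop; defaults chosen for a stable, fast benchmark."""

    max_mm_iter: int = 100
    mm_tol: float = 1e-4
    inner_tol: float = 1e-7
    inner_max_iter: int = 500
    init: str = "regularized_inverse"  # or "identity"
    penalize_diagonal: bool = True

    def __post_init__(self) -> None:
        if self.max_mm_iter < 1:
            raise ValueError("max_mm_iter must be >= 1")
        if self.mm_tol <= 0 or self.inner_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.init not in ("regularized_inverse", "identity"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class PrecisionEstimate:
    """A fitted precision matrix with its penalty and solver diagnostics."""

    omega: np.ndarray
    lam: float
    n_iter: int
    converged: bool
    objective: float
    objective_path: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if not np.isfinite(self.objective):
            raise ValueError("objective must be finite")

    @property
    def partial_correlations(self) -> np.ndarray:
        return partial_correlations(self)


def glasso_subproblem(
    S_target: np.ndarray,
    lam: float,
    inner_tol: float = 1e-7,
    max_iter: int = 500,
    penalize_diagonal: bool = True,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Solve min -ln|Omega| + Tr(Omega S) + lam*||Omega||_1 over PD Omega.

    Parameters
    ----------
    S_target : symmetric PSD input covariance.
    lam : penalty weight >= 0.
    penalize_diagonal : include |Omega_ii| in the L1 norm.  Folded into the
        smooth part exactly (diagonal of a PD matrix is positive).
    init : ignored by the coordinate-descent backend (kept for API symmetry
        of warm-started callers).
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    S_target = np.asarray(S_target, dtype=float)
    S_target = 0.5 * (S_target + S_target.T)
    if lam == 0:
        try:
            omega = linalg.inv(S_target)
        except linalg.LinAlgError as exc:
            raise ValueError("S_target singular and lam=0: no solution") from exc
        return 0.5 * (omega + omega.T)
    emp = S_target + lam * np.eye(len(S_target)) if penalize_diagonal else S_target
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            result = _sk_graphical_lasso(
                emp, alpha=lam, tol=inner_tol, enet_tol=inner_tol, max_iter=max_iter
            )
    except FloatingPointError as exc:
        raise RuntimeError(
            f"graphical-lasso subproblem failed at lam={lam:g}: {exc}"
        ) from exc
    omega = 0.5 * (result[1] + result[1].T)
    if any("did not converge" in str(w.message) for w in caught):
        # the dual-gap stopping rule can report tiny negative gaps at tight
        # tolerances; accept the iterate only if it satisfies stationarity
        res = kkt_residual(omega, S_target, lam, penalize_diagonal)
        if res > max(1e3 * inner_tol, 1e-3):
            raise RuntimeError(
                f"graphical-lasso subproblem did not converge at lam={lam:g} "
                f"(KKT residual {res:.2e} after {max_iter} iterations)"
            )
    return omega


def kkt_residual(
    omega: np.ndarray,
    S_target: np.ndarray,
    lam: float,
    penalize_diagonal: bool = True,
    zero_tol: float = 1e-8,
) -> float:
    """Max violation of the subproblem's stationarity conditions.

    Grad of the smooth part is S - Omega^-1.  On entries with Omega_ij != 0
    the full gradient S - Omega^-1 + lam*sign(Omega) must vanish; on zero
    entries |S - Omega^-1| <= lam must hold.
    """
    G = S_target - linalg.inv(omega)
    p = len(omega)
    penal = np.ones((p, p), dtype=bool)
    if not penalize_diagonal:
        np.fill_diagonal(penal, False)
    active = np.abs(omega) > zero_tol
    res_active = np.abs(G + lam * np.sign(omega) * penal)[active]
    res_zero = np.maximum(np.abs(G[~active & penal]) - lam, 0.0)
    res_unpenalized = np.abs(G[~penal]) if not penalize_diagonal else np.array([])
    pieces = [r for r in (res_active, res_zero, res_unpenalized) if r.size]
    return float(max(r.max() for r in pieces)) if pieces else 0.0


def _initial_omega(S: np.ndarray, config: SolverConfig) -> np.ndarray:
    p = len(S)
    if config.init == "identity":
        return np.eye(p)
    eps = 0.1 * float(np.mean(np.diag(S)))
    if eps <= 0:
        return np.eye(p)
    A = S + eps * np.eye(p)
    try:
        omega0 = linalg.inv(A)
    except linalg.LinAlgError:
        return np.eye(p)
    if np.linalg.cond(A) > 1e10 or not np.all(np.isfinite(omega0)):
        return np.eye(p)
    return 0.5 * (omega0 + omega0.T)


def _stabilized_moments(moments: SampleMoments) -> SampleMoments:
    """Ridge-stabilize S if some log-column is (numerically) constant."""
    diag = np.diag(moments.S)
    if np.any(diag < 1e-12):
        warnings.warn(
            "constant log-abundance column detected; ridge-stabilizing S",
            stacklevel=3,
        )
        ridge = 1e-6 * max(float(diag.max()), 1.0)
        return SampleMoments(
            S=moments.S + ridge * np.eye(len(moments.S)),
            n=moments.n,
            centered_logs=moments.centered_logs,
        )
    return moments


def fit_gmcoda(
    data: CompositionDataset | SampleMoments,
    lam: float,
    config: SolverConfig | None = None,
    structure: BlockStructure | None = None,
    omega_init: np.ndarray | None = None,
) -> PrecisionEstimate:
    """Fit the gmcoda precision matrix at a single penalty level.

    Accepts either a dataset (moments computed internally) or precomputed
    `SampleMoments` with an explicit `structure` (the path fitter uses the
    latter to avoid recomputing the covariance at every lambda).
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    config = config or SolverConfig()
    if isinstance(data, CompositionDataset):
        structure = data.structure
        moments = compute_moments(data)
    else:
        if structure is None:
            raise ValueError("structure required when passing SampleMoments")
        moments = data
    moments = _stabilized_moments(moments)

    omega = (
        np.asarray(omega_init, dtype=float)
        if omega_init is not None
        else _initial_omega(moments.S, config)
    )
    f = penalized_objective(
        omega, moments, structure, lam, config.penalize_diagonal
    )
    path = [f]
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_mm_iter + 1):
        S_k = surrogate_covariance(omega, moments, structure)
        omega_new = glasso_subproblem(
            S_k,
            lam,
            inner_tol=config.inner_tol,
            max_iter=config.inner_max_iter,
            penalize_diagonal=config.penalize_diagonal,
        )
        f_new = penalized_objective(
            omega_new, moments, structure, lam, config.penalize_diagonal
        )
        if f_new > f:  # inexact inner solve; keep the better iterate
            converged = True
            break
        rel_change = abs(f - f_new) / (abs(f) + 1.0)
        omega, f = omega_new, f_new
        path.append(f)
        if rel_change < config.mm_tol:
            converged = True
            break
    return PrecisionEstimate(
        omega=omega,
        lam=lam,
        n_iter=n_iter,
        converged=converged,
        objective=f,
        objective_path=path,
    )


def partial_correlations(estimate: PrecisionEstimate | np.ndarray) -> np.ndarray:
    """Standardize a precision matrix: rho_ij = -Omega_ij / sqrt(Omega_ii Omega_jj)."""
    omega = estimate.omega if isinstance(estimate, PrecisionEstimate) else estimate
    omega = np.asarray(omega, dtype=float)
    d = np.sqrt(np.diag(omega))
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be positive")
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho
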