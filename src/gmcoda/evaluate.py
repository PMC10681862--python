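"""Performance measures for network recovery and the simulation benchmark.

Edges are called on the strict upper triangle of the estimated
partial-correlation matrix (|rho| > 1e-6, matching the BIC edge count).
Besides the classification rates, two estimation-error measures compare
the estimated and true partial correlations over ordered off-diagonal
pairs:

    d1 = (1 / (p(p-1))) * sum_{i != j} |rho_hat_ij - rho_ij|
    dF = (1 / (p(p-1))) * sum_{i != j} (rho_hat_ij - rho_ij)^2

(dF is the mean of squared deviations, not its square root).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import BlockStructure
from .networks import NetworkSpec, make_network
from .selection import EDGE_TOL, FitPath, fit_path
from .simulate import draw_mean, simulate
from .solver import SolverConfig, partial_correlations

@dataclass
class EvalResult:
    fpr: float
    tpr: float
    precision: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    d1: float | None = None
    dF: float | None = None


def _edge_set(matrix: np.ndarray, tol: float) -> frozenset[tuple[int, int]]:
    iu = np.triu_indices(len(matrix), k=1)
    mask = np.abs(matrix[iu]) > tol
    return frozenset(
        (int(i), int(j)) for i, j in zip(iu[0][mask], iu[1][mask])
    )


def confusion(
    estimate: np.ndarray,
    truth: NetworkSpec,
    zero_tol: float = EDGE_TOL,
) -> EvalResult:
    """Classification rates of the estimated edge set against the truth.

    Degenerate-denominator conventions: precision = 1 when nothing is
    predicted, recall = 1 when the truth has no edges, F1 = 1 when both
    sides are empty and 0 when exactly one is.
    """
    estimate = np.asarray(estimate, dtype=float)
    p = truth.p
    if estimate.shape != (p, p):
        raise ValueError(f"estimate shape {estimate.shape} != ({p}, {p})")
    pred = _edge_set(estimate, zero_tol)
    true = truth.edges
    n_pairs = p * (p - 1) // 2
    tp = len(pred & true)
    fp = len(pred - true)
    fn = len(true - pred)
    tn = n_pairs - tp - fp - fn
    fpr = fp / (fp + tn) if (fp + tn) > 0 else 0.0
    prec = tp / (tp + fp) if pred else 1.0
    rec = tp / (tp + fn) if true else 1.0
    if not pred and not true:
        f1 = 1.0
    elif not pred or not true:
        f1 = 0.0
    else:
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
    return EvalResult(
        fpr=fpr, tpr=rec, precision=prec, f1=f1, tp=tp, fp=fp, tn=tn, fn=fn
    )


def estimation_errors(
    rho_hat: np.ndarray, rho_true: np.ndarray
) -> tuple[float, float]:
    """(d1, dF): mean absolute and mean squared off-diagonal deviation."""
    rho_hat = np.asarray(rho_hat, dtype=float)
    rho_true = np.asarray(rho_true, dtype=float)
    if rho_hat.shape != rho_true.shape:
        raise ValueError("shape mismatch")
    p = len(rho_hat)
    diff = rho_hat - rho_true
    off = ~np.eye(p, dtype=bool)
    denom = p * (p - 1)
    d1 = float(np.abs(diff[off]).sum() / denom)
    dF = float((diff[off] ** 2).sum() / denom)
    return d1, dF


def auc_over_path(path: FitPath, truth: NetworkSpec) -> float:
    """Trapezoidal area under the (FPR, TPR) curve traced by the lambda path.

    Endpoints (0, 0) and (1, 1) are appended before integration.
    """
    if len(path.estimates) < 2:
        raise ValueError("need at least two path points")
    pts = [(0.0, 0.0), (1.0, 1.0)]
    for est in path.estimates:
        rho = partial_correlations(est)
        res = confusion(rho, truth)
        pts.append((res.fpr, res.tpr))
    pts.sort()
    xs, ys = zip(*pts)
    return float(np.trapezoid(ys, xs))


def run_replicate(
    topology: str,
    n: int,
    structure: BlockStructure,
    seed: int | np.random.SeedSequence,
    config: SolverConfig | None = None,
    n_lambda: int = 15,
    compute_auc: bool = False,
) -> dict[str, float]:
    """One benchmark replicate: generate truth, simulate, fit, BIC-select, score."""
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    s_net, s_mu, s_data = ss.spawn(3)
    p = structure.p
    truth = make_network(
        topology, p, seed=np.random.default_rng(s_net), structure=structure
    )
    mean = draw_mean(p, np.random.default_rng(s_mu))
    sim = simulate(truth, mean, n, np.random.default_rng(s_data))
    t0 = time.perf_counter()
    path = fit_path(sim.data, config=config, n_lambda=n_lambda)
    elapsed = time.perf_counter() - t0
    rho_hat = partial_correlations(path.selected)
    res = confusion(rho_hat, truth)
    d1, dF = estimation_errors(rho_hat, truth.rho_true)
    out = {
        "fpr": res.fpr,
        "tpr": res.tpr,
        "precision": res.precision,
        "f1": res.f1,
        "d1": d1,
        "dF": dF,
        "time": elapsed,
        "lambda": float(path.lambdas[path.selected_index]),
        "n_edges": res.tp + res.fp,
    }
    if compute_auc:
        out["auc"] = auc_over_path(path, truth)
    return out


def run_benchmark(
    topology: str,
    n: int = 300,
    block_sizes: tuple[int, ...] = (25, 25),
    n_reps: int = 20,
    seed: int | np.random.SeedSequence = 0,
    config: SolverConfig | None = None,
    n_lambda: int = 15,
    compute_auc: bool = False,
) -> pd.DataFrame:
    """Replicate the simulation benchmark for one topology.

    Per replicate a fresh truth, mean, and dataset are drawn from spawned
    seed streams; the returned frame holds one row per replicate plus
    `mean` and `sd` summary rows.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    structure = BlockStructure(block_sizes)
    rows, failed = [], 0
    for rep, child in enumerate(ss.spawn(n_reps)):
        try:
            row = run_replicate(
                topology,
                n,
                structure,
                child,
                config=config,
                n_lambda=n_lambda,
                compute_auc=compute_auc,
            )
        except Exception as exc:  # noqa: BLE001
            failed += 1
            warnings.warn(f"replicate {rep} failed: {exc}")
            if failed > max(1, n_reps // 5):
                raise
            continue
        row["rep"] = rep
        rows.append(row)
    df = pd.DataFrame(rows).set_index("rep")
    summary = pd.DataFrame(
        {"mean": df.mean(), "sd": df.std(ddof=1)}
    ).T
    return pd.concat([df, summary])
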