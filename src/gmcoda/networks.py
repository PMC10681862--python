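"""Ground-truth precision-matrix generators for the simulation benchmark.

Six topologies: random, neighbor, band, hub, block, and scale-free, each
with fixed edge strengths, plus the positive-definiteness adjustment that
sets a common diagonal.  Approximate edge densities (fraction of the
p(p-1)/2 pairs): 0.1, 12/p, 10/p, 0.05 + 6/p, 0.1, and 10/p respectively.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .blocks import BlockStructure

PD_MARGIN = 0.2


@dataclass
class NetworkSpec:
    """A true sparse precision matrix with its topology label and edge set."""

    topology: str
    omega_true: np.ndarray
    edges: frozenset[tuple[int, int]]
    structure: BlockStructure

    @property
    def p(self) -> int:
        return len(self.omega_true)

    @property
    def rho_true(self) -> np.ndarray:
        """True partial-correlation matrix implied by omega_true."""
        d = np.sqrt(np.diag(self.omega_true))
        rho = -self.omega_true / np.outer(d, d)
        np.fill_diagonal(rho, 1.0)
        return rho

    def save_edge_list(self, path: str | Path) -> None:
        """Write `i j weight` lines (1-based indices)."""
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tweight\n")
            for i, j in sorted(self.edges):
                fh.write(f"{i + 1}\t{j + 1}\t{self.omega_true[i, j]:.10g}\n")

    def save_matrix(self, path: str | Path) -> None:
        np.savetxt(path, self.omega_true, delimiter="\t")


def make_positive_definite(omega_raw: np.ndarray) -> np.ndarray:
    """Set a common diagonal |lambda_min| + 0.2 so the matrix is PD.

    The uniform diagonal preserves the sign pattern of the implied partial
    correlations; the 0.2 margin keeps the latent covariance well
    conditioned.  Off-diagonal entries are untouched.
    """
    omega_raw = np.asarray(omega_raw, dtype=float)
    if not np.allclose(omega_raw, omega_raw.T, atol=1e-10):
        raise ValueError("omega_raw must be symmetric")
    off = omega_raw.copy()
    np.fill_diagonal(off, 0.0)
    lam_min = float(np.linalg.eigvalsh(off).min())
    omega = off
    np.fill_diagonal(omega, abs(lam_min) + PD_MARGIN)
    return omega


def _default_structure(p: int, structure: BlockStructure | None) -> BlockStructure:
    if structure is None:
        return BlockStructure((p,))
    if structure.p != p:
        raise ValueError(f"structure has p={structure.p}, expected {p}")
    return structure


def _finalize(
    topology: str,
    strengths: np.ndarray,
    structure: BlockStructure | None,
) -> NetworkSpec:
    """Symmetrize the upper-triangular strengths, adjust the diagonal."""
    p = len(strengths)
    raw = strengths + strengths.T
    omega = make_positive_definite(raw)
    iu = np.triu_indices(p, k=1)
    mask = omega[iu] != 0
    edges = frozenset(
        (int(i), int(j)) for i, j in zip(iu[0][mask], iu[1][mask])
    )
    return NetworkSpec(
        topology=topology,
        omega_true=omega,
        edges=edges,
        structure=_default_structure(p, structure),
    )


def _signed(rng: np.random.Generator, shape, magnitude: float = 0.15) -> np.ndarray:
    return magnitude * rng.choice([-1.0, 1.0], size=shape)


def make_random(
    p: int, seed: int | np.random.Generator, structure: BlockStructure | None = None
) -> NetworkSpec:
    """Erdos-Renyi pairs: edge probability 0.1, strengths +/-0.15."""
    if p < 2:
        raise ValueError("p must be >= 2")
    rng = np.random.default_rng(seed)
    upper = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    present = rng.random(len(iu[0])) < 0.1
    upper[iu] = np.where(present, _signed(rng, len(iu[0])), 0.0)
    return _finalize("random", upper, structure)


def make_neighbor(
    p: int, seed: int | np.random.Generator, structure: BlockStructure | None = None
) -> NetworkSpec:
    """8-nearest-neighbor graph of p uniform points on the unit square.

    The directed 8-NN relation is symmetrized by union, giving density
    close to 12/p; distance ties break toward the lower index (argsort is
    stable).  Strengths are +/-0.15 equiprobable.
    """
    if p < 9:
        raise ValueError("neighbor network needs p >= 9")
    rng = np.random.default_rng(seed)
    pts = rng.random((p, 2))
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    adj = np.zeros((p, p), dtype=bool)
    for i in range(p):
        nn = np.argsort(dist[i], kind="stable")[:8]
        adj[i, nn] = True
    adj = adj | adj.T
    upper = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    sel = adj[iu]
    upper[iu] = np.where(sel, _signed(rng, len(iu[0])), 0.0)
    return _finalize("neighbor", upper, structure)


_BAND_STRENGTHS = {1: 0.4, 2: 0.2, 3: -0.2, 4: -0.1, 5: -0.1}


def make_band(p: int, structure: BlockStructure | None = None) -> NetworkSpec:
    """Deterministic band: Omega_ij set by |i-j| = 1..5, zero beyond."""
    if p < 6:
        raise ValueError("band network needs p >= 6")
    upper = np.zeros((p, p))
    for dist, strength in _BAND_STRENGTHS.items():
        idx = np.arange(p - dist)
        upper[idx, idx + dist] = strength
    return _finalize("band", upper, structure)


def make_hub(
    p: int, seed: int | np.random.Generator, structure: BlockStructure | None = None
) -> NetworkSpec:
    """Four hub nodes: hub-hub always connected, hub-nonhub with prob 0.75
    (strength 0.1); nonhub pairs with prob 0.05 (strength 0.15)."""
    if p < 5:
        raise ValueError("hub network needs p >= 5")
    rng = np.random.default_rng(seed)
    hubs = rng.choice(p, size=4, replace=False)
    is_hub = np.zeros(p, dtype=bool)
    is_hub[hubs] = True
    upper = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if is_hub[i] and is_hub[j]:
                upper[i, j] = 0.1
            elif is_hub[i] or is_hub[j]:
                if rng.random() < 0.75:
                    upper[i, j] = 0.1
            elif rng.random() < 0.05:
                upper[i, j] = 0.15
    return _finalize("hub", upper, structure)


def make_block(
    p: int, seed: int | np.random.Generator, structure: BlockStructure | None = None
) -> NetworkSpec:
    """Eight near-equal contiguous blocks: within prob 0.45 strength 0.2,
    between prob 0.05 strength 0.15.

    Partition rule: the first (p mod 8) blocks get the extra node.
    """
    if p < 8:
        raise ValueError("block network needs p >= 8")
    rng = np.random.default_rng(seed)
    base, rem = divmod(p, 8)
    sizes = [base + 1] * rem + [base] * (8 - rem)
    labels = np.repeat(np.arange(8), sizes)
    upper = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if labels[i] == labels[j]:
                if rng.random() < 0.45:
                    upper[i, j] = 0.2
            elif rng.random() < 0.05:
                upper[i, j] = 0.15
    return _finalize("block", upper, structure)


_SCALEFREE_STRENGTHS = np.array([-0.8, -0.5, 0.5, 0.8])


def make_scalefree(
    p: int, seed: int | np.random.Generator, structure: BlockStructure | None = None
) -> NetworkSpec:
    """Preferential-attachment graph, attachment probability ~ degree^2.

    Growth starts from a 6-clique; each arriving node attaches 5 edges
    (10 new edge endpoints per step), giving density close to 10/p.
    Strengths are drawn i.i.d. uniform from {-0.8, -0.5, 0.5, 0.8}.
    """
    if p < 11:
        raise ValueError("scale-free network needs p >= 11")
    rng = np.random.default_rng(seed)
    m, core = 5, 6
    adj = np.zeros((p, p), dtype=bool)
    adj[:core, :core] = True
    np.fill_diagonal(adj, False)
    degree = adj.sum(axis=1).astype(float)
    for t in range(core, p):
        weights = degree[:t] ** 2
        probs = weights / weights.sum()
        targets = rng.choice(t, size=m, replace=False, p=probs)
        adj[t, targets] = adj[targets, t] = True
        degree[targets] += 1
        degree[t] = m
    upper = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    sel = adj[iu]
    upper[iu] = np.where(
        sel, rng.choice(_SCALEFREE_STRENGTHS, size=len(iu[0])), 0.0
    )
    return _finalize("scalefree", upper, structure)


GENERATORS = {
    "random": make_random,
    "neighbor": make_neighbor,
    "band": make_band,
    "hub": make_hub,
    "block": make_block,
    "scalefree": make_scalefree,
}


def make_network(
    topology: str,
    p: int,
    seed: int | np.random.Generator | None = None,
    structure: BlockStructure | None = None,
) -> NetworkSpec:
    """Dispatch by topology name; `band` is deterministic and ignores seed."""
    if topology not in GENERATORS:
        raise ValueError(f"unknown topology {topology!r}; one of {sorted(GENERATORS)}")
    if topology == "band":
        return make_band(p, structure=structure)
    return GENERATORS[topology](p, seed, structure=structure)
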