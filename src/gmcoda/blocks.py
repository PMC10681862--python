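"""Block-structure algebra for multiple compositional vectors.

A dataset holding d compositional vectors (e.g. bacterial 16S proportions
and fungal ITS proportions measured on the same samples) is stored as one
n x p matrix with the blocks concatenated in a fixed declared order.  The
block-indicator matrix R and the centering projection P are the two
operators everything else (likelihood, solver, simulators) is built from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BlockStructure:
    """Sizes (p1, ..., pd) of the d compositional blocks.

    Blocks are contiguous and ordered; every p x p matrix in the package
    uses this global taxon index.  Each block must have at least two
    components: a composition of length one carries no information.
    """

    block_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.block_sizes)
        if len(sizes) == 0:
            raise ValueError("need at least one block")
        if any(s < 2 for s in sizes):
            raise ValueError(f"every block size must be >= 2, got {sizes}")
        object.__setattr__(self, "block_sizes", sizes)

    @property
    def d(self) -> int:
        return len(self.block_sizes)

    @property
    def p(self) -> int:
        return sum(self.block_sizes)

    @property
    def slices(self) -> list[slice]:
        """Column slice of each block in the global index."""
        out, start = [], 0
        for s in self.block_sizes:
            out.append(slice(start, start + s))
            start += s
        return out

    def block_of(self, index: int) -> int:
        """Block number (0-based) that global column `index` belongs to."""
        start = 0
        for b, s in enumerate(self.block_sizes):
            if start <= index < start + s:
                return b
            start += s
        raise IndexError(index)


@dataclass
class CompositionDataset:
    """n x p matrix of strictly positive within-block proportions."""

    values: np.ndarray
    structure: BlockStructure

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be an n x p matrix")
        if self.values.shape[1] != self.structure.p:
            raise ValueError(
                f"data has {self.values.shape[1]} columns but structure "
                f"expects p={self.structure.p}"
            )
        if np.any(self.values <= 0):
            i, j = np.argwhere(self.values <= 0)[0]
            raise ValueError(
                f"non-positive proportion at sample {i}, taxon {j}; "
                "resolve zeros (e.g. pseudocount) before construction"
            )
        for sl in self.structure.slices:
            sums = self.values[:, sl].sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise ValueError(
                    f"block {sl} rows do not sum to 1 (max dev "
                    f"{np.abs(sums - 1).max():.2e})"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class LatentModelParams:
    """Mean and precision of the latent log-abundance normal model."""

    mean: np.ndarray
    precision: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        if not np.allclose(self.precision, self.precision.T, atol=1e-10):
            raise ValueError("precision must be symmetric")
        if np.linalg.eigvalsh(self.precision).min() <= 0:
            raise ValueError("precision must be positive definite")


def build_R(structure: BlockStructure) -> np.ndarray:
    """p x d block-indicator matrix: column j is 1 on block j, 0 elsewhere."""
    R = np.zeros((structure.p, structure.d))
    for j, sl in enumerate(structure.slices):
        R[sl, j] = 1.0
    return R


def build_P(structure: BlockStructure) -> np.ndarray:
    """p x p projection removing each block's mean: P = I - R (R'R)^-1 R'.

    P is symmetric, idempotent and annihilates R; its rank is p - d.
    """
    P = np.eye(structure.p)
    for s, sl in zip(structure.block_sizes, structure.slices):
        P[sl, sl] -= 1.0 / s
    return P
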