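"""Sampling compositional datasets from the latent log-normal model.

Latent log-abundances lnY are multivariate normal; each block of Y is then
closed to proportions (the forward map X_j = Y_j / sum_block Y), which
discards the per-block totals — exactly the information loss the estimator
has to live with.  The latent draw depends only on (mean, Omega, n, seed),
never on the block structure, so the same seed yields identical latent
logs whether the taxa are analyzed as one merged composition or split into
blocks — the design used when comparing against the single-composition
special case.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg

from .blocks import BlockStructure, CompositionDataset
from .networks import NetworkSpec


@dataclass
class SimulatedDataset:
    """A drawn dataset with its latent logs, lost totals, and the truth."""

    data: CompositionDataset
    latent_logs: np.ndarray
    totals: np.ndarray
    truth: NetworkSpec


def draw_mean(p: int, seed: int | np.random.Generator) -> np.ndarray:
    """Latent mean vector: i.i.d. Uniform(-0.5, 0.5) entries."""
    rng = np.random.default_rng(seed)
    return rng.uniform(-0.5, 0.5, size=p)


def close_to_compositions(
    latent_logs: np.ndarray, structure: BlockStructure
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block closure of exp(latent_logs); returns (proportions, log-totals)."""
    n, p = latent_logs.shape
    X = np.empty((n, p))
    totals = np.empty((n, structure.d))
    for b, sl in enumerate(structure.slices):
        block = latent_logs[:, sl]
        # subtract the block max before exponentiating for overflow safety
        shift = block.max(axis=1, keepdims=True)
        expb = np.exp(block - shift)
        sums = expb.sum(axis=1, keepdims=True)
        X[:, sl] = expb / sums
        totals[:, b] = np.log(sums[:, 0]) + shift[:, 0]
    return X, totals


def simulate(
    truth: NetworkSpec,
    mean: np.ndarray,
    n: int,
    seed: int | np.random.Generator,
    structure: BlockStructure | None = None,
) -> SimulatedDataset:
    """Draw n samples of lnY ~ N(mean, Omega_true^-1) and close per block."""
    if n < 2:
        raise ValueError("n must be >= 2")
    structure = structure or truth.structure
    rng = np.random.default_rng(seed)
    mean = np.asarray(mean, dtype=float)
    p = truth.p
    if mean.shape != (p,):
        raise ValueError(f"mean must have length {p}")
    cov = linalg.inv(truth.omega_true)
    cov = 0.5 * (cov + cov.T)
    L = linalg.cholesky(cov, lower=True)
    latent = mean + rng.standard_normal((n, p)) @ L.T
    X, totals = close_to_compositions(latent, structure)
    data = CompositionDataset(values=X, structure=structure)
    return SimulatedDataset(
        data=data, latent_logs=latent, totals=totals, truth=truth
    )


def multinomial_counts(
    data: CompositionDataset,
    depth: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Optional count-level sequencing noise: per-block multinomial resampling.

    Not used by the benchmark (the study conditions generate exact
    compositions); provided for building count tables for the real-data
    pipeline's synthetic exercises.
    """
    rng = np.random.default_rng(seed)
    counts = np.empty_like(data.values, dtype=int)
    for sl in data.structure.slices:
        for i in range(data.n):
            counts[i, sl] = rng.multinomial(depth, data.values[i, sl])
    return counts


def export_dataset(
    sim: SimulatedDataset, directory: str | Path, prefix: str = "block"
) -> list[Path]:
    """Write one full-precision TSV per block plus a manifest of block sizes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for b, sl in enumerate(sim.data.structure.slices):
        path = directory / f"{prefix}{b + 1}.tsv"
        header = "\t".join(f"taxon{j + 1}" for j in range(sl.stop - sl.start))
        np.savetxt(
            path,
            sim.data.values[:, sl],
            delimiter="\t",
            header=header,
            comments="",
            fmt="%.17g",
        )
        paths.append(path)
    manifest = directory / f"{prefix}_manifest.txt"
    manifest.write_text(
        "block_sizes\t"
        + ",".join(str(s) for s in sim.data.structure.block_sizes)
        + f"\nn\t{sim.data.n}\ntopology\t{sim.truth.topology}\n"
    )
    paths.append(manifest)
    return paths


def import_dataset(
    paths: list[str | Path], structure: BlockStructure | None = None
) -> CompositionDataset:
    """Read per-block TSVs back into a dataset (round-trips export_dataset)."""
    blocks = [np.loadtxt(p, delimiter="\t", skiprows=1, ndmin=2) for p in paths]
    values = np.hstack(blocks)
    structure = structure or BlockStructure(tuple(b.shape[1] for b in blocks))
    return CompositionDataset(values=values, structure=structure)
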