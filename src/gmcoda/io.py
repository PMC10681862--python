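"""Real-data pipeline: OTU tables in, networks out.

Reads one count table per domain (samples x taxa, TSV/CSV), applies the
prevalence filters (drop taxa then samples with more than 80% zeros,
per domain, then intersect sample IDs across domains), converts counts to
strictly positive compositions with a pseudocount, and exposes the
permutation null used to estimate the false-discovery count of the fitted
network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import BlockStructure, CompositionDataset
from .selection import EDGE_TOL, FitPath, fit_path
from .solver import PrecisionEstimate, SolverConfig, partial_correlations


@dataclass
class OtuTable:
    """Per-domain count table: samples in rows, taxa in columns."""

    counts: pd.DataFrame
    domain_label: str

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError(f"negative counts in table {self.domain_label!r}")
        if self.counts.index.duplicated().any():
            raise ValueError(f"duplicate sample IDs in {self.domain_label!r}")
        if self.counts.columns.duplicated().any():
            raise ValueError(f"duplicate taxon IDs in {self.domain_label!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class EdgeRecord:
    taxon_a: str
    taxon_b: str
    domain_a: str
    domain_b: str
    partial_correlation: float

    @property
    def pair_class(self) -> str:
        return f"{self.domain_a}-{self.domain_b}"


def read_otu_table(path: str | Path, domain_label: str) -> OtuTable:
    """Read a delimited count table (TSV/CSV auto-detected), index column first."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return OtuTable(counts=df, domain_label=domain_label)


def filter_tables(
    tables: list[OtuTable], zero_fraction: float = 0.8
) -> list[OtuTable]:
    """Prevalence-filter each table, then intersect sample IDs across tables.

    Per domain: first drop taxa whose zero fraction across samples exceeds
    `zero_fraction` (strictly), then drop samples whose zero fraction
    across the remaining taxa exceeds it.  Ordering is preserved.
    """
    if not tables:
        raise ValueError("need at least one table")
    filtered = []
    for t in tables:
        df = t.counts
        taxon_zero = (df == 0).mean(axis=0)
        df = df.loc[:, taxon_zero <= zero_fraction]
        if df.shape[1] == 0:
            raise ValueError(
                f"taxon filter emptied table {t.domain_label!r}"
            )
        sample_zero = (df == 0).mean(axis=1)
        df = df.loc[sample_zero <= zero_fraction, :]
        if df.shape[0] == 0:
            raise ValueError(
                f"sample filter emptied table {t.domain_label!r}"
            )
        filtered.append(OtuTable(counts=df, domain_label=t.domain_label))
    common = filtered[0].counts.index
    for t in filtered[1:]:
        common = common.intersection(t.counts.index, sort=False)
    if len(common) == 0:
        raise ValueError("sample intersection across domains is empty")
    return [
        OtuTable(counts=t.counts.loc[common], domain_label=t.domain_label)
        for t in filtered
    ]


def to_compositions(
    tables: list[OtuTable], pseudocount: float = 0.5
) -> CompositionDataset:
    """Counts + pseudocount, closed to proportions per domain, concatenated.

    The pseudocount is added to every count (not only zeros), which
    preserves within-sample rank order; set it to 0 for zero-free tables.
    """
    if not tables:
        raise ValueError("need at least one table")
    ids = tables[0].counts.index
    for t in tables[1:]:
        if not t.counts.index.equals(ids):
            raise ValueError("tables must share identical ordered sample IDs")
    blocks = []
    for t in tables:
        vals = t.counts.to_numpy(dtype=float) + pseudocount
        blocks.append(vals / vals.sum(axis=1, keepdims=True))
    values = np.hstack(blocks)
    structure = BlockStructure(tuple(b.shape[1] for b in blocks))
    return CompositionDataset(values=values, structure=structure)


def taxon_metadata(tables: list[OtuTable]) -> list[tuple[str, str]]:
    """(taxon_id, domain_label) per global column, in block order."""
    return [
        (taxon, t.domain_label) for t in tables for taxon in t.taxon_ids
    ]


def fit_tables(
    tables: list[OtuTable],
    pseudocount: float = 0.5,
    config: SolverConfig | None = None,
    n_lambda: int = 15,
) -> FitPath:
    """Convenience: compositions -> lambda path -> BIC selection."""
    data = to_compositions(tables, pseudocount=pseudocount)
    return fit_path(data, config=config, n_lambda=n_lambda)


def export_network(
    estimate: PrecisionEstimate | np.ndarray,
    metadata: list[tuple[str, str]],
    zero_tol: float = EDGE_TOL,
) -> tuple[list[EdgeRecord], dict[str, int]]:
    """Edge records for nonzero partial correlations plus per-class counts.

    Class counts cover every ordered domain pair present in the metadata
    (e.g. bacteria-bacteria, bacteria-fungi, fungi-fungi), zero-filled so
    the summary always has the full breakdown.
    """
    rho = partial_correlations(estimate) if not isinstance(
        estimate, np.ndarray
    ) else estimate
    p = len(rho)
    if len(metadata) != p:
        raise ValueError("metadata length must match matrix dimension")
    domains = []
    for _, dom in metadata:
        if dom not in domains:
            domains.append(dom)
    counts = {
        f"{domains[i]}-{domains[j]}": 0
        for i in range(len(domains))
        for j in range(i, len(domains))
    }
    records = []
    for i in range(p):
        for j in range(i + 1, p):
            if abs(rho[i, j]) <= zero_tol:
                continue
            dom_i, dom_j = metadata[i][1], metadata[j][1]
            ordered = sorted([dom_i, dom_j], key=domains.index)
            rec = EdgeRecord(
                taxon_a=metadata[i][0],
                taxon_b=metadata[j][0],
                domain_a=ordered[0],
                domain_b=ordered[1],
                partial_correlation=float(rho[i, j]),
            )
            records.append(rec)
            counts[rec.pair_class] += 1
    return records, counts


def write_edge_list(
    records: list[EdgeRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("taxon_a\ttaxon_b\tpair_class\tpartial_correlation\n")
        for r in records:
            fh.write(
                f"{r.taxon_a}\t{r.taxon_b}\t{r.pair_class}\t"
                f"{r.partial_correlation:.6g}\n"
            )


def permutation_false_discovery(
    tables: list[OtuTable],
    n_perm: int = 20,
    seed: int | np.random.Generator = 0,
    pseudocount: float = 0.5,
    config: SolverConfig | None = None,
    n_lambda: int = 15,
) -> tuple[float, list[int]]:
    """Permutation estimate of the false-discovery edge count.

    Each permutation independently shuffles every taxon's counts across
    samples (destroying all between-taxon dependence while preserving
    marginals), reruns the full pipeline — compositions, lambda path, BIC
    selection — and counts selected edges.  Returns the mean count and the
    per-permutation counts.
    """
    rng = np.random.default_rng(seed)
    n = len(tables[0].counts)
    counts_per_perm: list[int] = []
    for k in range(n_perm):
        permuted = []
        for t in tables:
            vals = t.counts.to_numpy().copy()
            for j in range(vals.shape[1]):
                vals[:, j] = vals[rng.permutation(n), j]
            permuted.append(
                OtuTable(
                    counts=pd.DataFrame(
                        vals, index=t.counts.index, columns=t.counts.columns
                    ),
                    domain_label=t.domain_label,
                )
            )
        try:
            path = fit_tables(
                permuted,
                pseudocount=pseudocount,
                config=config,
                n_lambda=n_lambda,
            )
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"permutation {k} failed and was excluded: {exc}")
            continue
        rho = partial_correlations(path.selected)
        iu = np.triu_indices(len(rho), k=1)
        counts_per_perm.append(int(np.sum(np.abs(rho[iu]) > EDGE_TOL)))
    if not counts_per_perm:
        raise RuntimeError("every permutation failed")
    return float(np.mean(counts_per_perm)), counts_per_perm
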