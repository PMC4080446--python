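"""Core containers shared across the pipeline.

Conventions: gene identifiers are opaque strings; networks are
:class:`networkx.Graph` objects whose edges may carry ``r`` (Pearson
correlation) and ``p`` (two-sided correlation p-value) attributes and whose
nodes may carry a boolean ``seed`` attribute; genomic intervals are 0-based,
half-open (BED); TSS positions are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

CONTROL = "control"
CASE = "case"

Edge = tuple[str, str]


def canonical_edge(a: str, b: str) -> Edge:
    """Order-independent representation of an undirected gene pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class InteractionSet:
    """Deduplicated undirected gene-gene interactions, no self-loops."""

    edges: frozenset[Edge]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "InteractionSet":
        edges = set()
        for a, b in pairs:
            if a == b:
                continue
            edges.add(canonical_edge(a, b))
        return cls(frozenset(edges))

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for e in self.edges for g in e)

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)


@dataclass
class GeneProfileMatrix:
    """Gene x sample numeric matrix with a control/case label per sample.

    ``values`` is indexed by gene id with sample ids as columns; ``groups``
    maps each sample id to ``"control"`` or ``"case"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without a group label: {missing}")
        bad = set(self.groups.unique()) - {CONTROL, CASE}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for grp in (CONTROL, CASE):
            if not (self.groups == grp).any():
                raise ValueError(f"group {grp!r} has no samples")
        if self.values.isna().any().any():
            raise ValueError("matrix contains missing values")
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_columns(self, group: str) -> pd.Index:
        return self.groups.index[self.groups == group]

    def group_values(self, group: str) -> np.ndarray:
        return self.values.loc[:, self.group_columns(group)].to_numpy(float)

    def group_means(self, group: str) -> pd.Series:
        return self.values.loc[:, self.group_columns(group)].mean(axis=1)


@dataclass
class TopologySummary:
    """Whole-network averages of the standard topological descriptors."""

    n_nodes: int
    n_edges: int
    mean_degree: float
    mean_clustering: float
    mean_betweenness: float
    powerlaw_exponent: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "mean_degree": self.mean_degree,
            "mean_clustering": self.mean_clustering,
            "mean_betweenness": self.mean_betweenness,
            "powerlaw_exponent": self.powerlaw_exponent,
        }


@dataclass
class Module:
    module_id: str
    genes: frozenset[str]
    score: float

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class ModuleSet:
    modules: list[Module]
    source: str = ""

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)


@dataclass
class InterplayResult:
    """One (methylation module, chromatin module) overlap test."""

    meth_module: str
    chrom_module: str
    background_size: int  # N
    meth_size: int  # M
    chrom_size: int  # H
    overlap_size: int  # x
    overlap_genes: frozenset[str]
    p_raw: float
    p_bonferroni: float  # NaN when the pair was below min_overlap (untested)
    tested: bool
    significant: bool


@dataclass
class NullDistribution:
    statistic: str
    observed: float
    values: np.ndarray
    tail: str  # "ge" or "le"
    p: float

    @property
    def n_replicates(self) -> int:
        return len(self.values)


@dataclass
class RegressionFit:
    """OLS line y = slope*x + intercept with a prediction band.

    ``half_width(x0)`` is the 95% (by default) prediction-interval
    half-width t_{1-a/2, n-2} * s * sqrt(1 + 1/n + (x0 - xbar)^2 / Sxx).
    """

    slope: float
    intercept: float
    resid_sd: float
    n: int
    level: float
    x_mean: float
    sxx: float
    t_crit: float
    spearman_rho: float
    spearman_p: float

    def predict(self, x0):
        return self.intercept + self.slope * np.asarray(x0, float)

    def half_width(self, x0):
        x0 = np.asarray(x0, float)
        return self.t_crit * self.resid_sd * np.sqrt(
            1.0 + 1.0 / self.n + (x0 - self.x_mean) ** 2 / self.sxx
        )

    def interval(self, x0):
        yhat = self.predict(x0)
        hw = self.half_width(x0)
        return yhat - hw, yhat + hw


@dataclass
class TSSTable:
    """Rows of (gene, chrom, position, strand); one row per (gene, TSS)."""

    table: pd.DataFrame  # columns: gene, chrom, pos, strand

    def __post_init__(self) -> None:
        required = ["gene", "chrom", "pos", "strand"]
        if list(self.table.columns[:4]) != required:
            raise ValueError(f"TSS table needs columns {required}")
        if (self.table["pos"] < 0).any():
            raise ValueError("TSS positions must be >= 0")
        if not self.table["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.table["gene"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PeakSet:
    """BED-like intervals with a nonnegative intensity score."""

    table: pd.DataFrame  # columns: chrom, start, end, score

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "score"]
        if list(self.table.columns[:4]) != required:
            raise ValueError(f"peak table needs columns {required}")
        if (self.table["start"] >= self.table["end"]).any():
            bad = self.table.index[self.table["start"] >= self.table["end"]][0]
            raise ValueError(f"empty or inverted interval at row {bad}")
        if (self.table["score"] < 0).any():
            raise ValueError("peak scores must be >= 0")

    def __len__(self) -> int:
        return len(self.table)

    def midpoints(self) -> np.ndarray:
        s = self.table["start"].to_numpy()
        e = self.table["end"].to_numpy()
        return (s + e) // 2
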