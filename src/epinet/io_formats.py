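"""Readers and writers for every on-disk format the pipeline touches.

All parsers validate strictly and raise :class:`FormatError` with the
offending line number rather than silently coercing. Writers are inverses of
the corresponding readers (round-trip identity, up to float formatting
precision for networks).

Formats: SIF interaction lists (2- or 3-column), TSV gene x sample matrices
with a separate sample->group table, BED4 peak files (0-based half-open),
TSV TSS tables, module tables and weighted-network edge tables.
"""

from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx
import pandas as pd

from .types import (
    GeneProfileMatrix,
    InteractionSet,
    Module,
    ModuleSet,
    PeakSet,
    TSSTable,
    canonical_edge,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed on-disk input, reported with file and line number."""


# ---------------------------------------------------------------- SIF


def read_sif(path) -> InteractionSet:
    """Parse a Simple Interaction Format file into an undirected edge set.

    Accepts ``nodeA relation nodeB`` (3 columns) and ``nodeA nodeB``
    (2 columns) rows, mixed freely. Duplicate edges (in either orientation)
    and self-loops are removed; their counts are logged.
    """
    edges: set[tuple[str, str]] = set()
    n_dup = n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) == 2:
                a, b = fields
            elif len(fields) == 3:
                a, _, b = fields
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(fields)}"
                )
            if not a or not b:
                raise FormatError(f"{path}:{lineno}: empty node id")
            if a == b:
                n_self += 1
                continue
            edge = canonical_edge(a, b)
            if edge in edges:
                n_dup += 1
            else:
                edges.add(edge)
    if n_dup or n_self:
        logger.info(
            "read_sif(%s): removed %d duplicate and %d self-loop rows",
            path, n_dup, n_self,
        )
    return InteractionSet(frozenset(edges))


def write_sif(interactions: InteractionSet, path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(interactions.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")


# ---------------------------------------------------------------- matrices


def read_matrix(path, groups_path=None) -> GeneProfileMatrix | pd.DataFrame:
    """Read a TSV matrix (header = sample ids, first column = gene ids).

    With ``groups_path`` (TSV ``sample<TAB>group``) a
    :class:`GeneProfileMatrix` is returned, otherwise the bare DataFrame.
    Duplicate gene rows and non-numeric cells are rejected with locations.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated(keep=False)]
        first = dup.unique()[0]
        lines = [i + 2 for i, g in enumerate(df.index) if g == first]
        raise FormatError(f"{path}: duplicate gene id {first!r} on lines {lines}")
    try:
        values = df.astype(float)
    except ValueError:
        for i, (gene, row) in enumerate(df.iterrows()):
            for col, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric cell {cell!r} at line {i + 2}, "
                        f"column {col!r}"
                    ) from None
        raise
    if values.isna().any().any():
        raise FormatError(f"{path}: missing values present")
    if groups_path is None:
        return values
    groups = read_groups(groups_path)
    return GeneProfileMatrix(values, groups)


def write_matrix(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="gene")


def read_groups(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"],
                     dtype=str, comment="#")
    return pd.Series(df["group"].values, index=df["sample"].values, name="group")


def write_groups(groups: pd.Series, path) -> None:
    with open(path, "w") as fh:
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------- BED / TSS


def read_bed(path) -> PeakSet:
    """Read a BED4 file (chrom, start, end, score); 0-based half-open."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                score = float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: empty interval [{start}, {end})"
                )
            if score < 0:
                raise FormatError(f"{path}:{lineno}: negative score {score}")
            rows.append((chrom, start, end, score))
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "score"]))


def write_bed(peaks: PeakSet, path) -> None:
    peaks.table.to_csv(path, sep="\t", header=False, index=False)


def read_tss(path) -> TSSTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str,
                                            "pos": int, "strand": str})
    return TSSTable(df[["gene", "chrom", "pos", "strand"]])


def write_tss(tss: TSSTable, path) -> None:
    tss.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- gene sets


def read_gene_set(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_set(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


# ---------------------------------------------------------------- networks


def read_network(path) -> nx.Graph:
    """Read a weighted-network edge table: geneA, geneB, r, p (TSV, header)."""
    df = pd.read_csv(path, sep="\t", dtype={"geneA": str, "geneB": str})
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.geneA, row.geneB, r=float(row.r), p=float(row.p))
    return g


def write_network(net: nx.Graph, path) -> None:
    rows = [
        {"geneA": a, "geneB": b, "r": d.get("r", float("nan")),
         "p": d.get("p", float("nan"))}
        for a, b, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["geneA", "geneB", "r", "p"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------- modules


def write_modules(modules: ModuleSet, path) -> None:
    """Module table: module_id, score, size, comma-joined gene list."""
    with open(path, "w") as fh:
        fh.write("module_id\tscore\tsize\tgenes\n")
        for m in modules:
            fh.write(
                f"{m.module_id}\t{m.score:.6g}\t{m.size}\t"
                f"{','.join(sorted(m.genes))}\n"
            )


def read_modules(path, source: str = "") -> ModuleSet:
    df = pd.read_csv(path, sep="\t", dtype={"module_id": str, "genes": str})
    mods = [
        Module(row.module_id, frozenset(row.genes.split(",")), float(row.score))
        for row in df.itertuples(index=False)
    ]
    return ModuleSet(mods, source=source)


def write_report(report: dict, path) -> None:
    """Write the pipeline summary as a deterministic, human-readable text file."""
    import json

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
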