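"""Readers, writers and filtering rules for the pipeline's tabular and graph inputs.

Conventions
-----------
* Gene interaction network: two-column delimited text (TSV), one undirected
  edge per line, gene symbols matched case-sensitively after whitespace
  stripping.
* Expression matrix: CSV, rows = samples (cell lines), columns = genes,
  nonnegative intensities.
* Drug-response table: CSV, rows = cell lines, columns = drugs, values =
  log(IC50); missing entries are empty cells (NaN internally).
* Descriptor table: CSV, rows = drugs, columns = cheminformatic descriptors,
  real-valued, missing allowed.
* Gene sets: GMT (set name, description, tab-separated member genes).

All tables are plain :class:`pandas.DataFrame` objects with the identifier
column as the index; validation lives in the readers and in
:func:`validate_expression` / :func:`validate_responses`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger("drugsense")

__all__ = [
    "GeneNetwork",
    "read_edge_list",
    "write_edge_list",
    "read_expression",
    "read_responses",
    "read_descriptors",
    "read_table",
    "write_table",
    "read_gmt",
    "restrict_to_lcc",
    "filter_cell_lines",
    "filter_drugs",
    "validate_expression",
]


@dataclass(frozen=True)
class GeneNetwork:
    """Simple undirected graph of gene (or descriptor) nodes with a fixed node order.

    Node order is the sorted list of node identifiers; every matrix indexed by
    network nodes elsewhere in the package follows this order.
    """

    graph: nx.Graph
    nodes: tuple = field(init=False)

    def __post_init__(self):
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("network must not contain self-loops")
        object.__setattr__(self, "nodes", tuple(sorted(self.graph.nodes)))

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edges(self) -> set:
        return {frozenset(e) for e in self.graph.edges}

    def neighbors(self, node) -> set:
        return set(self.graph.neighbors(node))

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)


def read_edge_list(path: str | Path) -> GeneNetwork:
    """Read a two-column edge list into a :class:`GeneNetwork`.

    Self-loops and duplicate edges are silently dropped; the counts are logged.
    Raises ``ValueError`` on malformed lines (with line number) or empty files.
    """
    graph = nx.Graph()
    n_self, n_dup = 0, 0
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed edge at line {lineno}: {line.rstrip()!r}")
            u, v = (p.strip() for p in parts)
            n_lines += 1
            if u == v:
                n_self += 1
                graph.add_node(u)
                continue
            if graph.has_edge(u, v):
                n_dup += 1
                continue
            graph.add_edge(u, v)
    if n_lines == 0:
        raise ValueError(f"{path}: empty edge list")
    if n_self or n_dup:
        logger.info("read_edge_list(%s): dropped %d self-loops, %d duplicate edges", path, n_self, n_dup)
    return GeneNetwork(graph)


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV with a header row and first column = identifiers."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate row identifiers")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate column identifiers")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path)


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check the samples x genes expression matrix: nonnegative, no missing."""
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if (expr.values < 0).any():
        raise ValueError("expression values must be nonnegative (linear scale, not log)")
    return expr


def read_expression(path: str | Path) -> pd.DataFrame:
    return validate_expression(read_table(path))


def read_responses(path: str | Path) -> pd.DataFrame:
    """Cell lines x drugs log(IC50) table; empty cells become NaN."""
    return read_table(path)


def read_descriptors(path: str | Path) -> pd.DataFrame:
    """Drugs x descriptors table; missing values allowed."""
    return read_table(path)


def read_gmt(path: str | Path) -> dict[str, set]:
    """Read GMT gene sets: name <tab> description <tab> member genes..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT record at line {lineno}")
            name, members = parts[0], {g.strip() for g in parts[2:] if g.strip()}
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set name {name!r}")
            sets[name] = members
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def restrict_to_lcc(network: GeneNetwork, keep: Iterable | None = None) -> GeneNetwork:
    """Induced subgraph on ``keep`` (if given), then its largest connected component.

    Component-size ties are broken by the lexicographically smallest member
    node, so the result is deterministic.
    """
    graph = network.graph
    if keep is not None:
        keep = set(keep) & set(graph.nodes)
        if not keep:
            raise ValueError("no network nodes remain after intersection with keep set")
        graph = graph.subgraph(keep)
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    components = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    lcc = components[0]
    dropped = graph.number_of_nodes() - len(lcc)
    if dropped:
        logger.info("restrict_to_lcc: kept %d nodes, dropped %d outside the LCC", len(lcc), dropped)
    return GeneNetwork(nx.Graph(graph.subgraph(lcc)))


def filter_cell_lines(responses: pd.DataFrame, max_missing_frac: float = 0.8) -> pd.DataFrame:
    """Drop cell lines missing responses for strictly more than ``max_missing_frac`` of drugs."""
    if not 0 < max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in (0, 1]")
    missing = responses.isna().mean(axis=1)
    kept = responses.loc[missing <= max_missing_frac]
    if kept.empty:
        raise ValueError("all cell lines removed by missingness filter")
    if len(kept) < len(responses):
        logger.info("filter_cell_lines: dropped %d of %d cell lines", len(responses) - len(kept), len(responses))
    return kept


def filter_drugs(responses: pd.DataFrame, min_coverage_frac: float = 0.5) -> pd.DataFrame:
    """Keep drugs with observed responses for strictly more than ``min_coverage_frac`` of cell lines."""
    if not 0 < min_coverage_frac <= 1:
        raise ValueError("min_coverage_frac must be in (0, 1]")
    coverage = responses.notna().mean(axis=0)
    kept = responses.loc[:, coverage > min_coverage_frac]
    if kept.shape[1] == 0:
        raise ValueError("all drugs removed by coverage filter")
    if kept.shape[1] < responses.shape[1]:
        logger.info("filter_drugs: dropped %d of %d drugs", responses.shape[1] - kept.shape[1], responses.shape[1])
    return kept
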