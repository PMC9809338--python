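"""Directed gene-network data model, file I/O and basic structural statistics.

The network is a simple directed graph over gene symbols, held as a
:class:`networkx.DiGraph`.  Distance-based statistics (characteristic path
length, giant component) are computed on the underlying *undirected* simple
graph with self-loops discarded: connectivity, not reachability, is what
they measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csgraph

__all__ = [
    "ParseError",
    "DegreeSummary",
    "PathStats",
    "load_edge_list",
    "write_edge_list",
    "load_gene_list",
    "induce_disease_network",
    "degree_profile",
    "characteristic_path_length",
    "giant_component_fraction",
    "path_stats",
    "undirected_view",
]

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised on malformed network or gene-list input."""


@dataclass(frozen=True)
class DegreeSummary:
    """Per-node directed degrees and the mean-degree baseline.

    ``table`` has one row per gene with columns ``in_degree``, ``out_degree``,
    ``degree_difference`` (= out − in), ``in_above_baseline`` and
    ``out_above_baseline``.  ``baseline`` is edges-per-node (|E|/|N|) unless
    a fixed value was supplied.
    """

    table: pd.DataFrame
    baseline: float

    @property
    def fraction_nonnegative_difference(self) -> float:
        return float((self.table["degree_difference"] >= 0).mean())


@dataclass(frozen=True)
class PathStats:
    """Characteristic path length and giant-component summary.

    ``L`` is None when no pair of nodes is connected (the "no-paths" marker).
    """

    L: float | None
    gc_fraction: float
    n_reachable_pairs: int


def _strip_comment_lines(lines: Iterable[str]) -> Iterable[tuple[int, str]]:
    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield i, line


def load_edge_list(
    path: str | Path,
    fmt: str = "tsv",
    header: bool = False,
    case_fold: bool = False,
) -> nx.DiGraph:
    """Read a directed network from a two-column edge list or a SIF file.

    TSV rows are ``source <tab/space> target`` (extra columns ignored); SIF
    rows are ``source interaction target [target ...]`` and fan out to one
    edge per target.  Duplicate edges collapse; node symbols are
    case-preserved unless ``case_fold`` lowercases them at load.

    Raises
    ------
    ParseError
        On an empty file or a row with too few fields (the line number is
        named in the message).
    """
    path = Path(path)
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format {fmt!r}; expected 'tsv' or 'sif'")
    net = nx.DiGraph()
    n_rows = 0
    with path.open() as fh:
        for lineno, line in _strip_comment_lines(fh):
            fields = line.split()
            if header and n_rows == 0:  # first non-comment row is the header
                n_rows += 1
                continue
            if fmt == "tsv":
                if len(fields) < 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}"
                    )
                pairs = [(fields[0], fields[1])]
            else:
                if len(fields) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: SIF row needs source, interaction and "
                        f"at least one target (got {len(fields)} fields)"
                    )
                pairs = [(fields[0], t) for t in fields[2:]]
            if case_fold:
                pairs = [(s.lower(), t.lower()) for s, t in pairs]
            net.add_edges_from(pairs)
            n_rows += 1
    if net.number_of_nodes() == 0:
        raise ParseError(f"{path}: no edges found")
    return net


def write_edge_list(net: nx.DiGraph, path: str | Path) -> None:
    """Write the network as a two-column TSV, edges sorted for stable output."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v in sorted(net.edges()):
            fh.write(f"{u}\t{v}\n")


def load_gene_list(path: str | Path, case_fold: bool = False) -> set[str]:
    """Read a gene list, one symbol per line; '#' comment lines are skipped."""
    genes: set[str] = set()
    with Path(path).open() as fh:
        for _, line in _strip_comment_lines(fh):
            sym = line.split()[0]
            genes.add(sym.lower() if case_fold else sym)
    return genes


def induce_disease_network(reference: nx.DiGraph, deg_list: set[str]) -> nx.DiGraph:
    """Induce the disease network: subgraph on the gene list, isolates dropped.

    The reference network is restricted to genes present in ``deg_list``;
    nodes left with no edge inside the induced graph (single nodes) are then
    removed.  An empty result is legal and logged.
    """
    if not deg_list:
        raise ValueError("deg_list must be non-empty")
    keep = set(deg_list) & set(reference.nodes)
    sub = nx.DiGraph(reference.subgraph(keep))
    isolates = [n for n in sub.nodes if sub.in_degree(n) + sub.out_degree(n) == 0]
    sub.remove_nodes_from(isolates)
    logger.info(
        "induced disease network: %d/%d listed genes mapped, %d isolates removed, "
        "%d nodes / %d edges retained",
        len(keep), len(deg_list), len(isolates),
        sub.number_of_nodes(), sub.number_of_edges(),
    )
    return sub


def degree_profile(net: nx.DiGraph, baseline: float | str = "auto") -> DegreeSummary:
    """Per-node in/out degree, degree difference, and above-baseline flags.

    ``baseline="auto"`` uses the mean directed degree |E|/|N|.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if baseline == "auto":
        base = net.number_of_edges() / net.number_of_nodes()
    else:
        base = float(baseline)
    if base <= 0:
        raise ValueError(f"baseline must be positive, got {base}")
    genes = sorted(net.nodes)
    tab = pd.DataFrame(
        {
            "in_degree": [net.in_degree(g) for g in genes],
            "out_degree": [net.out_degree(g) for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    tab["degree_difference"] = tab["out_degree"] - tab["in_degree"]
    tab["in_above_baseline"] = tab["in_degree"] > base
    tab["out_above_baseline"] = tab["out_degree"] > base
    return DegreeSummary(table=tab, baseline=base)


def undirected_view(net: nx.Graph) -> nx.Graph:
    """Underlying undirected simple graph with self-loops removed."""
    und = nx.Graph()
    und.add_nodes_from(net.nodes)
    und.add_edges_from((u, v) for u, v in net.edges() if u != v)
    return und


def _undirected_distance_matrix(net: nx.Graph) -> np.ndarray:
    """All-pairs hop distances on the undirected simple graph (inf = no path)."""
    nodes = sorted(net.nodes)
    und = undirected_view(net)
    adj = nx.to_scipy_sparse_array(und, nodelist=nodes, format="csr")
    return csgraph.shortest_path(adj, method="D", unweighted=True, directed=False)


def path_stats(net: nx.Graph) -> PathStats:
    """Characteristic path length, giant-component fraction and reachable pairs.

    L is the mean over nodes of the mean distance to nodes in the same
    component (self-distances and cross-component pairs excluded).  When the
    network has no connected pair at all, L is None.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("network is empty")
    dist = _undirected_distance_matrix(net)
    np.fill_diagonal(dist, np.inf)
    finite = np.isfinite(dist)
    n_pairs = int(finite.sum())
    if n_pairs == 0:
        L = None
    else:
        counts = finite.sum(axis=1)
        sums = np.where(finite, dist, 0.0).sum(axis=1)
        has_partner = counts > 0
        li = sums[has_partner] / counts[has_partner]
        L = float(li.mean())
    return PathStats(L=L, gc_fraction=giant_component_fraction(net), n_reachable_pairs=n_pairs)


def characteristic_path_length(net: nx.Graph) -> float | None:
    """Mean shortest-path distance over connected node pairs (None if no pair).

    Requires at least two nodes.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("characteristic path length needs >= 2 nodes")
    return path_stats(net).L


def giant_component_fraction(net: nx.Graph) -> float:
    """Largest (weakly) connected component size over total node count."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("network is empty")
    und = net.to_undirected(as_view=True) if net.is_directed() else net
    largest = max(len(c) for c in nx.connected_components(nx.Graph(und)))
    return largest / n
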