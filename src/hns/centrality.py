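"""The eleven hub/topology metrics used for core-gene ranking and fusion.

All metrics are computed on the underlying undirected simple graph (the
convention of the cytoHubba toolchain these definitions come from):

degree, MCC (maximal clique centrality), MNC (maximum neighborhood
component), DMNC (density of MNC, exponent 1.7), closeness (harmonic form,
well-defined on disconnected graphs), eccentricity score (1/ecc),
radiality, bottleneck, stress, betweenness (ordered source-target pairs,
unnormalized), and EPC (edge percolated component, Monte-Carlo).
"""

from __future__ import annotations

import math
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse import csgraph

from .graph import undirected_view

__all__ = [
    "METRICS",
    "mcc",
    "mnc",
    "dmnc",
    "path_metrics",
    "epc",
    "centrality_table",
    "top_k",
]

METRICS = (
    "degree",
    "mcc",
    "mnc",
    "dmnc",
    "closeness",
    "eccentricity",
    "radiality",
    "bottleneck",
    "stress",
    "betweenness",
    "epc",
)

DEFAULT_CLIQUE_CAP = 2_000_000


def mcc(net: nx.Graph, clique_cap: int = DEFAULT_CLIQUE_CAP) -> dict[str, int]:
    """Maximal clique centrality: MCC(v) = Σ over maximal cliques C ∋ v of (|C|−1)!.

    Maximal cliques are enumerated with Bron–Kerbosch (pivoting).  A node
    whose neighbors are pairwise non-adjacent only belongs to maximal cliques
    of size 2, so its MCC equals its degree; an isolated node scores 0.

    Raises if the number of maximal cliques exceeds ``clique_cap`` (guards
    pathological inputs; raise the cap explicitly to proceed).
    """
    und = undirected_view(net)
    scores: dict[str, int] = {v: 0 for v in und.nodes}
    n_cliques = 0
    for clique in nx.find_cliques(und):
        n_cliques += 1
        if n_cliques > clique_cap:
            raise RuntimeError(
                f"more than {clique_cap} maximal cliques; raise clique_cap to proceed"
            )
        if len(clique) < 2:
            continue  # isolated node: contributes 0
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores


def _neighborhood_component(und: nx.Graph, v: str) -> nx.Graph:
    """Largest connected component of the open-neighborhood-induced subgraph."""
    nbrs = set(und.neighbors(v))
    if not nbrs:
        return nx.Graph()
    sub = und.subgraph(nbrs)
    comp = max(nx.connected_components(sub), key=lambda c: (len(c), sorted(c)[0]))
    return und.subgraph(comp)


def mnc(net: nx.Graph, v: str) -> int:
    """Maximum neighborhood component: |V| of the largest component of G[N(v)]."""
    und = undirected_view(net)
    return _neighborhood_component(und, v).number_of_nodes()


def dmnc(net: nx.Graph, v: str) -> float:
    """Density of the maximum neighborhood component: |E| / |V|^1.7.

    Zero when the component has no edges (including isolated nodes).
    """
    und = undirected_view(net)
    comp = _neighborhood_component(und, v)
    ne = comp.number_of_edges()
    if ne == 0:
        return 0.0
    return ne / comp.number_of_nodes() ** 1.7


def path_metrics(net: nx.Graph) -> pd.DataFrame:
    """Shortest-path metrics per node, one BFS sweep per source.

    Columns: ``closeness`` (harmonic, Σ 1/d), ``eccentricity`` (1/ecc within
    the node's component; 0 for isolated nodes), ``radiality``
    (Σ (Δc + 1 − d)/(nc − 1) over the component, with Δc/nc its diameter and
    size), ``stress`` (# shortest paths through the node, ordered pairs),
    ``betweenness`` (Brandes, ordered pairs, unnormalized) and ``bottleneck``
    (# of BFS trees, lexicographic parent tie-break, in which the node's
    subtree holds more than a quarter of the tree).
    """
    und = undirected_view(net)
    nodes = sorted(und.nodes)
    pos = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    adj = {g: sorted(und.neighbors(g)) for g in nodes}

    closeness = np.zeros(n)
    ecc = np.zeros(n)  # raw eccentricity per node
    far_sum = np.zeros(n)  # Σ distances within component
    betweenness = np.zeros(n)
    stress = np.zeros(n)
    bottleneck = np.zeros(n, dtype=int)

    comp_of = {}
    comp_sizes = []
    comp_diam = []
    for comp in nx.connected_components(und):
        cid = len(comp_sizes)
        comp_sizes.append(len(comp))
        comp_diam.append(0)
        for g in comp:
            comp_of[g] = cid

    for s in nodes:
        # BFS with shortest-path counts, lexicographic first-parent
        dist = {s: 0}
        sigma = {s: 1}
        parent = {s: None}  # lex-smallest predecessor (bottleneck tree)
        preds: dict[str, list[str]] = {s: []}
        order = [s]
        q = deque([s])
        while q:
            u = q.popleft()
            du = dist[u]
            for w in adj[u]:
                if w not in dist:
                    dist[w] = du + 1
                    sigma[w] = 0
                    preds[w] = []
                    parent[w] = u
                    order.append(w)
                    q.append(w)
                if dist[w] == du + 1:
                    sigma[w] += sigma[u]
                    preds[w].append(u)
                    if u < parent[w]:
                        parent[w] = u

        si = pos[s]
        dmax = 0
        for g, d in dist.items():
            if g == s:
                continue
            closeness[si] += 1.0 / d
            far_sum[si] += d
            dmax = max(dmax, d)
        ecc[si] = dmax
        cid = comp_of[s]
        comp_diam[cid] = max(comp_diam[cid], dmax)

        # Brandes accumulation for betweenness; phi for stress
        delta = {g: 0.0 for g in order}
        phi = {g: 0.0 for g in order}
        for w in reversed(order):
            for u in preds[w]:
                delta[u] += sigma[u] / sigma[w] * (1 + delta[w])
                phi[u] += 1 + phi[w]
            if w != s:
                betweenness[pos[w]] += delta[w]
                stress[pos[w]] += sigma[w] * phi[w]

        # bottleneck: subtree sizes in the lexicographic BFS tree
        subtree = {g: 1 for g in order}
        for w in reversed(order):
            p = parent[w]
            if p is not None:
                subtree[p] += subtree[w]
        tree_n = len(order)
        for g in order:
            if g != s and subtree[g] > tree_n / 4:
                bottleneck[pos[g]] += 1

    radiality = np.zeros(n)
    ecc_score = np.zeros(n)
    for g in nodes:
        i = pos[g]
        cid = comp_of[g]
        nc = comp_sizes[cid]
        if nc > 1:
            radiality[i] = ((comp_diam[cid] + 1) * (nc - 1) - far_sum[i]) / (nc - 1)
        if ecc[i] > 0:
            ecc_score[i] = 1.0 / ecc[i]

    return pd.DataFrame(
        {
            "closeness": closeness,
            "eccentricity": ecc_score,
            "radiality": radiality,
            "bottleneck": bottleneck,
            "stress": stress,
            "betweenness": betweenness,
        },
        index=pd.Index(nodes, name="gene"),
    )


def epc(
    net: nx.Graph,
    realizations: int = 1000,
    edge_keep_prob: float = 0.5,
    seed: int | np.random.Generator | None = None,
) -> dict[str, float]:
    """Edge percolated component: mean size of the node's component under
    independent edge percolation (each edge kept with ``edge_keep_prob``).
    """
    if realizations < 1:
        raise ValueError("realizations must be >= 1")
    if not 0.0 <= edge_keep_prob <= 1.0:
        raise ValueError("edge_keep_prob must be in [0, 1]")
    und = undirected_view(net)
    nodes = sorted(und.nodes)
    pos = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    edges = np.array(
        [(pos[u], pos[v]) for u, v in und.edges()], dtype=np.int64
    ).reshape(-1, 2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    acc = np.zeros(n)
    for _ in range(realizations):
        keep = rng.random(len(edges)) < edge_keep_prob
        kept = edges[keep]
        data = np.ones(len(kept))
        adj = csr_array((data, (kept[:, 0], kept[:, 1])), shape=(n, n))
        _, labels = csgraph.connected_components(adj, directed=False)
        sizes = np.bincount(labels)
        acc += sizes[labels]
    return {g: float(acc[pos[g]] / realizations) for g in nodes}


def centrality_table(
    net: nx.Graph,
    epc_realizations: int = 1000,
    epc_keep_prob: float = 0.5,
    clique_cap: int = DEFAULT_CLIQUE_CAP,
    seed: int | None = None,
) -> pd.DataFrame:
    """All eleven hub metrics as one table, rows = genes (sorted), columns = METRICS.

    MCC values (exact integers, possibly huge) are stored as floats here;
    downstream consumers are rank-based, so the conversion is harmless.  Use
    :func:`mcc` directly for exact values.
    """
    und = undirected_view(net)
    nodes = sorted(und.nodes)
    mcc_scores = mcc(net, clique_cap=clique_cap)
    mnc_col = []
    dmnc_col = []
    for v in nodes:
        comp = _neighborhood_component(und, v)
        mnc_col.append(comp.number_of_nodes())
        ne = comp.number_of_edges()
        dmnc_col.append(ne / comp.number_of_nodes() ** 1.7 if ne else 0.0)
    paths = path_metrics(net)
    epc_scores = epc(net, realizations=epc_realizations, edge_keep_prob=epc_keep_prob, seed=seed)
    tab = pd.DataFrame(
        {
            "degree": [und.degree(v) for v in nodes],
            "mcc": [float(mcc_scores[v]) for v in nodes],
            "mnc": mnc_col,
            "dmnc": dmnc_col,
        },
        index=pd.Index(nodes, name="gene"),
    )
    tab = tab.join(paths)
    tab["epc"] = [epc_scores[v] for v in nodes]
    return tab[list(METRICS)]


def top_k(table: pd.DataFrame, metric: str, k: int) -> list[str]:
    """Top-k genes by one metric, descending, ties broken lexicographically."""
    if metric not in table.columns:
        raise ValueError(f"unknown metric {metric!r}; valid: {', '.join(table.columns)}")
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(table.index, key=lambda g: (-table.at[g, metric], g))
    return ranked[:k]
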