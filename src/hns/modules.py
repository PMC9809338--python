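"""Module detection and network-structure-entropy arbitration.

Three detectors are compared — weakly connected components, Markov
clustering (MCL), and molecular complex detection (MCODE) — and the method
whose modules have the lowest network structure entropy is kept.  The
entropy of a node set is E = −Σ Ii ln Ii with Ii = ki / Σ kj, the
degree-normalized importance of node i in the induced undirected subgraph;
a degree-regular subgraph on n nodes attains the maximum ln n, and lower
entropy means more homogeneous (more stable) modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph import undirected_view

__all__ = [
    "ModulePartition",
    "connected_components_modules",
    "mcl_modules",
    "mcode_modules",
    "structure_entropy",
    "method_entropy",
    "select_method_by_entropy",
]

METHOD_PREFERENCE = ("mcode", "mcl", "connected_components")  # tie-break order


@dataclass
class ModulePartition:
    """Modules from one detector, ordered, each a sorted gene list (size ≥ 2)."""

    method: str
    modules: list[list[str]]
    parameters: dict = field(default_factory=dict)
    method_entropy: float | None = None
    per_module_entropy: list[float] | None = None

    def node_union(self) -> set[str]:
        return {g for mod in self.modules for g in mod}


def _finalize(mods: list[set[str]]) -> list[list[str]]:
    """Drop sub-pair modules, sort members, order by (size desc, lex)."""
    kept = [sorted(m) for m in mods if len(m) >= 2]
    kept.sort(key=lambda m: (-len(m), m[0]))
    return kept


def connected_components_modules(net: nx.Graph) -> ModulePartition:
    """Weakly connected components as modules (singletons excluded)."""
    und = undirected_view(net)
    mods = [set(c) for c in nx.connected_components(und)]
    return ModulePartition(method="connected_components", modules=_finalize(mods))


def mcl_modules(
    net: nx.Graph,
    inflation: float = 2.0,
    iterations: int = 16,
    tol: float = 1e-8,
    attractor_tol: float = 1e-6,
) -> ModulePartition:
    """Markov clustering on the undirected graph with unit self-loops.

    Alternates expansion (matrix squaring) and inflation (entrywise power
    then column renormalization) for ``iterations`` rounds or until the
    column-stochastic matrix changes by less than ``tol`` in max norm.
    Clusters are the attractor basins: columns sharing an attractor row
    (diagonal mass > ``attractor_tol``) are merged.  Fully deterministic.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    und = undirected_view(net)
    nodes = sorted(und.nodes)
    n = len(nodes)
    if n == 0:
        return ModulePartition(method="mcl", modules=[])
    pos = {g: i for i, g in enumerate(nodes)}
    m = np.eye(n)
    for u, v in und.edges():
        m[pos[u], pos[v]] = 1.0
        m[pos[v], pos[u]] = 1.0
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(iterations):
        prev = m
        m = m @ m
        m = m ** inflation
        m /= m.sum(axis=0, keepdims=True)
        if np.max(np.abs(m - prev)) < tol:
            break

    # union columns through shared attractor rows
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    attractors = [i for i in range(n) if m[i, i] > attractor_tol]
    for a in attractors:
        members = np.nonzero(m[a] > attractor_tol)[0]
        for j in members:
            ra, rj = find(a), find(int(j))
            if ra != rj:
                parent[rj] = ra
    clusters: dict[int, set[str]] = {}
    for g in nodes:
        clusters.setdefault(find(pos[g]), set()).add(g)
    return ModulePartition(
        method="mcl",
        modules=_finalize(list(clusters.values())),
        parameters={"inflation": inflation, "iterations": iterations},
    )


def _mcode_weights(und: nx.Graph, degree_cutoff: int) -> dict[str, float]:
    """MCODE vertex weight: core number of the densest k-core of the closed
    neighborhood, times that k-core's edge density."""
    weights: dict[str, float] = {}
    for v in und.nodes:
        closed = set(und.neighbors(v)) | {v}
        sub = und.subgraph(closed)
        if sub.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core_nums = nx.core_number(sub)
        kmax = max(core_nums.values())
        core = sub.subgraph([g for g, c in core_nums.items() if c >= kmax])
        nv = core.number_of_nodes()
        density = 2 * core.number_of_edges() / (nv * (nv - 1)) if nv > 1 else 0.0
        weights[v] = kmax * density
    return weights


def mcode_modules(
    net: nx.Graph,
    degree_cutoff: int = 2,
    k_core: int = 2,
    node_score_threshold: float = 0.2,
) -> ModulePartition:
    """Molecular complex detection: dense-region extraction by vertex weighting.

    Nodes are weighted by local neighborhood density; seeds are taken in
    decreasing weight (nodes below ``degree_cutoff`` cannot seed), and a
    complex grows breadth-first over neighbors whose weight is at least
    seed_weight × (1 − node_score_threshold).  Each node joins at most one
    complex.  Complexes not containing a k-core of order ≥ ``k_core`` are
    discarded.  Haircut and fluff post-processing are off.  Modules are
    ordered by MCODE score (density × size) descending.
    """
    und = undirected_view(net)
    weights = _mcode_weights(und, degree_cutoff)
    seeds = sorted(
        (v for v in und.nodes if und.degree(v) >= degree_cutoff),
        key=lambda v: (-weights[v], v),
    )
    used: set[str] = set()
    complexes: list[set[str]] = []
    for seed in seeds:
        if seed in used:
            continue
        cutoff = weights[seed] * (1.0 - node_score_threshold)
        complex_nodes = {seed}
        frontier = [seed]
        used.add(seed)
        while frontier:
            nxt = []
            for u in frontier:
                for w in sorted(und.neighbors(u)):
                    if w in used or w in complex_nodes:
                        continue
                    if weights[w] >= cutoff:
                        complex_nodes.add(w)
                        used.add(w)
                        nxt.append(w)
            frontier = nxt
        if len(complex_nodes) < 2:
            continue
        sub = und.subgraph(complex_nodes)
        if max(nx.core_number(sub).values(), default=0) >= k_core:
            complexes.append(complex_nodes)

    def score(mod: set[str]) -> float:
        sub = und.subgraph(mod)
        nv = sub.number_of_nodes()
        density = 2 * sub.number_of_edges() / (nv * (nv - 1)) if nv > 1 else 0.0
        return density * nv

    kept = [sorted(m) for m in complexes if len(m) >= 2]
    kept.sort(key=lambda m: (-score(set(m)), -len(m), m[0]))
    return ModulePartition(
        method="mcode",
        modules=kept,
        parameters={
            "degree_cutoff": degree_cutoff,
            "k_core": k_core,
            "node_score_threshold": node_score_threshold,
        },
    )


def structure_entropy(net: nx.Graph, node_set: set[str] | None = None) -> float:
    """Network structure entropy of (the induced subgraph on) a node set, in nats.

    E = −Σ Ii ln Ii with Ii = ki / Σ kj on the induced undirected simple
    subgraph; zero-degree nodes contribute nothing.  Raises on an edgeless
    induced subgraph, where importance is undefined.
    """
    und = undirected_view(net)
    if node_set is not None:
        missing = set(node_set) - set(und.nodes)
        if missing:
            raise ValueError(f"nodes not in network: {sorted(missing)[:5]}")
        und = und.subgraph(node_set)
    degrees = np.array([d for _, d in und.degree()], dtype=float)
    total = degrees.sum()
    if total == 0:
        raise ValueError("induced subgraph has no edges; structure entropy undefined")
    ii = degrees[degrees > 0] / total
    return float(-(ii * np.log(ii)).sum())


def method_entropy(
    partition: ModulePartition, net: nx.Graph, aggregation: str = "union"
) -> float:
    """One entropy scalar for a detector's module set.

    ``union`` (default) scores the induced subgraph on the union of all
    module members; ``mean`` averages per-module entropies.
    """
    if not partition.modules:
        raise ValueError(f"{partition.method}: no modules to score")
    per_module = [structure_entropy(net, set(mod)) for mod in partition.modules]
    partition.per_module_entropy = per_module
    if aggregation == "union":
        e = structure_entropy(net, partition.node_union())
    elif aggregation == "mean":
        e = float(np.mean(per_module))
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}; use 'union' or 'mean'")
    partition.method_entropy = e
    return e


def select_method_by_entropy(
    partitions: list[ModulePartition],
    net: nx.Graph | None = None,
    aggregation: str = "union",
) -> ModulePartition:
    """Minimum-entropy arbitration between detectors.

    Entropies are computed on demand when ``net`` is given.  Ties fall back
    to the fixed preference order mcode > mcl > connected_components.
    """
    scored = []
    for p in partitions:
        if p.method_entropy is None:
            if net is None or not p.modules:
                continue
            method_entropy(p, net, aggregation=aggregation)
        scored.append(p)
    if not scored:
        raise ValueError("no partition with a defined method entropy")
    pref = {m: i for i, m in enumerate(METHOD_PREFERENCE)}
    return min(scored, key=lambda p: (p.method_entropy, pref.get(p.method, len(pref))))
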