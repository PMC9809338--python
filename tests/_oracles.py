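"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive (exhaustive enumeration, direct
formulas) and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx


def brute_force_max_matching(edges: list[tuple[str, str]]) -> int:
    """Maximum matching cardinality of the bipartite split, by recursion
    over the edge list (each node used at most once per side)."""

    def rec(i: int, used_out: frozenset, used_in: frozenset) -> int:
        if i == len(edges):
            return 0
        best = rec(i + 1, used_out, used_in)
        u, v = edges[i]
        if u not in used_out and v not in used_in:
            best = max(best, 1 + rec(i + 1, used_out | {u}, used_in | {v}))
        return best

    return rec(0, frozenset(), frozenset())


def naive_mcc(und: nx.Graph) -> dict[str, int]:
    """MCC by scanning every node subset for maximal cliques."""
    nodes = sorted(und.nodes)
    scores = {v: 0 for v in nodes}
    for r in range(2, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if not all(und.has_edge(a, b) for a, b in itertools.combinations(sub, 2)):
                continue
            # maximal iff no outside node adjacent to all of sub
            sset = set(sub)
            if any(
                sset <= set(und.neighbors(w)) for w in nodes if w not in sset
            ):
                continue
            for v in sub:
                scores[v] += math.factorial(r - 1)
    return scores


def enumerate_betweenness_stress(und: nx.Graph) -> tuple[dict, dict]:
    """Betweenness and stress by explicit enumeration of all shortest paths
    over ordered source-target pairs (endpoints excluded)."""
    bc = {v: 0.0 for v in und.nodes}
    stress = {v: 0 for v in und.nodes}
    for s in und.nodes:
        for t in und.nodes:
            if s == t or not nx.has_path(und, s, t):
                continue
            paths = list(nx.all_shortest_paths(und, s, t))
            for v in und.nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                stress[v] += through
                bc[v] += through / len(paths)
    return bc, stress


def entropy_from_degrees(degrees: list[int]) -> float:
    """Network structure entropy recomputed directly from a degree vector."""
    total = sum(degrees)
    e = 0.0
    for k in degrees:
        if k > 0:
            p = k / total
            e -= p * math.log(p)
    return e


def precision_recall_f(predicted: set, reference: set) -> tuple[float, float, float]:
    """Second, independent precision/recall/F implementation."""
    tp = sum(1 for g in predicted if g in reference)
    p = tp / len(predicted) if predicted else 0.0
    r = tp / len(reference)
    f = 0.0 if tp == 0 else 2.0 / (1.0 / p + 1.0 / r)
    return p, r, f


def chisq_statistic(observed) -> float:
    """Pearson chi-square from the textbook Σ(O−E)²/E formula."""
    rows = [sum(row) for row in observed]
    cols = [sum(col) for col in zip(*observed)]
    total = sum(rows)
    stat = 0.0
    for i, row in enumerate(observed):
        for j, o in enumerate(row):
            e = rows[i] * cols[j] / total
            stat += (o - e) ** 2 / e
    return stat


def components_by_union_find(nodes: list, edges: list[tuple]) -> list[set]:
    """Connected components via a plain union-find."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comps: dict = {}
    for v in nodes:
        comps.setdefault(find(v), set()).add(v)
    return list(comps.values())
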