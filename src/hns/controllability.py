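"""Structural controllability: driver nodes and control centrality.

Driver-node identification follows the structural-control recipe: split the
directed network into a bipartite graph (an out-copy and an in-copy per
gene, one bipartite edge per regulatory link), compute a maximum-cardinality
matching, and report the genes whose in-copy is left unmatched.  Injecting
independent control inputs at the driver nodes renders the network
structurally controllable; the number of drivers is max(N − |M|, 1).

Control centrality Cc(v) is the generic dimension of the subspace
controllable from a single input attached at v.  It is evaluated as the
rank, over a large prime field with independently random nonzero edge
weights, of the Krylov matrix [b, Ab, ..., A^(k)b] restricted to the set of
nodes reachable from v; the generic rank is attained with probability at
least 1 − n²/p per weight draw, and the maximum over a few draws is
reported.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "ControlProfile",
    "bipartite_split",
    "max_matching",
    "driver_nodes",
    "control_centrality",
    "compute_control_profile",
    "select_top_drivers",
]

DEFAULT_PRIME = 2_147_483_647  # 2^31 − 1 (Mersenne)
DEFAULT_TRIALS = 3

_OUT, _IN = 0, 1  # bipartite side tags


@dataclass
class ControlProfile:
    """Driver-node set, the maximum matching behind it, and Cc scores."""

    matching: set[tuple[str, str]]
    driver_nodes: list[str]  # sorted
    n_drivers: int
    control_centrality: dict[str, int] = field(default_factory=dict)


def bipartite_split(net: nx.DiGraph) -> nx.Graph:
    """Bipartite representation: (0, u) out-copies vs (1, v) in-copies.

    One bipartite edge ((0, u), (1, v)) per directed edge u→v, so the
    bipartite edge count always equals the directed edge count.
    """
    bip = nx.Graph()
    for n in sorted(net.nodes):
        bip.add_node((_OUT, n), bipartite=0)
        bip.add_node((_IN, n), bipartite=1)
    for u, v in net.edges():
        bip.add_edge((_OUT, u), (_IN, v))
    return bip


def max_matching(net: nx.DiGraph) -> set[tuple[str, str]]:
    """Maximum-cardinality matching of the bipartite split, as directed edges.

    The matching is canonicalized: in-copies are claimed by augmenting paths
    in *descending* lexicographic order, so that when several maximum
    matchings exist the set of unmatched in-copies (the driver set) is the
    lexicographically smallest possible.  Matching cardinality itself is
    unique.
    """
    # adjacency: in-copy v -> sorted out-copy neighbours u (u -> v edges)
    preds: dict[str, list[str]] = {v: sorted(net.predecessors(v)) for v in net.nodes}
    match_of_out: dict[str, str] = {}  # out-copy u -> in-copy v
    match_of_in: dict[str, str] = {}

    def try_augment(v: str, visited: set[str]) -> bool:
        for u in preds[v]:
            if u in visited:
                continue
            visited.add(u)
            if u not in match_of_out or try_augment(match_of_out[u], visited):
                match_of_out[u] = v
                match_of_in[v] = u
                return True
        return False

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, net.number_of_nodes() + 1000))
    try:
        for v in sorted(net.nodes, reverse=True):
            try_augment(v, set())
    finally:
        sys.setrecursionlimit(old_limit)
    return {(u, v) for u, v in match_of_out.items()}


def driver_nodes(net: nx.DiGraph) -> ControlProfile:
    """Driver genes: nodes unmatched as regulatory targets.

    Every in-degree-0 gene is necessarily a driver.  A perfectly matched
    network still needs one input; by convention the lexicographically
    smallest gene is then reported as the single driver.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    matching = max_matching(net)
    matched_in = {v for _, v in matching}
    drivers = sorted(set(net.nodes) - matched_in)
    n_drivers = max(net.number_of_nodes() - len(matching), 1)
    if not drivers:  # perfect matching
        drivers = [min(net.nodes)]
    return ControlProfile(matching=matching, driver_nodes=drivers, n_drivers=n_drivers)


def _reachable(net: nx.DiGraph, v: str) -> list[str]:
    return sorted(nx.descendants(net, v) | {v})


def control_centrality(
    net: nx.DiGraph,
    v: str,
    trials: int = DEFAULT_TRIALS,
    prime: int = DEFAULT_PRIME,
    seed: int | np.random.Generator | None = None,
) -> int:
    """Generic dimension of the subspace controllable from a single input at v.

    Random nonzero integer edge weights are drawn modulo ``prime`` for the
    subgraph reachable from v, and the rank of the Krylov sequence
    b, Ab, A²b, ... (b the indicator of v, A the weighted adjacency with
    A[target, source] ≠ 0 per edge) is computed over the prime field.  The
    sequence is truncated as soon as a vector falls in the span of its
    predecessors.  The maximum rank over ``trials`` independent draws is
    returned; 1 ≤ Cc(v) ≤ |reachable set of v|.
    """
    if v not in net:
        raise ValueError(f"node {v!r} not in network")
    n = net.number_of_nodes()
    if prime < n * n:
        raise ValueError(
            f"prime {prime} < n^2 = {n * n}: failure probability of the "
            "randomized rank would be too high"
        )
    if trials < 1:
        raise ValueError("trials must be >= 1")
    nodes = _reachable(net, v)
    r = len(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    # edge u -> w contributes A[w, u]; restrict to the reachable subgraph
    rows = []
    cols = []
    for u in nodes:
        for w in net.successors(u):
            if w in idx:
                rows.append(idx[w])
                cols.append(idx[u])
    rows_a = np.asarray(rows, dtype=np.int64)
    cols_a = np.asarray(cols, dtype=np.int64)
    if rows_a.size == 0:
        return 1  # only b itself spans the controllable subspace

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best = 0
    for _ in range(trials):
        weights = rng.integers(1, prime, size=rows_a.size, dtype=np.int64)
        rank = _krylov_rank(rows_a, cols_a, weights, r, idx[v], prime)
        best = max(best, rank)
        if best == r:
            break
    return best


def _krylov_rank(
    rows: np.ndarray,
    cols: np.ndarray,
    weights: np.ndarray,
    r: int,
    b_index: int,
    prime: int,
) -> int:
    """Rank over GF(prime) of the Krylov matrix, with early termination.

    Maintains a reduced row-echelon basis; each candidate vector is reduced
    against it, and the iteration stops at the first dependent vector
    (Krylov spans are nested, so all later vectors are dependent too).
    Products of two residues fit in int64 (prime < 2^31.5); per-row sums in
    the matrix-vector product are reduced mod prime before accumulation.
    """
    basis: list[np.ndarray] = []
    pivots: list[int] = []
    x = np.zeros(r, dtype=np.int64)
    x[b_index] = 1
    for _ in range(r):
        y = x.copy()
        for row, piv in zip(basis, pivots):
            c = y[piv]
            if c:
                y = (y - c * row) % prime
        nz = np.nonzero(y)[0]
        if nz.size == 0:
            break
        piv = int(nz[0])
        inv = pow(int(y[piv]), prime - 2, prime)
        y = (y * inv) % prime
        # keep the basis fully reduced so future reductions are single-pass
        for i, row in enumerate(basis):
            c = row[piv]
            if c:
                basis[i] = (row - c * y) % prime
        basis.append(y)
        pivots.append(piv)
        if len(basis) == r:
            break
        # next Krylov vector: x <- A x (true sequence, not the reduced one)
        prod = (weights * x[cols]) % prime
        nxt = np.zeros(r, dtype=np.int64)
        np.add.at(nxt, rows, prod)
        x = nxt % prime
    return len(basis)


def compute_control_profile(
    net: nx.DiGraph,
    trials: int = DEFAULT_TRIALS,
    prime: int = DEFAULT_PRIME,
    seed: int | None = None,
    cc_nodes: str = "drivers",
) -> ControlProfile:
    """Drivers plus control-centrality scores for them (or for all nodes)."""
    profile = driver_nodes(net)
    targets = profile.driver_nodes if cc_nodes == "drivers" else sorted(net.nodes)
    rng = np.random.default_rng(seed)
    profile.control_centrality = {
        g: control_centrality(net, g, trials=trials, prime=prime, seed=rng)
        for g in targets
    }
    return profile


def select_top_drivers(profile: ControlProfile, k: int) -> list[str]:
    """Drivers ranked by control centrality (descending, lexicographic ties)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    missing = [g for g in profile.driver_nodes if g not in profile.control_centrality]
    if missing:
        raise ValueError(
            f"control centrality missing for {len(missing)} driver(s), e.g. {missing[0]!r}"
        )
    ranked = sorted(profile.driver_nodes, key=lambda g: (-profile.control_centrality[g], g))
    return ranked[:k]
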