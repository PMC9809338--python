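"""Performance assessment of candidate target sets.

Covers the removal experiments (single-node scans and nested incremental
removal, tracking characteristic path length L and giant-component
fraction), the F-measure against a reference target list, chi-square tests
on above-baseline degree ratios, Pearson correlations between degree and
post-removal L/GC, and the essentiality filter over a gene × cell-line
knockout score table (Chronos-like scale: 0 non-essential, −1 comparable to
the median pan-essential gene).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .graph import giant_component_fraction, path_stats

__all__ = [
    "RemovalTrace",
    "FMeasureResult",
    "ChisqResult",
    "single_node_removal_scan",
    "incremental_removal",
    "f_measure",
    "degree_ratio_chisq",
    "degree_lgc_correlation",
    "essentiality_filter",
]


@dataclass
class RemovalTrace:
    """L and giant-component trajectory along a nested removal sequence.

    ``steps`` rows: n_removed, L (NaN marks the no-paths state), gc_fraction.
    Step 0 is the intact-network baseline.
    """

    set_label: str
    steps: pd.DataFrame
    seed: int | None = None
    nested: bool = True
    removed: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class FMeasureResult:
    precision: float
    recall: float
    f: float
    n_overlap: int


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    p_value: float
    dof: int
    table: pd.DataFrame
    warnings: list[str]


def _residual_stats(
    net: nx.DiGraph, drop: set[str], compute_l: bool, denominator: int | None = None
) -> tuple[float, float]:
    """L and gc of the network minus ``drop``.

    ``denominator`` rescales the giant-component fraction to a fixed node
    count (the intact network) so that nested removal traces are monotone;
    None uses the residual network's own size.
    """
    residual = net.subgraph(set(net.nodes) - drop)
    nres = residual.number_of_nodes()
    if nres == 0:
        return (np.nan, 0.0)
    gc = giant_component_fraction(residual)
    if denominator is not None:
        gc = gc * nres / denominator
    if not compute_l:
        return (np.nan, gc)
    ps = path_stats(residual)
    return (np.nan if ps.L is None else ps.L, gc)


def single_node_removal_scan(net: nx.DiGraph, node_set: set[str]) -> pd.DataFrame:
    """Remove each node independently and record the residual L and GC.

    The network is restored between removals.  The first row (gene = NaN
    index label ``__baseline__``) is the intact network.
    """
    missing = set(node_set) - set(net.nodes)
    if missing:
        raise ValueError(f"nodes not in network: {sorted(missing)[:5]}")
    base = path_stats(net)
    rows = {"__baseline__": (np.nan if base.L is None else base.L, base.gc_fraction)}
    for g in sorted(node_set):
        rows[g] = _residual_stats(net, {g}, compute_l=True)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["L", "gc_fraction"])
    df.index.name = "gene"
    return df


def incremental_removal(
    net: nx.DiGraph,
    node_set: set[str],
    step: int = 5,
    iterations: int = 10,
    seed: int | np.random.Generator | None = None,
    set_label: str = "",
    compute_l: bool = True,
    nested: bool = True,
) -> RemovalTrace:
    """Remove randomly chosen genes from the set in growing batches.

    One random permutation of the node set is drawn; at step t the first
    ``step × t`` genes are removed (nested subsets), and the residual L and
    giant-component fraction are recorded.  The gc fraction is taken over
    the *intact* network's node count, which makes it non-increasing along
    the nested trace by construction.  If the set is smaller than
    ``step × iterations`` the trace is truncated with a warning.  With
    ``nested=False`` each step draws an independent sample of size
    ``step × t`` instead.
    """
    node_list = sorted(set(node_set) & set(net.nodes))
    if len(node_list) < len(set(node_set)):
        raise ValueError("node_set contains genes absent from the network")
    max_iter = len(node_list) // step
    if max_iter < iterations:
        warnings.warn(
            f"{set_label or 'set'}: only {len(node_list)} genes; truncating to "
            f"{max_iter} removal steps",
            stacklevel=2,
        )
        iterations = max_iter
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = list(rng.permutation(node_list))
    n_intact = net.number_of_nodes()
    base = path_stats(net)
    records = [(0, np.nan if base.L is None else base.L, base.gc_fraction)]
    removed: list[str] = []
    for t in range(1, iterations + 1):
        k = step * t
        batch = perm[:k] if nested else list(rng.choice(node_list, size=k, replace=False))
        removed = batch
        l_val, gc = _residual_stats(net, set(batch), compute_l, denominator=n_intact)
        records.append((k, l_val, gc))
    steps = pd.DataFrame(records, columns=["n_removed", "L", "gc_fraction"])
    return RemovalTrace(
        set_label=set_label,
        steps=steps,
        seed=seed if isinstance(seed, int) else None,
        nested=nested,
        removed=removed,
    )


def f_measure(predicted: set[str], reference: set[str]) -> FMeasureResult:
    """Precision, recall and F (harmonic mean) of a predicted gene set."""
    if not reference:
        raise ValueError("reference gene set is empty")
    overlap = len(set(predicted) & set(reference))
    p = overlap / len(predicted) if predicted else 0.0
    r = overlap / len(reference)
    f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return FMeasureResult(precision=p, recall=r, f=f, n_overlap=overlap)


def degree_ratio_chisq(
    sets: dict[str, set[str]],
    summary,
    degree_type: str = "in",
) -> ChisqResult:
    """Pearson chi-square on the above-baseline degree ratio across gene sets.

    Builds a (sets × 2) contingency table of counts above vs at-or-below the
    baseline degree for the requested ``degree_type`` ('in' or 'out'), using
    the flags from a :class:`~hns.graph.DegreeSummary`.  Expected cells below
    1 attach a warning to the result rather than failing.
    """
    if degree_type not in ("in", "out"):
        raise ValueError("degree_type must be 'in' or 'out'")
    if len(sets) < 2:
        raise ValueError("need at least two gene sets")
    flag_col = f"{degree_type}_above_baseline"
    counts = {}
    for label, genes in sets.items():
        if not genes:
            raise ValueError(f"gene set {label!r} is empty")
        missing = set(genes) - set(summary.table.index)
        if missing:
            raise ValueError(f"{label}: genes absent from degree summary: {sorted(missing)[:5]}")
        flags = summary.table.loc[sorted(genes), flag_col]
        counts[label] = (int(flags.sum()), int((~flags).sum()))
    table = pd.DataFrame(counts, index=["above", "at_or_below"]).T
    warns: list[str] = []
    obs = table.to_numpy(dtype=float)
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("degenerate contingency table (all-zero row or column)")
    stat, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    if (expected < 1).any():
        warns.append("expected cell count below 1; chi-square approximation is unreliable")
    return ChisqResult(statistic=float(stat), p_value=float(p), dof=int(dof),
                       table=table, warnings=warns)


def degree_lgc_correlation(scan: pd.DataFrame, summary) -> pd.DataFrame:
    """Pearson r and two-sided p between node degrees and post-removal L / GC.

    ``scan`` is the output of :func:`single_node_removal_scan`; the baseline
    row and rows whose L is undefined are dropped.  Zero-variance inputs
    yield NaN r and p (undefined-correlation marker).
    """
    nodes = scan.drop(index="__baseline__", errors="ignore").dropna(subset=["L"])
    if len(nodes) < 3:
        raise ValueError("need at least 3 removable nodes with defined L")
    merged = nodes.join(summary.table[["in_degree", "out_degree"]], how="inner")
    rows = []
    for deg_col in ("in_degree", "out_degree"):
        for out_col in ("L", "gc_fraction"):
            x = merged[deg_col].to_numpy(dtype=float)
            y = merged[out_col].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            rows.append((deg_col, out_col, r, p))
    return pd.DataFrame(rows, columns=["degree", "outcome", "r", "p"])


def essentiality_filter(
    scores: pd.DataFrame,
    query_genes: set[str] | None = None,
    aggregate: str = "median",
    threshold: float = -1.0,
) -> list[str]:
    """Genes whose aggregated knockout score across cell lines is ≤ threshold.

    ``scores`` has genes as rows, cell lines as columns.  Genes with no
    observed score are excluded with a warning.  The default (median ≤ −1)
    keeps genes at least as depleting as the median pan-essential gene.
    """
    if scores.empty:
        raise ValueError("score table is empty")
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be 'median' or 'mean'")
    sub = scores if query_genes is None else scores.loc[scores.index.isin(set(query_genes))]
    all_missing = sub.index[sub.isna().all(axis=1)]
    if len(all_missing):
        warnings.warn(
            f"{len(all_missing)} gene(s) with no scores excluded, e.g. {all_missing[0]!r}",
            stacklevel=2,
        )
        sub = sub.drop(index=all_missing)
    agg = sub.median(axis=1) if aggregate == "median" else sub.mean(axis=1)
    return sorted(agg.index[agg <= threshold])
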