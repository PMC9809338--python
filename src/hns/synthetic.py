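"""Seeded generators for every input the pipeline consumes.

The generators emulate, at desk scale, the structural regimes of a
disease regulatory network derived from tumor expression data: a directed
network with heavy-tailed out-degree and near-Poisson in-degree, a planted
dense module (the ground-truth core module), pure-source regulators
(in-degree 0, hence guaranteed driver nodes), a differential-gene list
biased to retain the planted module, a marker list enriched in the module,
and a gene × cell-line knockout score table with a planted essential subset
near −1.  Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._seeds import stage_rng
from .graph import write_edge_list

__all__ = [
    "SyntheticTruth",
    "generate_reference_network",
    "generate_deg_list",
    "generate_marker_list",
    "generate_score_table",
    "generate_all",
    "write_fixture",
]

MAX_DEGREE_RESAMPLES = 100


@dataclass
class SyntheticTruth:
    """A generated study: the network plus all planted ground truth."""

    reference_network: nx.DiGraph
    planted_module: frozenset[str]
    planted_sources: frozenset[str]
    seed: int
    deg_list: frozenset[str] | None = None
    marker_list: frozenset[str] | None = None
    essential_genes: frozenset[str] | None = None
    score_table: pd.DataFrame | None = None


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_reference_network(
    n: int = 800,
    mean_out_degree: float = 7.0,
    powerlaw_exponent: float = 2.5,
    module_size: int = 50,
    module_density: float = 0.7,
    n_sources: int = 40,
    regulator_fraction: float = 0.5,
    target_skew_exponent: float = 2.5,
    seed: int = 0,
) -> SyntheticTruth:
    """Directed network with heavy-tailed out-degree and planted structure.

    Only a ``regulator_fraction`` of genes regulate anything (real
    regulatory networks are mostly targets); regulator out-degrees follow a
    truncated Pareto tail with ``powerlaw_exponent`` so the network-wide
    mean out-degree is ``mean_out_degree``.  Each edge's target is drawn
    with probability proportional to a heavy-tailed per-gene attractiveness
    (Pareto tail ``target_skew_exponent − 1``), giving a skewed in-degree
    with many once-regulated peripheral genes — removing a hub regulator
    therefore strands its exclusive targets, the fragility the removal
    experiments probe.  The degree-sequence total is budgeted so the final
    edge count lands within 10% of n × mean_out_degree after planting
    (resampled up to 100 rounds, then an error).

    The module of ``module_size`` genes is planted on the highest
    out-degree regulators — the core disease module of a regulatory network
    sits among its master regulators, which is what makes it central — and
    wired as a random near-regular undirected graph at ``module_density``
    (member degree = round(density × (size − 1)), parity-adjusted) with
    random edge directions: a stable complex has homogeneous member
    connectivity, exactly what the minimum-entropy stability criterion
    models.  ``n_sources`` regulators outside the module have all incoming
    edges deleted and so are pure sources (guaranteed driver nodes).
    """
    if not 0 < module_size < n:
        raise ValueError("module_size must be in (0, n)")
    if mean_out_degree <= 0 or powerlaw_exponent <= 1 or target_skew_exponent <= 1:
        raise ValueError(
            "mean_out_degree must be > 0 and the power-law exponents > 1"
        )
    if not 0 < regulator_fraction <= 1:
        raise ValueError("regulator_fraction must be in (0, 1]")
    n_regulators = int(round(regulator_fraction * n))
    if n_sources + module_size > n_regulators:
        raise ValueError("n_sources + module_size must not exceed the regulator count")
    rng = stage_rng(seed, "reference_network")
    genes = _gene_names(n)

    # planted edits shift the edge count; budget the base draw so the final
    # total still lands near n·mean_out_degree
    d_mod = int(round(module_density * (module_size - 1)))
    d_mod = min(d_mod, module_size - 1)
    if d_mod * module_size % 2 == 1:
        d_mod -= 1  # a d-regular graph needs d·size even
    base_total = n * mean_out_degree - d_mod * module_size / 2 + n_sources * mean_out_degree

    alpha = powerlaw_exponent - 1.0  # Pareto tail index of the out-degree draw
    mean_reg_out = base_total / n_regulators
    xm = mean_reg_out * (alpha - 1.0) / alpha if alpha > 1 else mean_reg_out / 3.0
    for _ in range(MAX_DEGREE_RESAMPLES):
        draws = xm * (1.0 - rng.random(n_regulators)) ** (-1.0 / alpha)
        degs = np.minimum(np.floor(draws).astype(int), n - 1)
        if abs(degs.sum() - base_total) <= 0.05 * base_total:
            break
    else:
        raise RuntimeError(
            f"no feasible out-degree sequence within 5% of the budgeted total "
            f"after {MAX_DEGREE_RESAMPLES} resampling rounds"
        )

    regulator_idx = np.sort(rng.choice(n, size=n_regulators, replace=False))
    beta = target_skew_exponent - 1.0  # attractiveness tail index
    attractiveness = (1.0 - rng.random(n)) ** (-1.0 / beta)

    # module = the hub regulators (largest drawn out-degrees); its members
    # broadcast uniformly across the genome, while background regulators
    # preferentially target highly-regulated genes
    order = sorted(range(n_regulators), key=lambda pos: (-degs[pos], pos))
    module_pos = set(order[:module_size])
    module = sorted(genes[regulator_idx[pos]] for pos in module_pos)
    module_idx = {int(regulator_idx[pos]) for pos in module_pos}

    net = nx.DiGraph()
    net.add_nodes_from(genes)
    uniform = np.ones(n)
    for pos, i in enumerate(regulator_idx):
        d = int(degs[pos])
        if d == 0:
            continue
        w = (uniform if int(i) in module_idx else attractiveness).copy()
        w[i] = 0.0  # no self-loops
        w /= w.sum()
        targets = rng.choice(n, size=min(d, n - 1), replace=False, p=w)
        net.add_edges_from((genes[i], genes[j]) for j in targets)

    rest = np.array([int(regulator_idx[pos]) for pos in order[module_size:]])
    sources = sorted(genes[i] for i in rng.choice(rest, size=n_sources, replace=False))

    if d_mod > 0:
        # internal wiring is exactly the near-regular pattern: background
        # hub-hub edges inside the module are replaced, keeping member
        # connectivity homogeneous
        module_set = set(module)
        net.remove_edges_from([
            (u, v) for u, v in list(net.edges()) if u in module_set and v in module_set
        ])
        pattern = nx.random_regular_graph(d_mod, module_size, seed=int(rng.integers(2**31)))
        for a_pos, b_pos in pattern.edges():
            u, v = module[a_pos], module[b_pos]
            if rng.random() < 0.5:
                net.add_edge(u, v)
            else:
                net.add_edge(v, u)
    for s in sources:
        net.remove_edges_from([(u, s) for u in list(net.predecessors(s))])

    return SyntheticTruth(
        reference_network=net,
        planted_module=frozenset(module),
        planted_sources=frozenset(sources),
        seed=seed,
    )


def generate_deg_list(
    truth: SyntheticTruth,
    fraction: float = 0.6,
    module_bias: float = 0.95,
    seed: int | None = None,
) -> frozenset[str]:
    """Differential-gene list: each gene kept with probability ``fraction``,
    upweighted to ``module_bias`` inside the planted module."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = stage_rng(truth.seed if seed is None else seed, "deg_list")
    out = set()
    for g in sorted(truth.reference_network.nodes):
        p = module_bias if g in truth.planted_module else fraction
        if rng.random() < p:
            out.add(g)
    return frozenset(out)


def generate_marker_list(
    truth: SyntheticTruth,
    n_markers: int = 30,
    module_frac: float = 0.5,
    seed: int | None = None,
) -> frozenset[str]:
    """Reference marker/target list enriched in the planted module."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    rng = stage_rng(truth.seed if seed is None else seed, "marker_list")
    module = sorted(truth.planted_module)
    background = sorted(set(truth.reference_network.nodes) - truth.planted_module)
    n_mod = min(int(round(n_markers * module_frac)), len(module))
    picked = set(rng.choice(module, size=n_mod, replace=False)) if n_mod else set()
    n_bg = n_markers - len(picked)
    picked |= set(rng.choice(background, size=n_bg, replace=False))
    return frozenset(picked)


def generate_score_table(
    truth: SyntheticTruth,
    n_cell_lines: int = 20,
    essential_mean: float = -1.1,
    background_mean: float = 0.0,
    sd: float = 0.15,
    n_essential: int = 13,
    seed: int | None = None,
) -> tuple[pd.DataFrame, frozenset[str]]:
    """Gene × cell-line knockout scores with a planted essential subset.

    Rows are the differential genes (``truth.deg_list`` must be set); the
    essential genes are drawn from the planted module members present in the
    differential list, with Gaussian scores around ``essential_mean``;
    everything else scatters around ``background_mean``.
    """
    if truth.deg_list is None:
        raise ValueError("generate the differential-gene list first")
    if n_cell_lines < 1:
        raise ValueError("n_cell_lines must be >= 1")
    rng = stage_rng(truth.seed if seed is None else seed, "score_table")
    genes = sorted(truth.deg_list)
    pool = sorted(truth.planted_module & truth.deg_list)
    if len(pool) < n_essential:
        raise ValueError(
            f"only {len(pool)} module genes survive the differential list; "
            f"cannot plant {n_essential} essential genes"
        )
    essential = frozenset(rng.choice(pool, size=n_essential, replace=False))
    means = np.where([g in essential for g in genes], essential_mean, background_mean)
    scores = rng.normal(loc=means[:, None], scale=sd, size=(len(genes), n_cell_lines))
    table = pd.DataFrame(
        scores,
        index=pd.Index(genes, name="gene"),
        columns=[f"CL{j:03d}" for j in range(1, n_cell_lines + 1)],
    )
    return table, essential


def generate_all(seed: int = 1, **network_kwargs) -> SyntheticTruth:
    """Generate the complete study: network, gene lists and score table."""
    truth = generate_reference_network(seed=seed, **network_kwargs)
    truth.deg_list = generate_deg_list(truth)
    truth.marker_list = generate_marker_list(truth)
    truth.score_table, truth.essential_genes = generate_score_table(truth)
    return truth


def write_fixture(truth: SyntheticTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write net.tsv, degs.txt, targets.txt, chronos.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "net.tsv",
        "degs": out / "degs.txt",
        "markers": out / "targets.txt",
        "scores": out / "chronos.tsv",
        "truth": out / "truth.json",
    }
    write_edge_list(truth.reference_network, paths["network"])
    paths["degs"].write_text("".join(f"{g}\n" for g in sorted(truth.deg_list or ())))
    paths["markers"].write_text("".join(f"{g}\n" for g in sorted(truth.marker_list or ())))
    if truth.score_table is not None:
        truth.score_table.to_csv(paths["scores"], sep="\t")
    paths["truth"].write_text(
        json.dumps(
            {
                "seed": truth.seed,
                "planted_module": sorted(truth.planted_module),
                "planted_sources": sorted(truth.planted_sources),
                "essential_genes": sorted(truth.essential_genes or ()),
            },
            indent=2,
        )
    )
    return paths
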