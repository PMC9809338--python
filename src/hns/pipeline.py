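"""End-to-end orchestration of the target-set workflow.

Order of stages: induce the disease network from the differential-gene
list; identify driver nodes and their control centrality; compute the
eleven hub metrics (core nodes = top-k by MCC); detect modules by three
methods and keep the minimum-entropy one; fuse module rankings with the
rank-sum ratio to pick the core module; assemble the OHNS; and run the
evaluation battery.  Every stage writes a plain-text artifact and the run
ends with a machine-readable ``summary.json``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import centrality, controllability, evaluation, fusion, modules
from ._seeds import stage_rng
from .config import RunConfig
from .graph import degree_profile, induce_disease_network, load_edge_list, load_gene_list

__all__ = ["PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

SET_LABELS = ("CM", "CN", "DN", "OHNS", "RN")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapper

    return deco


def _derive_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow; returns the summary dict (also written to disk)."""
    if config.network is None or config.degs is None:
        raise PipelineError("stage 'load': both 'network' and 'degs' paths are required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    reference = _stage("load")(load_edge_list)(
        config.network, fmt=config.network_format,
        header=config.header, case_fold=config.case_fold,
    )
    deg_list = _stage("load")(load_gene_list)(config.degs, case_fold=config.case_fold)
    net = _stage("induce")(induce_disease_network)(reference, deg_list)
    if net.number_of_nodes() == 0:
        raise PipelineError("stage 'induce': induced disease network is empty")

    import networkx
    import numpy
    import pandas
    import scipy

    from . import __version__

    summary: dict = {
        "config": config.to_dict(),
        "versions": {
            "hns": __version__,
            "networkx": networkx.__version__,
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "scipy": scipy.__version__,
        },
        "reference_network": {
            "n_nodes": reference.number_of_nodes(),
            "n_edges": reference.number_of_edges(),
        },
        "disease_network": {
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
        },
    }

    # --- degrees -----------------------------------------------------------
    summary_deg = _stage("degrees")(degree_profile)(net)
    summary["degree_baseline"] = summary_deg.baseline

    # --- controllability ---------------------------------------------------
    profile = _stage("controllability")(controllability.compute_control_profile)(
        net,
        trials=config.cc_trials,
        prime=config.cc_prime,
        seed=_derive_seed(stage_rng(config.seed, "control_centrality")),
    )
    dn = controllability.select_top_drivers(profile, config.top_k_dn)
    summary["controllability"] = {
        "matching_size": len(profile.matching),
        "n_drivers": profile.n_drivers,
        "n_driver_genes": len(profile.driver_nodes),
        "n_dn_selected": len(dn),
    }

    # --- hub metrics -------------------------------------------------------
    table = _stage("centrality")(centrality.centrality_table)(
        net,
        epc_realizations=config.epc_realizations,
        epc_keep_prob=config.epc_keep_prob,
        clique_cap=config.clique_cap,
        seed=_derive_seed(stage_rng(config.seed, "epc")),
    )
    cn = centrality.top_k(table, "mcc", config.top_k_cn)

    # --- module detection + entropy arbitration ---------------------------
    parts = []
    for maker in (
        lambda: modules.connected_components_modules(net),
        lambda: modules.mcl_modules(
            net, inflation=config.mcl_inflation, iterations=config.mcl_iterations
        ),
        lambda: modules.mcode_modules(
            net,
            degree_cutoff=config.mcode_degree_cutoff,
            k_core=config.mcode_k_core,
            node_score_threshold=config.mcode_node_score_threshold,
        ),
    ):
        p = _stage("modules")(maker)()
        if p.modules:
            _stage("modules")(modules.method_entropy)(
                p, net, aggregation=config.entropy_aggregation
            )
            parts.append(p)
        else:
            logger.warning("module method %s found no modules; skipped", p.method)
    chosen = _stage("modules")(modules.select_method_by_entropy)(parts)
    summary["modules"] = {
        "entropy": {p.method: p.method_entropy for p in parts},
        "n_modules": {p.method: len(p.modules) for p in parts},
        "selected_method": chosen.method,
    }

    # --- MMCF fusion -> core module ---------------------------------------
    matrix = _stage("mmcf")(fusion.module_metric_matrix)(chosen, table)
    rsr = _stage("mmcf")(fusion.rank_sum_ratio)(matrix, chosen)
    cm = chosen.modules[rsr.winner]
    summary["mmcf"] = {
        "rsr": {int(i): float(v) for i, v in rsr.rsr.items()},
        "winner": rsr.winner,
        "core_module_size": len(cm),
    }

    # --- OHNS --------------------------------------------------------------
    ohns = _stage("ohns")(fusion.build_ohns)(cm, profile, k=config.ohns_top_drivers)

    rn_rng = stage_rng(config.seed, "random_nodes")
    rn_size = min(config.removal_step * config.removal_iterations, net.number_of_nodes())
    rn = sorted(rn_rng.choice(sorted(net.nodes), size=rn_size, replace=False))
    gene_sets: dict[str, set[str]] = {
        "CM": set(cm),
        "CN": set(cn),
        "DN": set(dn),
        "OHNS": set(ohns.genes),
        "RN": set(rn),
    }
    summary["set_sizes"] = {k: len(v) for k, v in gene_sets.items()}

    # --- evaluation --------------------------------------------------------
    traces = {}
    for label in SET_LABELS:
        traces[label] = _stage("evaluation")(evaluation.incremental_removal)(
            net,
            gene_sets[label],
            step=config.removal_step,
            iterations=config.removal_iterations,
            seed=_derive_seed(stage_rng(config.seed, f"removal_{label}")),
            set_label=label,
        )
    summary["removal_final"] = {
        label: {
            "n_removed": int(tr.steps["n_removed"].iloc[-1]),
            "L": None if pd.isna(tr.steps["L"].iloc[-1]) else float(tr.steps["L"].iloc[-1]),
            "gc_fraction": float(tr.steps["gc_fraction"].iloc[-1]),
        }
        for label, tr in traces.items()
    }

    scan_union = gene_sets["CM"] | gene_sets["CN"] | gene_sets["DN"]
    scan = _stage("evaluation")(evaluation.single_node_removal_scan)(net, scan_union)

    chisq = {}
    for deg_type in ("in", "out"):
        res = _stage("evaluation")(evaluation.degree_ratio_chisq)(
            {k: gene_sets[k] for k in ("CM", "CN", "DN")}, summary_deg, degree_type=deg_type
        )
        chisq[deg_type] = {
            "statistic": res.statistic,
            "p_value": res.p_value,
            "dof": res.dof,
            "warnings": res.warnings,
        }
    summary["degree_ratio_chisq"] = chisq

    corr = _stage("evaluation")(evaluation.degree_lgc_correlation)(scan, summary_deg)
    summary["degree_lgc_correlation"] = corr.to_dict(orient="records")

    if config.markers is not None:
        markers = _stage("evaluation")(load_gene_list)(config.markers, case_fold=config.case_fold)
        summary["f_measure"] = {
            label: evaluation.f_measure(gene_sets[label], markers).__dict__
            for label in ("CM", "CN", "DN", "OHNS")
        }

    if config.scores is not None:
        scores = pd.read_csv(config.scores, sep="\t", index_col=0)
        hits = _stage("evaluation")(evaluation.essentiality_filter)(
            scores,
            query_genes=scan_union | gene_sets["OHNS"],
            aggregate=config.essentiality_aggregate,
            threshold=config.essentiality_threshold,
        )
        summary["essential_hits"] = hits

    _write_artifacts(out, net, summary_deg, profile, table, parts, chosen,
                     matrix, rsr, ohns, gene_sets, traces, scan, summary)
    log_lines = [
        f"seed: {config.seed}",
        *(f"version {k}: {v}" for k, v in summary["versions"].items()),
        f"reference network: {summary['reference_network']}",
        f"disease network: {summary['disease_network']}",
        f"drivers: {summary['controllability']}",
        f"module entropies: {summary['modules']['entropy']}",
        f"selected method: {chosen.method}",
        f"set sizes: {summary['set_sizes']}",
    ]
    (out / "run.log").write_text("".join(f"{line}\n" for line in log_lines))
    return summary


def _write_artifacts(out, net, summary_deg, profile, table, parts, chosen,
                     matrix, rsr, ohns, gene_sets, traces, scan, summary) -> None:
    nodes = summary_deg.table.copy()
    nodes["is_driver"] = nodes.index.isin(profile.driver_nodes)
    nodes["control_centrality"] = [
        profile.control_centrality.get(g, "") for g in nodes.index
    ]
    nodes.to_csv(out / "nodes.tsv", sep="\t")
    table.to_csv(out / "hubs.tsv", sep="\t")
    with (out / "modules.json").open("w") as fh:
        json.dump(
            [
                {
                    "method": p.method,
                    "parameters": p.parameters,
                    "method_entropy": p.method_entropy,
                    "per_module_entropy": p.per_module_entropy,
                    "selected": p.method == chosen.method,
                    "modules": p.modules,
                }
                for p in parts
            ],
            fh,
            indent=2,
        )
    rsr_tab = matrix.copy()
    rsr_tab["rsr"] = rsr.rsr
    rsr_tab.to_csv(out / "rsr.tsv", sep="\t")
    with (out / "ohns.tsv").open("w") as fh:
        fh.write("gene\tsource\n")
        for g in ohns.genes:
            fh.write(f"{g}\t{ohns.source[g]}\n")
    with (out / "sets.json").open("w") as fh:
        json.dump({k: sorted(v) for k, v in gene_sets.items()}, fh, indent=2)
    pd.concat(
        [tr.steps.assign(set_label=label) for label, tr in traces.items()],
        ignore_index=True,
    ).to_csv(out / "traces.tsv", sep="\t", index=False)
    scan.to_csv(out / "scan.tsv", sep="\t")
    with (out / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
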