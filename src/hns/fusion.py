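"""Multi-metric module fusion (rank-sum ratio) and OHNS assembly.

Each candidate module is summarized by the mean of its member genes'
values on the eleven hub metrics; modules are ranked per metric (ascending,
so the best value takes rank m; midranks on ties) and the rank-sum ratio
RSR_j = Σ_i R_ij / (m·n) combines the eleven rankings into one score in
(0, 1].  The winning module is the core module (CM); the optimized hit
network-target set (OHNS) is its union with the top-k control-centrality
driver nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import rankdata

from .centrality import METRICS
from .controllability import ControlProfile, select_top_drivers
from .modules import ModulePartition

__all__ = ["RsrResult", "OhnsResult", "module_metric_matrix", "rank_sum_ratio", "build_ohns"]


@dataclass
class RsrResult:
    ranks: pd.DataFrame  # midranks, rows = modules, columns = metrics
    rsr: pd.Series  # per-module rank-sum ratio
    winner: int  # index of the winning module


@dataclass
class OhnsResult:
    genes: list[str]  # sorted
    source: dict[str, str]  # gene -> 'CM' | 'DN' | 'both'


def module_metric_matrix(
    partition: ModulePartition, table: pd.DataFrame
) -> pd.DataFrame:
    """Module × metric matrix: arithmetic mean of member-node metric values."""
    rows = []
    for i, mod in enumerate(partition.modules):
        missing = [g for g in mod if g not in table.index]
        if missing:
            raise ValueError(
                f"module {i}: gene {missing[0]!r} absent from the centrality table"
            )
        rows.append(table.loc[mod, list(METRICS)].mean(axis=0))
    return pd.DataFrame(rows, index=pd.RangeIndex(len(rows), name="module"))


def rank_sum_ratio(
    matrix: pd.DataFrame, partition: ModulePartition | None = None
) -> RsrResult:
    """Rank-sum-ratio fusion over metric columns; all metrics are
    larger-is-better (eccentricity enters upstream as 1/ecc).

    Ranks ascend with metric value (best = m) with midranks on ties, so each
    RSR lies in [1/m, 1] and a module dominating every column scores exactly
    1.  Winner ties are broken by module size (larger wins), then by the
    lexicographically smallest member gene; member info comes from
    ``partition`` when provided.
    """
    m = len(matrix)
    if m == 0:
        raise ValueError("no modules to rank")
    if m == 1:
        warnings.warn("single module: RSR is trivially 1", stacklevel=2)
        ranks = pd.DataFrame(1.0, index=matrix.index, columns=matrix.columns)
        return RsrResult(ranks=ranks, rsr=pd.Series([1.0], index=matrix.index), winner=0)
    ranks = matrix.apply(lambda col: rankdata(col, method="average"), axis=0)
    ranks = pd.DataFrame(ranks, index=matrix.index, columns=matrix.columns)
    rsr = ranks.sum(axis=1) / (m * matrix.shape[1])

    def tie_key(i: int):
        if partition is not None:
            mod = partition.modules[i]
            return (-rsr.loc[i], -len(mod), mod[0])
        return (-rsr.loc[i], i)

    winner = min(matrix.index, key=tie_key)
    return RsrResult(ranks=ranks, rsr=rsr, winner=int(winner))


def build_ohns(
    core_module: set[str] | list[str], profile: ControlProfile, k: int = 50
) -> OhnsResult:
    """OHNS = core-module genes ∪ top-k control-centrality driver nodes.

    Each gene keeps a provenance label: CM, DN, or both.  An empty driver
    set degrades (with a warning) to the core module alone.
    """
    cm = set(core_module)
    if not cm:
        raise ValueError("core module is empty")
    if profile.driver_nodes:
        top = set(select_top_drivers(profile, k)) if k > 0 else set()
    else:
        warnings.warn("empty driver set: OHNS falls back to the core module", stacklevel=2)
        top = set()
    genes = sorted(cm | top)
    source = {
        g: "both" if (g in cm and g in top) else ("CM" if g in cm else "DN")
        for g in genes
    }
    return OhnsResult(genes=genes, source=source)
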