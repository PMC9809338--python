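"""Run configuration: defaults, YAML loading and strict validation.

Every tunable of the pipeline lives here with its default; unknown keys and
out-of-range values are rejected with the offending key named.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "validate_config"]


@dataclass
class RunConfig:
    # input/output paths
    network: str | None = None
    degs: str | None = None
    markers: str | None = None
    scores: str | None = None
    out_dir: str = "hns_out"
    network_format: str = "tsv"
    header: bool = False
    case_fold: bool = False
    # global seed (fans out to per-stage streams)
    seed: int = 1
    # set sizes
    top_k_cn: int = 100  # core nodes: top-k by MCC
    top_k_dn: int = 201  # driver-node set: top-k by control centrality
    ohns_top_drivers: int = 50  # drivers folded into the OHNS
    # control centrality
    cc_trials: int = 3
    cc_prime: int = 2_147_483_647
    # module detection
    mcl_inflation: float = 2.0
    mcl_iterations: int = 16
    mcode_degree_cutoff: int = 2
    mcode_k_core: int = 2
    mcode_node_score_threshold: float = 0.2
    entropy_aggregation: str = "union"
    # centrality
    epc_realizations: int = 1000
    epc_keep_prob: float = 0.5
    clique_cap: int = 2_000_000
    # removal experiments
    removal_step: int = 5
    removal_iterations: int = 10
    # essentiality filter
    essentiality_aggregate: str = "median"
    essentiality_threshold: float = -1.0

    def __post_init__(self) -> None:
        _check(self)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_POSITIVE_INT = (
    "seed", "top_k_cn", "top_k_dn", "cc_trials", "cc_prime",
    "mcl_iterations", "mcode_k_core", "epc_realizations", "clique_cap",
    "removal_step", "removal_iterations",
)
_NONNEG_INT = ("ohns_top_drivers", "mcode_degree_cutoff")
_CHOICES = {
    "network_format": ("tsv", "sif"),
    "entropy_aggregation": ("union", "mean"),
    "essentiality_aggregate": ("median", "mean"),
}


def _check(cfg: RunConfig) -> None:
    for name in _POSITIVE_INT + _NONNEG_INT:
        val = getattr(cfg, name)
        if isinstance(val, bool) or not isinstance(val, int):
            raise ValueError(f"config key {name!r}: expected an integer, got {val!r}")
        low = 1 if name in _POSITIVE_INT else 0
        if val < low:
            raise ValueError(f"config key {name!r}: must be >= {low}, got {val}")
    for name, choices in _CHOICES.items():
        if getattr(cfg, name) not in choices:
            raise ValueError(
                f"config key {name!r}: must be one of {choices}, got {getattr(cfg, name)!r}"
            )
    if not cfg.mcl_inflation > 1:
        raise ValueError(f"config key 'mcl_inflation': must be > 1, got {cfg.mcl_inflation}")
    if not 0.0 <= cfg.mcode_node_score_threshold <= 1.0:
        raise ValueError("config key 'mcode_node_score_threshold': must be in [0, 1]")
    if not 0.0 <= cfg.epc_keep_prob <= 1.0:
        raise ValueError("config key 'epc_keep_prob': must be in [0, 1]")
    for name in ("header", "case_fold"):
        if not isinstance(getattr(cfg, name), bool):
            raise ValueError(f"config key {name!r}: expected a boolean")


def validate_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML/JSON config file, fill defaults, reject unknown keys.

    An empty (or absent) file yields the all-defaults configuration.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping, got {type(raw).__name__}")
        data.update(raw)
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    return RunConfig(**data)
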