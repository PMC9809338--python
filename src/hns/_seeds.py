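"""Deterministic per-stage random streams.

One global seed fans out to independent per-stage generators keyed by a
CRC32 hash of the stage name, so adding a stage never perturbs the
randomness any other stage sees.
"""

from __future__ import annotations

from zlib import crc32

import numpy as np

__all__ = ["stage_rng"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(crc32(stage.encode()),))
    )
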