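"""Named substreams of a single master seed.

Every stochastic stage of the pipeline draws from its own generator derived
from (master seed, stage name), so rerunning one stage reproduces it exactly
regardless of how many draws other stages consumed.
"""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for a named stage of a seeded run.

    The stage name is folded into the seed sequence via CRC32, so distinct
    stages get statistically independent streams while remaining fully
    deterministic under the master ``seed``.
    """
    entropy = [int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode("utf-8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy))
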