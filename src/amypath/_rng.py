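"""Named random substreams.

Every stochastic stage draws from a generator derived from the one root
seed plus a stage name, so changing the amount of randomness one stage
consumes never perturbs another stage's draws.
"""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic generator for stage ``name`` under root ``seed``."""
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
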