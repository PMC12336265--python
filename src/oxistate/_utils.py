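"""Small shared helpers: seeding and validation."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Derive a stage-specific seed (< 2**31) from one global seed.

    A stable hash of the stage name is folded into the global seed so each
    pipeline stage gets an isolated but reproducible stream.
    """
    h = zlib.crc32(stage.encode("utf8"))
    return int((int(global_seed) * 1_000_003 + h) % (2**31 - 1))


def rng_for(global_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(global_seed, stage))
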