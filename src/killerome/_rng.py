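"""Deterministic seed derivation.

One root seed drives the whole pipeline; each stochastic stage draws from a
child generator keyed by a stable stage name (CRC32 of the name mixed into a
SeedSequence), so stages are independent and reruns are bit-identical on any
platform.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(root_seed: int, stage: str) -> np.random.SeedSequence:
    """SeedSequence for ``stage`` derived from ``root_seed``."""
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.SeedSequence(entropy=int(root_seed), spawn_key=(key,))


def child_rng(root_seed: int, stage: str) -> np.random.Generator:
    """A Generator seeded deterministically from (root_seed, stage name)."""
    return np.random.default_rng(child_seed(root_seed, stage))
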