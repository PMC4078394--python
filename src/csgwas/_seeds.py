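"""Deterministic seed-substream derivation.

Every stochastic operation in the package takes an explicit integer seed.
Replicates and sub-operations derive independent substreams from
``(seed, key...)`` via :class:`numpy.random.SeedSequence` spawn keys, so a
single root seed reproduces an entire experiment bit-for-bit while replicate
streams stay statistically independent.
"""

from __future__ import annotations

import numpy as np

__all__ = ["seed_sequence", "substream"]


def seed_sequence(seed: int, *key: int) -> np.random.SeedSequence:
    """SeedSequence for root ``seed`` and an optional hierarchical key."""
    return np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key))


def substream(seed: int, *key: int) -> np.random.Generator:
    """Generator on the substream identified by ``(seed, *key)``."""
    return np.random.default_rng(seed_sequence(seed, *key))
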