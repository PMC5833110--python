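"""Seeded random generators with per-purpose stream separation.

Different pipeline stages (data simulation, CV fold assignment, bootstrap
resampling, optimiser restarts) frequently receive the same user-facing
seed.  Giving each stage a generator derived from (seed, stage label) via a
SeedSequence spawn key keeps the streams statistically independent; reusing
one integer for two stages would otherwise make their uniform draws
identical, silently coupling e.g. simulated ages with resampling decisions.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derived_rng(seed: int, label: str) -> np.random.Generator:
    """A Generator seeded by ``seed`` on an independent stream per label."""
    key = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "little")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                               spawn_key=(key,)))


__all__ = ["derived_rng"]
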