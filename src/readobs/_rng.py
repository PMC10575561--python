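"""Deterministic, order-independent seed derivation.

Per-token observer runs (and per-participant simulations) each get their own
generator derived from a master seed and a stable string key, so outputs do
not depend on iteration order and are reproducible across processes.
"""

from __future__ import annotations

import hashlib

import numpy as np


def stable_seed(master_seed: int, *parts) -> np.random.SeedSequence:
    key = "|".join(str(p) for p in parts).encode("utf-8")
    digest = hashlib.blake2b(key, digest_size=8).digest()
    return np.random.SeedSequence([int(master_seed), int.from_bytes(digest, "little")])


def derived_rng(master_seed: int, *parts) -> np.random.Generator:
    return np.random.default_rng(stable_seed(master_seed, *parts))
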