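"""Deterministic child-seed derivation.

One master seed drives an experiment; every stage (graph construction,
kingdom split, abundance sampling, read simulation per trial, ...) derives
its own independent stream from the master seed plus a stable key path.
String keys are hashed with CRC32 so the scheme is reproducible across
processes and platforms.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    return int(key)


def child_seed(master_seed: int, *keys: int | str) -> np.random.SeedSequence:
    """Derive a SeedSequence for the stage identified by ``keys``."""
    entropy = [int(master_seed)] + [_key_to_int(k) for k in keys]
    return np.random.SeedSequence(entropy)


def child_rng(master_seed: int, *keys: int | str) -> np.random.Generator:
    """Generator seeded by :func:`child_seed` on the same key path."""
    return np.random.default_rng(child_seed(master_seed, *keys))
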