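"""Deterministic RNG stream derivation.

One user-facing seed per run; every table/variable gets its own child stream so
that adding one draw site never perturbs the others.
"""
from __future__ import annotations

import zlib

import numpy as np


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Return a Generator for the named child stream of ``seed``.

    The stream name is hashed with CRC-32, so streams are stable across runs
    and Python processes (no reliance on ``hash()`` randomisation).
    """
    tag = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def as_rng(seed_or_rng) -> np.random.Generator:
    """Accept either a seed or an existing Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
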