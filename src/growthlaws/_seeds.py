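"""Deterministic expansion of one global seed into per-operation child seeds.

Every stochastic operation takes a ``seed`` and a fixed string label; the
child stream is ``SeedSequence([seed, crc32(label)])``.  Rerunning a single
stage of a pipeline therefore reproduces exactly the stream it saw inside a
full run, without any shared mutable RNG state.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]

_MOD = 2**31


def child_seed(seed: int, label: str) -> int:
    """Derive a stable child seed (< 2**31) from a global seed and a label."""
    ss = np.random.SeedSequence([int(seed) % _MOD, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % _MOD)


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Generator seeded from :func:`child_seed` for the given label."""
    ss = np.random.SeedSequence([int(seed) % _MOD, zlib.crc32(label.encode())])
    return np.random.default_rng(ss)
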