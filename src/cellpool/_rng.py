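"""Seeded random-number substreams.

All randomness in the package flows from a single integer seed. Each stage
draws from a named substream so that adding or reordering stages never
perturbs another stage's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *tags: str) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a sequence of string tags.

    The same (seed, tags) pair always yields an identical stream; distinct
    tags yield statistically independent streams (SeedSequence spawning).
    """
    if seed < 0:
        raise ValueError("seed must be a nonnegative integer")
    entropy = [int(seed)] + [zlib.crc32(t.encode("utf-8")) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))
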