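"""Seeding policy: one root seed, independent named streams per module.

Every stochastic routine in the package takes either an explicit
``numpy.random.Generator`` or a root seed from which it derives one via
:func:`stream`.  Streams are derived by hashing the stream name into a
``SeedSequence`` spawn key, so ``stream(seed, "world")`` is independent of
``stream(seed, "drive")`` and each can be re-created in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of a root seed.

    Deterministic: the same ``(seed, name)`` pair always yields a generator
    in the same state.  Distinct names give statistically independent
    streams (SeedSequence spawn-key semantics).
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)
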