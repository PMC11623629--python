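"""Seeding helpers: one root seed, named independent substreams.

Every simulator derives its generator from the root seed plus a stable string
key, so adding a new simulator never perturbs the draws of existing ones and
identical seeds give bitwise-identical outputs.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``root_seed``.

    The substream key is a CRC32 of ``name``, which is stable across
    processes and Python hash randomization.
    """
    if root_seed is None:
        raise ValueError("root_seed must be an integer, not None")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(root_seed), spawn_key=(key,)))
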