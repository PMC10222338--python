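"""Deterministic child-seed derivation.

Every stochastic operation in the package draws its randomness from a
``numpy.random.Generator`` seeded through :func:`child_seed`, keyed on a
master seed plus a tuple of purpose tags (strings or integers).  The scheme
is a splittable counter built on ``numpy.random.SeedSequence`` spawn keys, so
replicates, switches and bootstrap loops are mutually independent and fully
reproducible from the master seed alone.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def _tag_to_int(tag: object) -> int:
    if isinstance(tag, (int, np.integer)):
        if tag < 0:
            raise ValueError("seed tags must be non-negative integers or strings")
        return int(tag)
    return zlib.crc32(str(tag).encode("utf-8"))


def child_seed(master_seed: int, *tags: object) -> int:
    """Derive a deterministic child seed (< 2**31) from a master seed and tags."""
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=tuple(_tag_to_int(t) for t in tags)
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def child_rng(master_seed: int, *tags: object) -> np.random.Generator:
    """A Generator seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(master_seed, *tags))
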