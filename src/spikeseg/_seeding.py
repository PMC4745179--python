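"""Deterministic derivation of per-condition / per-trial random streams.

Every stochastic element of a simulation draws from a generator derived
from a root seed plus a tuple of string/int keys, so that (a) reruns with
one root seed are bit-reproducible and (b) different network wirings can
share identical input noise by sharing keys.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng", "child_int"]


def _hash_key(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0x7FFFFFFF
    return zlib.crc32(str(key).encode("utf-8")) & 0x7FFFFFFF


def child_seed_sequence(root: int, *keys) -> np.random.SeedSequence:
    """SeedSequence for stream (root, *keys); stable across processes."""
    return np.random.SeedSequence([int(root) & 0x7FFFFFFF] + [_hash_key(k) for k in keys])


def child_rng(root: int, *keys) -> np.random.Generator:
    return np.random.default_rng(child_seed_sequence(root, *keys))


def child_int(root: int, *keys) -> int:
    """A derived integer seed below 2**31."""
    return int(child_seed_sequence(root, *keys).generate_state(1, np.uint32)[0]) & 0x7FFFFFFF
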