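"""Named, order-independent random substreams.

A single user seed is expanded into independent generators keyed by
arbitrary hashable labels (grid-cell coordinates, scenario names, ...), so
each cell of a sweep is individually reproducible and results do not
depend on evaluation order.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "substream_seedseq"]


def _key_words(key: object) -> list[int]:
    digest = hashlib.sha256(repr(key).encode("utf-8")).digest()
    return [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]


def substream_seedseq(seed: int, *keys: object) -> np.random.SeedSequence:
    """Deterministic SeedSequence for (seed, *keys).

    Keys are hashed through SHA-256 of their ``repr``; equal keys give
    identical streams, distinct keys independent ones.
    """
    entropy = [int(seed)]
    for key in keys:
        entropy.extend(_key_words(key))
    return np.random.SeedSequence(entropy)


def substream(seed: int, *keys: object) -> np.random.Generator:
    """A PCG64 generator on the named substream of ``seed``."""
    return np.random.default_rng(substream_seedseq(seed, *keys))
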