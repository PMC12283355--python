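"""Deterministic random-number stream management.

Every stochastic component of the pipeline draws from a Generator obtained
through :func:`child_rng`, so a single top-level seed makes the entire run
bit-reproducible while keeping the per-stage streams statistically
independent.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    # stable across processes (unlike hash())
    return zlib.crc32(str(key).encode("utf-8"))


def child_rng(seed: int, *path: object) -> np.random.Generator:
    """Return a Generator for the stream identified by ``path`` under ``seed``.

    Distinct paths yield independent streams; the same ``(seed, path)`` pair
    always yields the same stream.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in path]
    return np.random.default_rng(np.random.SeedSequence(entropy))
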