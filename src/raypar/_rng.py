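"""Seed management: every source of randomness flows from one integer seed
through named substreams, so pipeline stages are individually reproducible
and order-independent."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def child_seed(seed: int, name: str) -> int:
    """Derive a deterministic 31-bit child seed for a named substream."""
    return (int(seed) ^ zlib.crc32(name.encode("utf-8"))) & 0x7FFFFFFF


def substream(seed: int, name: str) -> np.random.Generator:
    """A Generator for the substream ``name`` of the global ``seed``.

    Identical (seed, name) pairs always yield identical streams; distinct
    names yield statistically independent streams.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))]))
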