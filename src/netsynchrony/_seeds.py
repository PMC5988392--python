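"""Deterministic derivation of per-stage random streams from one master seed."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def derive_seed(master: int, *tags: str | int) -> int:
    """Map (master seed, tag path) to a stable 31-bit integer seed.

    Tags are hashed with CRC32 so the same path always yields the same
    stream, independent of Python's per-process hash randomization.
    """
    acc = int(master) & 0x7FFFFFFF
    for tag in tags:
        data = str(tag).encode("utf-8")
        acc = (acc * 1_000_003 + zlib.crc32(data)) & 0x7FFFFFFF
    return acc


def derive_rng(master: int, *tags: str | int) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *tags))
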