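"""Seed bookkeeping: one global seed expands into named sub-streams."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["subseed", "sub_rng"]


def subseed(seed: int, *names: str | int) -> int:
    """Deterministic 31-bit sub-seed for the named stream.

    Labels are hashed with crc32 so each (seed, name path) pair maps to
    a stable integer usable as a ``random_state`` anywhere.
    """
    keys = [int(seed)]
    for name in names:
        keys.append(zlib.crc32(str(name).encode()) if isinstance(name, str) else int(name))
    ss = np.random.SeedSequence(keys)
    return int(ss.generate_state(1)[0] % (2**31))


def sub_rng(seed: int, *names: str | int) -> np.random.Generator:
    return np.random.default_rng(subseed(seed, *names))
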