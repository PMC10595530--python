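"""Shared helpers: seeded substreams and input validation."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named, reproducible RNG substream of a master seed.

    Every stochastic operation in the package consumes its own named
    substream so that changing the parameters of one stage never perturbs
    the draws of another.  The stream key is derived from a CRC32 of the
    stage name, which is stable across platforms and Python versions.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def check_unique(values, what: str) -> None:
    seen = set()
    for v in values:
        if v in seen:
            raise ValueError(f"duplicate {what}: {v!r}")
        seen.add(v)
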