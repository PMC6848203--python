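"""Seed plumbing: one global seed, stable per-module streams."""

import zlib

import numpy as np


def stream(seed: int, name: str) -> np.random.Generator:
    """Derive a named, reproducible random stream from the global seed.

    The stream is a function of ``(seed, name)`` only, so adding a new
    consumer elsewhere in the code never shifts the numbers another
    module draws.
    """
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) % 2**31, spawn_key=(key,)))
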