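"""Named seed streams.

A single run seed fans out into independent per-component generators (split,
sampler, negatives, parameter init, ...) so that changing how one component
consumes randomness never perturbs the others.  Streams are derived with
``numpy.random.SeedSequence`` keyed by the master seed plus a stable hash of
the stream name.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, *names: str) -> np.random.Generator:
    """Return a generator for the stream identified by ``names`` under ``seed``."""
    keys = [int(seed)] + [zlib.crc32(n.encode("utf8")) for n in names]
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(keys)))


def spawn_seed(seed: int, *names: str) -> int:
    """A derived integer seed (< 2**31) for APIs that take a plain seed."""
    return int(stream(seed, *names).integers(0, 2**31 - 1))
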