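"""Deterministic seed management.

One master seed per run is split into named per-purpose streams with
:class:`numpy.random.SeedSequence` so that, e.g., the trial schedule and the
simulated observer are independently reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(master_seed: int, *purpose: str | int) -> np.random.Generator:
    """Return a Generator for ``purpose`` derived from ``master_seed``.

    The purpose path (strings and integers) is hashed into spawn keys so the
    same (seed, path) pair always yields the same stream and distinct paths
    yield independent streams.
    """
    keys = [
        zlib.crc32(str(p).encode()) if isinstance(p, str) else int(p)
        for p in purpose
    ]
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=keys))
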