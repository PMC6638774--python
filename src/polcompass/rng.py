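"""Deterministic named random streams.

Every stochastic component (sun sampling, disturbance masks, terrain,
routes, ...) draws from its own stream derived from the master seed and a
stable name, so changing one component's draws never perturbs another's.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "substream_seed"]


def substream_seed(master_seed: int, name: str) -> int:
    """A 31-bit seed for the named sub-stream of ``master_seed``."""
    h = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, h])
    return int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


def stream(master_seed: int, name: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for the named sub-stream."""
    return np.random.default_rng(substream_seed(master_seed, name))
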