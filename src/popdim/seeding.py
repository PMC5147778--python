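"""Deterministic named substreams from a single master seed.

Every stochastic stage draws from a generator derived from the master seed
and a stage label, so partial pipeline reruns reproduce the same streams.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(master_seed: int, label: str) -> np.random.Generator:
    """Generator for a named stage, stable across runs and platforms."""
    tag = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([master_seed, tag]))
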