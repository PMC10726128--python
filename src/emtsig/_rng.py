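"""Named per-component RNG streams derived from one integer seed.

A single global seed fans out to independent streams keyed by a string
name, so adding a new generator to a simulation never perturbs the draws
of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the (seed, name) stream, deterministic across runs."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))
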