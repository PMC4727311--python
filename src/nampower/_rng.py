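"""Deterministic, label-addressed random number streams.

One master seed per run; each pipeline stage draws from a child generator
derived from (master seed, run index, stage label) so that adding or
reordering stages never perturbs the randomness of the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "as_rng"]


def child_rng(master_seed: int, *labels: int | str) -> np.random.Generator:
    """Return a Generator for the stream addressed by ``labels``.

    String labels are hashed with CRC-32 so the scheme is stable across
    sessions and platforms.
    """
    entropy = [int(master_seed) & 0x7FFFFFFF]
    for lab in labels:
        if isinstance(lab, str):
            entropy.append(zlib.crc32(lab.encode("utf-8")))
        else:
            entropy.append(int(lab) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def as_rng(rng: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce a seed / Generator / None into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
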