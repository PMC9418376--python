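"""Seed-derived independent random substreams.

Every simulator draws from its own named substream of a single global seed,
so generators can be called in any order (or individually) and still
reproduce byte-identical output for the same (seed, config).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return a Generator for the substream ``name``/``index`` of ``seed``.

    The stream key is derived from a CRC of the name, so adding new
    generators never perturbs existing ones.
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key, int(index)))
    return np.random.default_rng(ss)
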