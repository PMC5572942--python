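"""Deterministic per-operation random streams.

Every randomized stage derives its generator from the analysis seed plus a
stable string key (operation name, subject id, ...), so re-running any single
stage in isolation reproduces it exactly.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng"]


def derive_rng(seed: int, *keys) -> np.random.Generator:
    """Return a Generator determined by ``seed`` and the string form of ``keys``.

    The sub-stream key is a CRC32 of the joined keys, combined with the seed in
    a SeedSequence, so distinct operation names give independent streams while
    remaining reproducible across processes and platforms.
    """
    tag = "/".join(str(k) for k in keys)
    h = zlib.crc32(tag.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, h]))
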