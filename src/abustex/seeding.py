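"""Deterministic seed derivation.

A single experiment seed fans out to per-stage and per-entity sub-seeds
through a counter scheme based on :class:`numpy.random.SeedSequence`, so
each stage (cohort generation, splitting, grid search, ...) is
independently reproducible from the base seed and a stable tag.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed"]


def _tag_to_int(tag: object) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag) & 0xFFFFFFFF
    return zlib.crc32(str(tag).encode("utf-8"))


def derive_seed(seed: int, *tags: object) -> int:
    """Derive a sub-seed < 2**31 from a base seed and a stable tag path.

    The same ``(seed, *tags)`` always maps to the same sub-seed; distinct
    tag paths decorrelate through ``SeedSequence`` mixing.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_tag_to_int(t) for t in tags]
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
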