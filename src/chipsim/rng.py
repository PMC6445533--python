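"""Deterministic random-stream management.

A single root seed drives a whole simulation.  Every stage (binding,
extraction, amplification, ...) and every sample (ChIP, input) pulls its own
child generator, derived from the root seed and a stable string tag, so any
stage can be re-run in isolation and reproduces bit-identical output.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn"]


def _tag_entropy(tag: str) -> int:
    # crc32 is stable across platforms and Python versions, unlike hash()
    return zlib.crc32(tag.encode("utf-8"))


def substream(seed: int, *tags: str) -> np.random.Generator:
    """Return a Generator for ``seed`` specialised by one or more string tags.

    The same (seed, tags) pair always yields the same stream; distinct tags
    yield statistically independent streams.
    """
    entropy = [int(seed)] + [_tag_entropy(t) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def spawn(seed: int, tag: str, n: int) -> list[np.random.Generator]:
    """Return ``n`` independent generators for replicate loops."""
    return [substream(seed, tag, str(i)) for i in range(n)]
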