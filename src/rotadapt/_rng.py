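"""Seed plumbing: one root seed, named substreams per pipeline stage."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seeds"]


def _stage_key(stage: str) -> int:
    # stable across runs and platforms, unlike hash()
    return zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF


def substream(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Return an independent generator for a named stage of the pipeline.

    Every source of randomness in the package flows from a single root seed
    through these named substreams, so stages can be re-run or re-ordered
    without perturbing each other's draws.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_stage_key(stage), int(index)))
    return np.random.default_rng(ss)


def spawn_seeds(seed: int, stage: str, n: int) -> list[int]:
    """Derive ``n`` integer child seeds (< 2**31) for a named stage."""
    rng = substream(seed, stage)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
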