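"""Seed management: one master seed, named independent substreams.

Every stochastic stage (data generation, splitting, model init, dropout,
perturbation, attribution) draws from its own substream so stages can be
re-run independently without disturbing each other's randomness.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return an independent Generator for a named substream of ``master_seed``."""
    return np.random.default_rng(_seq(master_seed, name))


def substream_seed(master_seed: int, name: str) -> int:
    """A plain integer seed (< 2**31) derived from a named substream.

    For libraries that take ``random_state`` integers rather than Generators.
    """
    return int(_seq(master_seed, name).generate_state(1)[0] % (2**31))


def _seq(master_seed: int, name: str) -> np.random.SeedSequence:
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key,))
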