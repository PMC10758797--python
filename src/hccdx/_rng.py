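"""Seed fan-out: one master seed, independent named substreams.

Every stochastic component (shuffling, HHO, bag assignment, synthesis,
binarization thresholds) pulls its generator from :func:`seed_stream` so a
single master seed reproduces a full experiment while components stay
independently replayable.
"""

import hashlib

import numpy as np


def seed_stream(master_seed: int, *names: str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The substream key is a SHA-256 hash of the joined names, mixed into a
    ``SeedSequence`` together with the master seed, so distinct names give
    statistically independent streams and the mapping is stable across
    platforms and sessions.
    """
    digest = hashlib.sha256("/".join(names).encode("utf-8")).digest()
    words = [int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4)]
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *words])
    return np.random.default_rng(ss)


def child_seed(master_seed: int, *names: str) -> int:
    """A plain integer seed (< 2**31) derived from the named substream."""
    return int(seed_stream(master_seed, *names).integers(0, 2**31 - 1))
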