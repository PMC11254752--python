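"""Seeding discipline.

Every stochastic operation draws from its own named substream derived from a
single root seed, so adding one analysis scope never perturbs the draws of
another.  Substreams are built from ``numpy.random.SeedSequence`` with a
spawn key obtained by CRC-hashing the (operation, scope, ...) name tuple;
the bit generator is NumPy's default PCG64, which is reproducible across
platforms.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_words(keys: tuple) -> list[int]:
    words = []
    for k in keys:
        if isinstance(k, (int, np.integer)):
            words.append(int(k) & 0xFFFFFFFF)
        else:
            words.append(zlib.crc32(str(k).encode("utf-8")))
    return words


def substream(root_seed: int, *keys) -> np.random.Generator:
    """Return a generator for the named substream of ``root_seed``.

    Parameters
    ----------
    root_seed
        The run's single documented seed.
    *keys
        Operation / scope names (strings or small ints) identifying the
        substream, e.g. ``substream(seed, "mc_anova", cell_id)``.
    """
    seq = np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF] + _key_words(keys))
    return np.random.default_rng(seq)
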