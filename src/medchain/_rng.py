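"""Named, reproducible random substreams.

All stochastic artifacts in the package draw from a master integer seed
combined with a stable per-artifact name, so that regenerating any single
artifact is bit-identical regardless of the order in which artifacts are
produced.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by (seed, name).

    The name is hashed with CRC-32, which is stable across platforms and
    Python processes (unlike the builtin ``hash``).
    """
    entropy = [int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8"))]
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy)))
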