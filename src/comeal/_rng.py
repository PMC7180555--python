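"""Named random substreams derived from a single root seed.

Every stochastic component (world generation, splits, expert simulation,
query strategies) draws from its own substream so that changing, say, the
expert pool layout never perturbs the generated world.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Return an independent generator for ``name`` derived from ``root_seed``."""
    return np.random.default_rng(
        np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def substream_seed(root_seed: int, name: str) -> int:
    """A scalar seed (< 2**31) for libraries that take ``random_state`` ints."""
    return int(substream(root_seed, name).integers(0, 2**31 - 1))
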