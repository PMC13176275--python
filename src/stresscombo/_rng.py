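"""Named, order-independent random substreams.

Every stochastic stage derives its generator from the global seed plus a
tuple of string tags (trait name, contrast label, stage name).  Tags are
hashed with CRC-32 so that adding a trait or reordering contrasts never
perturbs the draws of the others.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *tags: str) -> np.random.Generator:
    """Return a Generator unique to (seed, tags), independent of call order."""
    entropy = (int(seed),) + tuple(zlib.crc32(str(t).encode("utf-8")) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(entropy))
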