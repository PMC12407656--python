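"""Named random substreams derived from a single master seed.

Every stochastic stage (founders, mating, meiosis, phenotypes, masking, ...)
draws from its own generator so that changing one stage's consumption pattern
does not perturb the others.
"""

from __future__ import annotations

import hashlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is a stable hash of ``name``, so the mapping is identical
    across platforms and sessions.
    """
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
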