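"""Deterministic seed substreams.

Every stochastic component draws from its own named substream derived from a
single master seed, so adding a component (or reordering calls) never perturbs
the draws of another. Substream seeds are 31-bit, derived by hashing
``"<master>:<name>"`` with SHA-256.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream_seed", "substream"]


def substream_seed(master_seed: int, name: str) -> int:
    """Return a 31-bit integer seed for the named substream."""
    digest = hashlib.sha256(f"{master_seed}:{name}".encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return a ``numpy`` Generator seeded for the named substream."""
    return np.random.default_rng(substream_seed(master_seed, name))
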