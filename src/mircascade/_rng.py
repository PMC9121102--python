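"""Deterministic random-stream derivation.

Every source of randomness in the package draws from a stream derived from a
single master seed plus a stable string label, so that each output file (and
each simulated library) is reproducible independently of evaluation order.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def child_seed(seed: int, label: str) -> int:
    """Derive a stable 31-bit child seed from a master seed and a label."""
    h = hashlib.sha256(f"{int(seed)}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def rng_for(seed: int, label: str) -> np.random.Generator:
    """A ``numpy`` generator seeded by ``child_seed(seed, label)``."""
    return np.random.default_rng(child_seed(seed, label))
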