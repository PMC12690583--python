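"""Deterministic per-stage seed derivation.

All randomness in a pipeline run flows from one global seed. Each stage
draws from a child seed derived as SHA-256(global_seed ":" stage_name),
so adding or reordering stages never perturbs the randomness of the
others.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]

_MASK = (1 << 63) - 1


def derive_seed(global_seed: int, stage: str) -> int:
    """Return a 63-bit seed unique to ``(global_seed, stage)``."""
    digest = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "little") & _MASK


def rng_for(global_seed: int, stage: str) -> np.random.Generator:
    """Generator seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(global_seed, stage))
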