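"""Deterministic seed derivation.

All randomness in the package flows from a single root seed.  Every
consumer (a simulation replicate, a table build, a mutation-placement
RNG) derives its own stream from ``(root, *keys)`` so that any part of a
study can be replayed in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    # stable across processes (no PYTHONHASHSEED dependence)
    return zlib.crc32(str(key).encode())


def derive_seed(root: int, *keys: object) -> int:
    """Derive a child seed in [1, 2^31 - 1] from a root seed and a key path.

    Distinct key paths give (with overwhelming probability) distinct,
    statistically independent child seeds; the same path always gives
    the same seed.  The result fits msprime's ``random_seed`` range.
    """
    entropy = [int(root) & 0xFFFFFFFF] + [_key_to_int(k) for k in keys]
    state = np.random.SeedSequence(entropy).generate_state(1, dtype=np.uint32)[0]
    return int(state % (2**31 - 2)) + 1


def derive_rng(root: int, *keys: object) -> np.random.Generator:
    """A numpy Generator seeded via :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(root, *keys))
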