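"""Deterministic stream splitting.

A single master seed is expanded into independent child generators keyed by
arbitrary labels (stage name, stratum, bin index, replicate index, ...), so
that results do not depend on iteration order or parallelism.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFFFFFFFFFF
    digest = hashlib.sha256(str(key).encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def child_rng(seed: int, *keys) -> np.random.Generator:
    """Return a Generator derived deterministically from ``seed`` and ``keys``."""
    entropy = [int(seed) & 0xFFFFFFFFFFFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
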