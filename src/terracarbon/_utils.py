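"""Shared helpers: RNG plumbing and file checksums."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce a seed or Generator into a Generator (no global state)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one parent seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
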