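"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np


def largest_remainder(values: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals to integers summing exactly to ``total``.

    Floors every value, then distributes the shortfall to the largest
    fractional remainders (ties broken by index, so the result is
    deterministic).
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("largest_remainder requires non-negative values")
    s = values.sum()
    if s == 0:
        if total == 0:
            return np.zeros(len(values), dtype=np.int64)
        raise ValueError("cannot apportion a positive total over all-zero values")
    scaled = values * (total / s)
    floors = np.floor(scaled).astype(np.int64)
    short = int(total - floors.sum())
    if short > 0:
        order = np.argsort(-(scaled - floors), kind="stable")
        floors[order[:short]] += 1
    return floors


def split_seed(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit stage seeds from one master seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]
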