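"""Small shared helpers (RNG handling, integer apportionment)."""
from __future__ import annotations

import numpy as np


def as_rng(seed) -> np.random.Generator:
    """Coerce ``seed`` (int, None, or Generator) into a numpy Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one integer seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def integer_apportion(total: int, weights) -> np.ndarray:
    """Split ``total`` units over categories proportional to ``weights``.

    Uses the largest-remainder method so the result is deterministic and
    sums exactly to ``total``.
    """
    w = np.asarray(weights, dtype=float)
    if total < 0:
        raise ValueError("total must be non-negative")
    if w.ndim != 1 or w.size == 0 or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative and sum to > 0")
    ideal = total * w / w.sum()
    base = np.floor(ideal).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        order = np.argsort(-(ideal - base), kind="stable")
        base[order[:short]] += 1
    return base
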