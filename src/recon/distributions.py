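"""Clone-size distributions and Hill-number diversity measures.

A repertoire (overall or sampled) is summarized by its clone-size
*spectrum*: for each clone size ``x`` (cells per clone), the number of
clones of that size.  All diversity measures used in this package are
Hill numbers

    qD = (sum_i p_i**q) ** (1 / (1 - q)),

where ``p_i`` is the frequency of clone ``i`` and the sum runs over
clones observed at size > 0.  ``q`` controls how strongly large clones
are weighted: ``q=0`` is species richness, ``q -> 1`` the exponential of
Shannon entropy, ``q=2`` the inverse Simpson index and ``q=inf`` the
inverse Berger-Parker index (reciprocal frequency of the largest clone).
"""
from __future__ import annotations

import math
from collections.abc import Iterable, Mapping

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "CloneSizeDistribution",
    "HillOrder",
    "DEFAULT_ORDERS",
    "hill_diversity",
    "hill_from_abundances",
    "diversity_profile",
    "entropy_bits_to_effective",
    "effective_to_entropy_bits",
]

#: Diversity order: any non-negative real, or ``math.inf``.
HillOrder = float

#: The four orders reported by default: richness, entropy, Simpson, Berger-Parker.
DEFAULT_ORDERS: tuple[HillOrder, ...] = (0.0, 1.0, 2.0, math.inf)

# |q - 1| below this routes to the entropy (q -> 1) closed form, which is
# the removable singularity of the general formula.
_Q1_BAND = 1e-9


class CloneSizeDistribution:
    """A clone-size spectrum: map from clone size (cells) to clone count.

    Size 0 is a legal key and represents the *missing* class -- clones
    present in the overall repertoire that contributed no cells to the
    sample.  It is excluded from all frequency-based computations.

    Counts are stored as floats because noise models may perturb them;
    sizes are non-negative integers.
    """

    __slots__ = ("_sizes", "_counts")

    def __init__(self, spectrum: Mapping[int, float]):
        items = []
        for size, count in spectrum.items():
            s = int(size)
            if s != size or s < 0:
                raise ValueError(f"clone size must be a non-negative integer, got {size!r}")
            c = float(count)
            if not np.isfinite(c) or c < 0:
                raise ValueError(f"clone count must be finite and >= 0, got {count!r}")
            if c > 0:
                items.append((s, c))
        items.sort()
        self._sizes = np.array([s for s, _ in items], dtype=np.int64)
        self._counts = np.array([c for _, c in items], dtype=float)

    # -- constructors -------------------------------------------------

    @classmethod
    def from_spectrum(cls, spectrum: Mapping[int, float]) -> "CloneSizeDistribution":
        return cls(spectrum)

    @classmethod
    def from_clone_sizes(cls, sizes: Iterable[int]) -> "CloneSizeDistribution":
        """Tally a per-clone abundance list into a spectrum."""
        arr = np.asarray(list(sizes), dtype=np.int64)
        if arr.size == 0:
            return cls({})
        if np.any(arr < 0):
            raise ValueError("clone sizes must be >= 0")
        vals, counts = np.unique(arr, return_counts=True)
        return cls(dict(zip(vals.tolist(), counts.tolist())))

    # -- accessors ----------------------------------------------------

    @property
    def sizes(self) -> np.ndarray:
        """All stored sizes (ascending), possibly including 0."""
        return self._sizes

    @property
    def counts(self) -> np.ndarray:
        return self._counts

    @property
    def observed_sizes(self) -> np.ndarray:
        """Sizes > 0 only."""
        return self._sizes[self._sizes > 0]

    @property
    def observed_counts(self) -> np.ndarray:
        return self._counts[self._sizes > 0]

    @property
    def missing(self) -> float:
        """Count stored at size 0 (the missing-clone class)."""
        idx = np.searchsorted(self._sizes, 0)
        if idx < len(self._sizes) and self._sizes[idx] == 0:
            return float(self._counts[idx])
        return 0.0

    @property
    def n_clones(self) -> float:
        """Number of clones of size > 0."""
        return float(self.observed_counts.sum())

    @property
    def total_cells(self) -> float:
        return float((self.observed_sizes * self.observed_counts).sum())

    def as_dict(self) -> dict[int, float]:
        return {int(s): float(c) for s, c in zip(self._sizes, self._counts)}

    def drop_missing(self) -> "CloneSizeDistribution":
        return CloneSizeDistribution(
            dict(zip(self.observed_sizes.tolist(), self.observed_counts.tolist()))
        )

    def split(self, threshold: float) -> tuple["CloneSizeDistribution", np.ndarray]:
        """Split into (spectrum of sizes <= threshold, per-clone array of larger sizes)."""
        small_mask = (self._sizes > 0) & (self._sizes <= threshold)
        small = CloneSizeDistribution(
            dict(zip(self._sizes[small_mask].tolist(), self._counts[small_mask].tolist()))
        )
        big_mask = self._sizes > threshold
        large = np.repeat(
            self._sizes[big_mask], np.round(self._counts[big_mask]).astype(np.int64)
        )
        return small, large

    def __eq__(self, other) -> bool:
        if not isinstance(other, CloneSizeDistribution):
            return NotImplemented
        return (
            np.array_equal(self._sizes, other._sizes)
            and np.allclose(self._counts, other._counts)
        )

    def __hash__(self):  # pragma: no cover - not meant to be hashed
        return id(self)

    def __len__(self) -> int:
        return len(self._sizes)

    def __repr__(self) -> str:
        return (
            f"CloneSizeDistribution(n_clones={self.n_clones:g}, "
            f"total_cells={self.total_cells:g}, classes={len(self._sizes)})"
        )


def hill_from_abundances(abundances, multiplicities, q: HillOrder) -> float:
    """Hill number of order ``q`` for clones given by (abundance, multiplicity) pairs.

    ``abundances`` are per-clone sizes in any common unit (cells, or mean
    sampled cells for a fitted mixture component); ``multiplicities`` how
    many clones share each abundance.  Zero-abundance entries are ignored.
    """
    if q < 0:
        raise ValueError("diversity order q must be >= 0")
    a = np.asarray(abundances, dtype=float)
    m = np.asarray(multiplicities, dtype=float)
    if a.shape != m.shape:
        raise ValueError("abundances and multiplicities must have the same shape")
    keep = (a > 0) & (m > 0)
    a, m = a[keep], m[keep]
    if a.size == 0:
        raise ValueError("no observed clones")
    total = float((a * m).sum())
    logp = np.log(a) - math.log(total)
    if q == 0:
        return float(m.sum())
    if math.isinf(q):
        return float(math.exp(-logp.max()))
    if abs(q - 1.0) < _Q1_BAND:
        # exp of Shannon entropy (natural log)
        return float(math.exp(-float((m * np.exp(logp) * logp).sum())))
    # (sum_i p_i^q)^(1/(1-q)) computed in log space for stability
    log_sum = logsumexp(q * logp, b=m)
    return float(math.exp(log_sum / (1.0 - q)))


def hill_diversity(dist: CloneSizeDistribution, q: HillOrder) -> float:
    """Effective number of clones of order ``q`` for a clone-size spectrum.

    Size-0 (missing) entries are excluded from the frequencies.
    """
    return hill_from_abundances(dist.observed_sizes, dist.observed_counts, q)


def diversity_profile(
    dist: CloneSizeDistribution, orders: Iterable[HillOrder] = DEFAULT_ORDERS
) -> dict[HillOrder, float]:
    """Hill numbers at each requested order (default 0, 1, 2, inf)."""
    return {q: hill_diversity(dist, q) for q in orders}


def entropy_bits_to_effective(bits: float) -> float:
    """Convert Shannon entropy in bits to an effective clone number (2**bits)."""
    if not np.isfinite(bits):
        raise ValueError("entropy in bits must be finite")
    return float(2.0**bits)


def effective_to_entropy_bits(effective: float) -> float:
    """Inverse of :func:`entropy_bits_to_effective`."""
    if not (effective > 0 and np.isfinite(effective)):
        raise ValueError("effective number must be positive and finite")
    return float(math.log2(effective))
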