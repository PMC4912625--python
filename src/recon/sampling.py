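"""The Poisson sampling model linking overall repertoires to samples.

Each clone of overall frequency ``f`` contributes ``Poisson(f * S)``
cells to a sample of nominal size ``S``.  This holds when the repertoire
is well mixed, is much larger than the sample, and no single clone
dominates it (clones above ~30% of all cells are better counted
directly).  The realized number of sampled cells is therefore itself
random, with mean ``S``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from ._util import as_rng, integer_apportion
from .distributions import CloneSizeDistribution

__all__ = [
    "RepertoireScale",
    "poisson_sample",
    "expected_sample_spectrum",
    "resample_from_fit",
]


@dataclass(frozen=True)
class RepertoireScale:
    """Sizes of the overall repertoire and the sample.

    N: total cells in the overall repertoire (None if unknown).
    S: cells in the sample.
    """

    N: float | None
    S: float

    def __post_init__(self):
        if self.S < 0:
            raise ValueError("sample size S must be >= 0")
        if self.N is not None and self.N < self.S:
            raise ValueError("overall repertoire N must be >= sample S")

    def coverage(self, n_overall_clones: float) -> float:
        """Cells in the sample per clone in the overall repertoire."""
        if n_overall_clones <= 0:
            raise ValueError("clone count must be positive")
        return self.S / n_overall_clones


def poisson_sample(
    parent: CloneSizeDistribution,
    sample_cells: int,
    seed=None,
    *,
    check: bool = True,
) -> CloneSizeDistribution:
    """Draw a Poisson sample of ``sample_cells`` cells from a parent spectrum.

    Returns the sample clone-size spectrum, with the clones that
    contributed zero cells recorded at size 0 (the missing class).
    """
    if sample_cells < 0:
        raise ValueError("sample_cells must be >= 0")
    if parent.n_clones <= 0:
        raise ValueError("empty parent distribution")
    rng = as_rng(seed)
    total = parent.total_cells
    if check:
        if sample_cells > 0 and total / sample_cells < 10:
            warnings.warn(
                "parent has fewer than 10x the cells of the sample; the Poisson "
                "sampling model may be inaccurate",
                stacklevel=2,
            )
        if parent.observed_sizes.max() / total > 0.30:
            warnings.warn(
                "a single clone holds >30% of the parent; consider counting it "
                "directly rather than sampling",
                stacklevel=2,
            )
    mult = np.round(parent.observed_counts).astype(np.int64)
    lam = np.repeat(parent.observed_sizes / total * sample_cells, mult)
    if lam.size == 0 or sample_cells == 0:
        return CloneSizeDistribution({0: float(mult.sum())})
    draws = rng.poisson(lam)
    spec = np.bincount(draws)
    out = {i: int(c) for i, c in enumerate(spec) if c > 0}
    return CloneSizeDistribution(out)


def expected_sample_spectrum(mixture, max_size: int) -> dict[int, float]:
    """Expected clone counts at sizes 0..max_size under a fitted Poisson mixture.

    Size ``i`` has expectation ``D_total * sum_j w_j e^{-m_j} m_j^i / i!``;
    summed over all i >= 0 this recovers ``D_total``.
    """
    mixture.validate()
    sizes = np.arange(max_size + 1)
    pmf = poisson.pmf(sizes[None, :], mixture.means[:, None])  # (k, max_size+1)
    expected = mixture.D_total * (mixture.weights[:, None] * pmf).sum(axis=0)
    return {int(i): float(e) for i, e in zip(sizes, expected)}


def resample_from_fit(fit, sample_cells: int, seed=None) -> CloneSizeDistribution:
    """Draw a synthetic sample spectrum from a fitted overall repertoire.

    A parent realization is drawn from the mixture (component clone
    counts by largest-remainder apportionment of ``D_total * w_j``) and
    Poisson-sampled; directly-counted large clones are sampled at their
    observed frequencies.  Used for predicted-versus-observed overlays,
    including the predicted missing-clone count at size 0.
    """
    if sample_cells <= 0:
        raise ValueError("sample_cells must be > 0")
    fit.validate()
    rng = as_rng(seed)
    # mixture means are per-clone Poisson means at the *fitted* sample size;
    # rescale if resampling at a different depth
    s_fit = fit.scale.S if fit.scale is not None else None
    factor = sample_cells / s_fit if s_fit else 1.0
    lams = []
    if fit.n_components and fit.D_total > 0:
        per_comp = integer_apportion(int(round(fit.D_total)), fit.weights)
        lams.append(np.repeat(fit.means * factor, per_comp))
    if len(fit.large_clone_sizes) and s_fit:
        lams.append(fit.large_clone_sizes * factor)
    elif len(fit.large_clone_sizes):
        lams.append(fit.large_clone_sizes.astype(float))
    if not lams:
        raise ValueError("fit has no clones to resample")
    lam = np.concatenate(lams)
    draws = rng.poisson(lam)
    spec = np.bincount(draws)
    out = {i: int(c) for i, c in enumerate(spec) if c > 0}
    return CloneSizeDistribution(out)
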