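"""Gold-standard synthetic repertoires, noise models and the Chao baseline.

Parent repertoires with exactly known diversity are generated from three
clone-size families commonly used to emulate real repertoires:

* ``exponential`` -- clone-size frequencies f(x) proportional to e^{-sx};
  steep (s = 0.2, dominated by small clones) to nearly flat (s = 0.02).
* ``reciprocal_exponential`` -- f(x) proportional to e^{-sx} / x, the
  stationary shape of a simple birth-death model of clone dynamics.
* ``bimodal`` -- two clone-size groups whose mean sizes differ by a
  configurable ratio (e.g. 20-30x), emulating expanded clones on a
  background of small ones.

Relative sizes are rescaled so the repertoire holds ``N`` cells (default
1e9) in exactly ``D`` clones.  Three experimental-noise modes perturb
sampled spectra: per-count noise of SD ``1.22 * sqrt(n)``, a small
baseline perturbation of every size class, and sporadic inflation of
random size classes (PCR jackpot-like).
"""
from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import as_rng, integer_apportion, spawn_seeds
from .distributions import DEFAULT_ORDERS, CloneSizeDistribution, hill_diversity
from .sampling import RepertoireScale, poisson_sample

__all__ = [
    "ParentSpec",
    "NoiseSpec",
    "make_parent",
    "apply_noise",
    "chao_estimator",
    "run_validation_sweep",
]

_FAMILIES = ("exponential", "reciprocal_exponential", "bimodal")


@dataclass(frozen=True)
class ParentSpec:
    """Specification of a synthetic parent repertoire.

    family: clone-size family (see module docstring).
    s: steepness of the exponential families.
    size_ratio: mean large/small size multiple for the bimodal family.
    D: number of clones.  N: total cells (None = leave sizes relative).
    """

    family: str
    D: int
    s: float | None = None
    size_ratio: float | None = None
    N: float | None = 1e9

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ("exponential", "reciprocal_exponential"):
            if self.s is None or self.s <= 0:
                raise ValueError("exponential families require steepness s > 0")
        if self.family == "bimodal" and (self.size_ratio is None or self.size_ratio <= 1):
            raise ValueError("bimodal family requires size_ratio > 1")
        if self.D < 1:
            raise ValueError("D must be >= 1")
        if self.N is not None and self.N < self.D:
            raise ValueError("N must be >= D (clones cannot outnumber cells)")


@dataclass(frozen=True)
class NoiseSpec:
    """Experimental-noise model applied to a sampled spectrum.

    mode: 'per_count' (count n perturbed with SD sd_scale*sqrt(n)),
    'baseline' (every size class perturbed with SD baseline_level),
    'sporadic' (each size class inflated with probability sporadic_rate),
    or 'none'.
    """

    mode: str = "none"
    sd_scale: float = 1.22
    baseline_level: float = 1.0
    sporadic_rate: float = 0.02
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("per_count", "baseline", "sporadic", "none"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if min(self.sd_scale, self.baseline_level, self.sporadic_rate) < 0:
            raise ValueError("noise parameters must be >= 0")


def _relative_sizes(spec: ParentSpec) -> tuple[np.ndarray, np.ndarray]:
    """(sizes, clone counts) before rescaling to N cells; counts sum to D."""
    if spec.family == "bimodal":
        counts = integer_apportion(spec.D, [0.5, 0.5])
        return np.array([1.0, float(spec.size_ratio)]), counts
    # truncate where cumulative clone mass reaches 1 - 1e-12
    x_max = int(np.ceil(-np.log(1e-12) / spec.s)) + 1
    x = np.arange(1, x_max + 1, dtype=float)
    logf = -spec.s * x
    if spec.family == "reciprocal_exponential":
        logf = logf - np.log(x)
    f = np.exp(logf - logf.max())
    f /= f.sum()
    counts = integer_apportion(spec.D, f)
    keep = counts > 0
    return x[keep], counts[keep]


def make_parent(spec: ParentSpec) -> CloneSizeDistribution:
    """Build a gold-standard parent spectrum with exactly ``spec.D`` clones.

    Sizes are rescaled so total cells approximate ``spec.N`` (exactly D
    clones is guaranteed; the cell total is approximate after integer
    rounding).  With ``N=None`` the relative integer sizes are returned
    unscaled.
    """
    x, counts = _relative_sizes(spec)
    if spec.N is not None:
        total_rel = float((x * counts).sum())
        scaling = spec.N / total_rel
        if scaling < 1.0 - 1e-9:
            raise ValueError(
                f"infeasible (D, N): need at least {total_rel:.0f} cells for D={spec.D}"
            )
        x = np.maximum(1, np.round(x * scaling))
    sizes = np.round(x).astype(np.int64)
    spectrum: dict[int, float] = {}
    for s_, c in zip(sizes.tolist(), counts.tolist()):
        spectrum[s_] = spectrum.get(s_, 0) + c
    return CloneSizeDistribution(spectrum)


def apply_noise(spectrum: CloneSizeDistribution, noise: NoiseSpec, seed=None) -> CloneSizeDistribution:
    """Perturb a sampled spectrum according to a noise model.

    Counts are rounded and floored at zero; the size-0 (missing) class is
    never perturbed.  Per-count noise is zero-mean, so the total clone
    count is preserved in expectation.
    """
    if noise.mode == "none":
        return spectrum
    rng = as_rng(noise.seed if seed is None else seed)
    sizes = spectrum.observed_sizes
    counts = spectrum.observed_counts.astype(float)
    if noise.mode == "per_count":
        counts = counts + rng.normal(0.0, noise.sd_scale * np.sqrt(counts))
    elif noise.mode == "baseline":
        counts = counts + rng.normal(0.0, noise.baseline_level, size=counts.shape)
    elif noise.mode == "sporadic":
        hit = rng.random(counts.shape) < noise.sporadic_rate
        counts = np.where(hit, counts * rng.uniform(2.0, 10.0, size=counts.shape), counts)
    counts = np.maximum(np.round(counts), 0.0)
    out = {int(s): float(c) for s, c in zip(sizes, counts) if c > 0}
    if spectrum.missing > 0:
        out[0] = spectrum.missing
    return CloneSizeDistribution(out)


def chao_estimator(spectrum: CloneSizeDistribution) -> float:
    """Chao1 species-richness estimate from singleton and doubleton counts.

    ``S_obs + F1^2 / (2 F2)``, or the bias-corrected
    ``S_obs + F1 (F1 - 1) / 2`` when no doubletons were observed.
    """
    if spectrum.n_clones <= 0:
        raise ValueError("empty spectrum")
    d = spectrum.as_dict()
    f1 = d.get(1, 0.0)
    f2 = d.get(2, 0.0)
    s_obs = spectrum.n_clones
    if f2 > 0:
        return float(s_obs + f1 * f1 / (2.0 * f2))
    return float(s_obs + f1 * (f1 - 1.0) / 2.0)


def run_validation_sweep(
    specs,
    coverages,
    noise: NoiseSpec = NoiseSpec("none"),
    seeds=(0,),
    config=None,
    orders=DEFAULT_ORDERS,
    progress: bool = False,
) -> pd.DataFrame:
    """Sample every parent at every coverage and reconstruct it.

    For each (parent spec, coverage, seed): builds the parent, draws a
    Poisson sample of ``coverage * D`` cells, optionally applies noise,
    runs the reconstruction and the Chao baseline, and records true
    versus estimated diversities.  Individual failures are flagged in the
    ``error`` column, never aborting the sweep.  The output feeds the
    error-profile builder.
    """
    from .core import reconstruct  # deferred: avoids import cycle

    specs = list(specs)
    rows = []
    for spec_idx, spec in enumerate(specs):
        parent = make_parent(spec)
        truth = {q: hill_diversity(parent, q) for q in orders}
        for cov_idx, cov in enumerate(coverages):
            s_cells = int(round(cov * spec.D))
            for seed in seeds:
                base = (int(seed) * 1000003 + spec_idx * 8191 + cov_idx * 131) % (2**31)
                child = spawn_seeds(base, 3)
                row = {
                    "family": spec.family,
                    "s": spec.s,
                    "size_ratio": spec.size_ratio,
                    "D": spec.D,
                    "N": spec.N,
                    "coverage": cov,
                    "sample_cells": s_cells,
                    "seed": int(seed),
                    "noise_mode": noise.mode,
                    "error": "",
                }
                for q, v in truth.items():
                    row[f"true_q{q:g}"] = v
                t0 = time.perf_counter()
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        sample = poisson_sample(parent, s_cells, seed=child[0])
                        sample = apply_noise(sample, noise, seed=child[1])
                        row["sample_q0"] = sample.n_clones
                        row["missing_true"] = sample.missing
                        row["chao_q0"] = chao_estimator(sample)
                        scale = RepertoireScale(N=spec.N, S=s_cells)
                        rep = reconstruct(
                            sample.drop_missing(), scale=scale,
                            config=config or _default_config(), seed=child[2],
                            orders=orders,
                        )
                    for q, v in rep.diversity_overall.items():
                        row[f"est_q{q:g}"] = v
                    row["missing_est"] = rep.missing
                    row["n_components"] = rep.mixture.n_components
                except Exception as exc:  # noqa: BLE001 - sweep must not abort
                    row["error"] = f"{type(exc).__name__}: {exc}"
                row["runtime_s"] = time.perf_counter() - t0
                rows.append(row)
                if progress:
                    print(f"done {row['family']} D={row['D']} cov={cov} seed={seed}")
    return pd.DataFrame(rows)


def _default_config():
    from .core import AlgoConfig

    return AlgoConfig()
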