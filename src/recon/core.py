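"""Reconstruction of the overall clone-size distribution from a sample.

The estimator models the clones observed at small sizes (<= a
large-clone threshold, default 30 cells) as a finite mixture of Poisson
contributions: a fraction ``w_j`` of overall clones each contributes a
mean of ``m_j`` cells to the sample.  Because a clone is only observed
if it contributes at least one cell, the likelihood is that of a
zero-truncated Poisson mixture; the unobserved (missing) clones are
estimated alongside the fit by a Horvitz-Thompson correction

    D_total = n_observed / (1 - P(0)),   P(0) = sum_j w_j e^{-m_j}.

Fitting alternates EM updates of (w, m) -- with the current missing
count standing in for the unobservable zero class -- with updates of the
missing count, until both are self-consistent.  Model growth (adding
mixture components) is accepted only when the corrected Akaike
information criterion improves *and* the new component's expected
contribution of observed clones exceeds sampling noise by a configurable
number of standard deviations.  Clones larger than the threshold have
negligible relative sampling error and are counted directly.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln, logsumexp

from .distributions import (
    DEFAULT_ORDERS,
    CloneSizeDistribution,
    hill_from_abundances,
)
from .sampling import RepertoireScale, resample_from_fit

__all__ = [
    "AlgoConfig",
    "ParentMixture",
    "FitReport",
    "conditional_loglik",
    "multinomial_adjustment",
    "horvitz_thompson_missing",
    "fit_fixed_k",
    "scan_fit",
    "passes_noise_threshold",
    "aicc",
    "reconstruct",
    "min_detected_clone_size",
    "upper_bound_U",
]


@dataclass(frozen=True)
class AlgoConfig:
    """Tunable parameters of the reconstruction algorithm.

    large_clone_threshold: sample size (cells) above which clones are
        counted directly instead of entering the EM fit.
    noise_sd_multiplier: how many Poisson standard deviations the
        expected observed-clone contribution of a new component must
        exceed to be accepted.
    n_scan_starts: number of deterministic EM starting points per
        component count.
    em_tolerance: relative log-likelihood change declaring convergence.
    max_em_iterations: cap on EM/self-consistency sweeps.
    max_components: cap on mixture size.
    m_floor: smallest allowed component mean (also floored at S/N when
        the overall cell count is known, so that no fitted clone is
        smaller than a single cell in the overall repertoire).
    """

    large_clone_threshold: int = 30
    noise_sd_multiplier: float = 3.0
    n_scan_starts: int = 56
    em_tolerance: float = 1e-8
    max_em_iterations: int = 500
    max_components: int = 8
    m_floor: float = 1e-4

    def __post_init__(self):
        if self.large_clone_threshold < 1:
            raise ValueError("large_clone_threshold must be >= 1")
        if self.noise_sd_multiplier < 0:
            raise ValueError("noise_sd_multiplier must be >= 0")
        if self.n_scan_starts < 1:
            raise ValueError("n_scan_starts must be >= 1")


# scanning grid bounds for component means (mean sampled cells per clone)
_SCAN_M_LO = 0.05
_SCAN_M_HI = 30.0
_SCAN_WEIGHTS = np.array([0.01, 0.03, 0.05, 0.10, 0.20, 0.30, 0.50])
_MERGE_TOL = 1e-6


@dataclass
class ParentMixture:
    """A fitted description of the overall clone-size distribution.

    weights/means: mixture components; ``w_j`` is the fraction of
        small (EM-fitted) overall clones whose mean contribution to the
        sample is ``m_j`` cells.
    D_total: estimated number of small overall clones (observed + missing).
    missing: estimated number of clones contributing zero cells.
    n_observed_small: observed clones at sizes 1..threshold.
    large_clone_sizes: per-clone observed sizes above the threshold,
        counted directly.
    """

    weights: np.ndarray
    means: np.ndarray
    D_total: float
    missing: float
    n_observed_small: float
    large_clone_sizes: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    scale: RepertoireScale | None = None
    loglik: float = math.nan
    adjusted_loglik: float = math.nan
    converged: bool = True

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.large_clone_sizes = np.asarray(self.large_clone_sizes)

    def validate(self):
        if len(self.weights) != len(self.means):
            raise ValueError("weights and means must have equal length")
        if len(self.weights):
            if abs(self.weights.sum() - 1.0) > 1e-9:
                raise ValueError("mixture weights must sum to 1")
            if np.any(self.weights <= 0) or np.any(self.means <= 0):
                raise ValueError("mixture weights and means must be > 0")
            if len(np.unique(np.round(self.means / _MERGE_TOL))) < len(self.means):
                raise ValueError("duplicate component means")
        if self.missing < -1e-9 or self.D_total + 1e-9 < self.n_observed_small:
            raise ValueError("missing-clone count must be >= 0")

    @property
    def n_components(self) -> int:
        return len(self.means)

    @property
    def p_zero(self) -> float:
        """Probability that a small clone contributes no cells to the sample."""
        if not len(self.weights):
            return 0.0
        return float((self.weights * np.exp(-self.means)).sum())

    @property
    def k_params(self) -> int:
        """Free parameters: k means + k weights - 1 normalization constraint."""
        k = self.n_components
        return max(2 * k - 1, 0)

    @property
    def n_clones_overall(self) -> float:
        """Estimated overall species richness (small + directly counted)."""
        return self.D_total + len(self.large_clone_sizes)

    @property
    def m_min(self) -> float:
        return float(self.means.min())

    @property
    def w_min(self) -> float:
        """Weight of the smallest-mean component."""
        return float(self.weights[np.argmin(self.means)])


# --------------------------------------------------------------------------
# likelihood machinery

def _log_mix_pmf(weights, means, sizes):
    """log P(size) under the (untruncated) Poisson mixture; shapes (B,k),(B,k),(L,)."""
    i = np.asarray(sizes, dtype=float)
    logpmf = (
        i[None, None, :] * np.log(means)[:, :, None]
        - means[:, :, None]
        - gammaln(i + 1)[None, None, :]
    )
    return logsumexp(logpmf + np.log(weights)[:, :, None], axis=1)  # (B, L)


def conditional_loglik(mixture: ParentMixture, observed: CloneSizeDistribution) -> float:
    """Multinomial log-likelihood of the observed spectrum conditional on detection.

    ``sum_i n_i ln[P(i) / (1 - P(0))]`` over observed sizes i >= 1.
    """
    mixture.validate()
    sizes = observed.observed_sizes
    counts = observed.observed_counts
    if sizes.size == 0:
        raise ValueError("no observed clones")
    if mixture.n_components == 0:
        raise ValueError("mixture has no components")
    p0 = mixture.p_zero
    if p0 >= 1.0 - 1e-12:
        raise ValueError("no detection probability: P(0) = 1")
    logp = _log_mix_pmf(mixture.weights[None, :], mixture.means[None, :], sizes)[0]
    if np.any(np.isneginf(logp)):
        return -math.inf
    return float((counts * (logp - math.log1p(-p0))).sum())


def multinomial_adjustment(observed: CloneSizeDistribution) -> float:
    """ln[n! / prod_i n_i!]: the number of ways to assign clones to size classes.

    Added to the spectrum likelihood when ranking scan results; it is
    constant for fixed data, so it does not alter within-data rankings,
    but makes likelihoods comparable across resampled spectra.
    """
    counts = np.round(observed.observed_counts)
    n = counts.sum()
    return float(gammaln(n + 1) - gammaln(counts + 1).sum())


def horvitz_thompson_missing(mixture: ParentMixture, n_observed_clones: float):
    """Estimate (D_total, missing) by inverse detection probability.

    ``D_total = n_observed / (1 - P(0))`` where ``P(0)`` is the mixture's
    zero-class probability.
    """
    p0 = mixture.p_zero
    if p0 >= 1.0 - 1e-12:
        raise ValueError("no detection probability: P(0) ~ 1")
    d_total = n_observed_clones / (1.0 - p0)
    return d_total, d_total - n_observed_clones


def aicc(loglik: float, k_params: int, n_obs: int) -> float:
    """Corrected Akaike information criterion.

    ``n_obs`` counts size classes including observed absences (sizes
    0..threshold, i.e. threshold+1 classes).
    """
    if n_obs <= k_params + 1:
        raise ValueError("insufficient observations for AICc")
    return -2.0 * loglik + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (n_obs - k_params - 1)


# --------------------------------------------------------------------------
# batched EM

def _fit_batch(sizes, counts, W0, M0, config: AlgoConfig, m_floor, missing_cap):
    """Fit a batch of Poisson-mixture starts to one truncated spectrum.

    sizes (L,) int >= 1; counts (L,); W0, M0 (B, k).  Each EM sweep
    treats the current missing count as the zero-class datum (closed-form
    M-step for a complete-data Poisson mixture), then refreshes the
    missing count by Horvitz-Thompson.  Returns converged (W, M, missing,
    conditional loglik, converged mask).
    """
    B, k = W0.shape
    n_obs = float(counts.sum())
    i_all = np.concatenate(([0.0], sizes.astype(float)))  # (L+1,)
    lgam = gammaln(i_all + 1.0)
    counts_b = np.broadcast_to(counts, (B, len(counts)))

    W = np.clip(W0.astype(float), 1e-12, None)
    W = W / W.sum(axis=1, keepdims=True)
    M = np.clip(M0.astype(float), m_floor, None)

    p0 = (W * np.exp(-M)).sum(axis=1)
    p0 = np.minimum(p0, 1.0 - 1e-12)
    missing = np.minimum(n_obs * p0 / (1.0 - p0), missing_cap)

    ll_prev = np.full(B, -np.inf)
    missing_prev = missing.copy()
    converged = np.zeros(B, dtype=bool)
    ll = ll_prev.copy()

    for _ in range(config.max_em_iterations):
        logpmf = (
            i_all[None, None, :] * np.log(M)[:, :, None]
            - M[:, :, None]
            - lgam[None, None, :]
        )  # (B, k, L+1)
        lj = logpmf + np.log(W)[:, :, None]
        ltot = logsumexp(lj, axis=1)  # (B, L+1)
        resp = np.exp(lj - ltot[:, None, :])  # (B, k, L+1)

        n_data = np.concatenate([missing[:, None], counts_b], axis=1)  # (B, L+1)
        Nk = np.einsum("bl,bkl->bk", n_data, resp)
        denom = np.maximum(Nk.sum(axis=1, keepdims=True), 1e-300)
        W = np.clip(Nk / denom, 1e-12, None)
        W = W / W.sum(axis=1, keepdims=True)
        M = np.einsum("bl,bkl->bk", n_data * i_all[None, :], resp) / np.maximum(Nk, 1e-300)
        M = np.clip(M, m_floor, None)

        p0 = np.minimum((W * np.exp(-M)).sum(axis=1), 1.0 - 1e-12)
        missing = np.minimum(n_obs * p0 / (1.0 - p0), missing_cap)

        # conditional log-likelihood of the observed (truncated) spectrum
        logp_obs = _log_mix_pmf(W, M, sizes)
        ll = (counts[None, :] * (logp_obs - np.log1p(-p0)[:, None])).sum(axis=1)

        dll = np.abs(ll - ll_prev) <= config.em_tolerance * (np.abs(ll) + 1.0)
        dmiss = np.abs(missing - missing_prev) <= 1e-6 * (missing + 1.0)
        converged = dll & dmiss
        if converged.all():
            break
        ll_prev = ll
        missing_prev = missing.copy()

    return W, M, missing, ll, converged


def _merge_duplicates(w, m):
    """Merge components whose means coincide (within tolerance); drop ~zero weights."""
    order = np.argsort(m)
    w, m = w[order], m[order]
    out_w, out_m = [], []
    for wj, mj in zip(w, m):
        if out_m and abs(mj - out_m[-1]) < max(_MERGE_TOL, 1e-4 * mj):
            # weighted-mean position, pooled weight
            out_m[-1] = (out_m[-1] * out_w[-1] + mj * wj) / (out_w[-1] + wj)
            out_w[-1] += wj
        else:
            out_w.append(float(wj))
            out_m.append(float(mj))
    w = np.array(out_w)
    m = np.array(out_m)
    keep = w > 1e-9
    w, m = w[keep], m[keep]
    return w / w.sum(), m


def _result_from_arrays(w, m, missing, ll, conv, observed, config, scale, adjustment):
    w, m = _merge_duplicates(np.asarray(w), np.asarray(m))
    n_obs = observed.n_clones
    mix = ParentMixture(
        weights=w,
        means=m,
        D_total=n_obs + float(missing),
        missing=float(missing),
        n_observed_small=n_obs,
        scale=scale,
        loglik=float(ll),
        adjusted_loglik=float(ll) + adjustment,
        converged=bool(conv),
    )
    return mix


def _m_floor(config: AlgoConfig, scale: RepertoireScale | None) -> float:
    floor = config.m_floor
    if scale is not None and scale.N:
        floor = max(floor, scale.S / scale.N)
    return floor


def _missing_cap(scale: RepertoireScale | None, n_obs_total: float) -> float:
    # overall clones cannot outnumber overall cells
    if scale is not None and scale.N:
        return max(scale.N - n_obs_total, 0.0)
    return 1e15


def fit_fixed_k(
    observed: CloneSizeDistribution,
    k: int,
    start: ParentMixture,
    config: AlgoConfig = AlgoConfig(),
    scale: RepertoireScale | None = None,
) -> ParentMixture:
    """EM fit with a fixed number of components from one starting mixture.

    Alternates likelihood maximization of (w, m) with Horvitz-Thompson
    updates of the missing-clone count until both are self-consistent.
    Non-convergence is flagged on the result, not raised.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if start.n_components != k:
        raise ValueError("start mixture must have k components")
    sizes = observed.observed_sizes.astype(float)
    counts = observed.observed_counts
    if sizes.size == 0:
        raise ValueError("no observed clones")
    scale = scale or start.scale
    W, M, missing, ll, conv = _fit_batch(
        sizes,
        counts,
        start.weights[None, :],
        start.means[None, :],
        config,
        _m_floor(config, scale),
        _missing_cap(scale, observed.n_clones),
    )
    adj = multinomial_adjustment(observed)
    return _result_from_arrays(
        W[0], M[0], missing[0], ll[0], conv[0], observed, config, scale, adj
    )


def _scan_starts(k: int, incumbent: ParentMixture | None, config: AlgoConfig):
    """Deterministic grid of EM starting points for k components.

    k=1: means log-spaced over [0.05, 30].  k>1: the incumbent (k-1)-
    component fit is augmented by one new component with mean from a
    log-spaced grid and weight from a fixed fraction ladder, existing
    weights rescaled.
    """
    n = config.n_scan_starts
    if k == 1:
        M = np.geomspace(_SCAN_M_LO, _SCAN_M_HI, n)[:, None]
        W = np.ones((n, 1))
        return W, M
    if incumbent is None or incumbent.n_components != k - 1:
        raise ValueError("scanning k > 1 requires a (k-1)-component incumbent")
    n_m = max(1, int(round(n / len(_SCAN_WEIGHTS))))
    new_m = np.geomspace(_SCAN_M_LO, _SCAN_M_HI, n_m)
    Ws, Ms = [], []
    for wn in _SCAN_WEIGHTS:
        for mn in new_m:
            Ws.append(np.concatenate([incumbent.weights * (1 - wn), [wn]]))
            Ms.append(np.concatenate([incumbent.means, [mn]]))
    return np.array(Ws), np.array(Ms)


def _rank_key(mix: ParentMixture):
    # higher adjusted likelihood first; ties favor fewer components, then
    # smaller total fitted sample mass
    return (
        -round(mix.adjusted_loglik / 1e-9) * 1e-9,
        mix.n_components,
        float((mix.weights * mix.means).sum()),
    )


def scan_fit(
    observed: CloneSizeDistribution,
    k: int,
    config: AlgoConfig = AlgoConfig(),
    incumbent: ParentMixture | None = None,
    scale: RepertoireScale | None = None,
) -> ParentMixture:
    """Multi-start EM: fit from a deterministic grid of starting points.

    All starts are fitted, ranked by adjusted likelihood, and one extra
    start is run from the component-wise average of the two top-ranked
    results (components matched by rank of their means).  Returns the
    best-ranked fit.
    """
    sizes = observed.observed_sizes.astype(float)
    counts = observed.observed_counts
    if sizes.size == 0:
        raise ValueError("no observed clones")
    W0, M0 = _scan_starts(k, incumbent, config)
    floor = _m_floor(config, scale)
    cap = _missing_cap(scale, observed.n_clones)
    adj = multinomial_adjustment(observed)
    W, M, missing, ll, conv = _fit_batch(sizes, counts, W0, M0, config, floor, cap)
    results = [
        _result_from_arrays(W[b], M[b], missing[b], ll[b], conv[b], observed, config, scale, adj)
        for b in range(W.shape[0])
    ]
    results.sort(key=_rank_key)
    # extra start: average of the two top-ranked results, matched by mean rank
    top = [r for r in results if np.isfinite(r.loglik)][:2]
    if len(top) == 2 and top[0].n_components == top[1].n_components == k:
        o0, o1 = np.argsort(top[0].means), np.argsort(top[1].means)
        m_avg = (top[0].means[o0] + top[1].means[o1]) / 2
        w_avg = (top[0].weights[o0] + top[1].weights[o1]) / 2
        w_avg = w_avg / w_avg.sum()
        try:
            start = ParentMixture(
                weights=w_avg, means=m_avg,
                D_total=observed.n_clones, missing=0.0,
                n_observed_small=observed.n_clones, scale=scale,
            )
            results.append(fit_fixed_k(observed, k, start, config, scale))
            results.sort(key=_rank_key)
        except ValueError:
            pass
    best = results[0]
    if not np.isfinite(best.loglik):
        raise RuntimeError(f"all {len(results)} scan starts failed for k={k}")
    return best


def passes_noise_threshold(
    candidate: ParentMixture,
    incumbent: ParentMixture,
    config: AlgoConfig = AlgoConfig(),
    observed: CloneSizeDistribution | None = None,
) -> bool:
    """Does the candidate's new component rise above sampling noise?

    The new component (the candidate component farthest, in log-mean,
    from every incumbent component) is expected to contribute

        E_new = D_total * w_new * P(X >= 2 | m_new)

    *corroborated* clones -- clones sampled at two or more cells.
    Singleton mass is excluded because it is degenerate: a component's
    weight and mean trade off freely against the missing-clone count on
    singletons alone, so singletons cannot distinguish a real component
    from sampling noise.  ``E_new`` is compared with the observed clone
    count ``B`` inside the component's own size window (roughly
    ``m_new +/- 3 sqrt(m_new)``, never below size 2):

    * detectability: ``E_new > multiplier * sqrt(max(B, 1))`` -- the
      contribution must exceed the Poisson fluctuation of the counts it
      competes with; and
    * consistency: ``E_new <= B + multiplier * sqrt(max(B, 1))`` -- it
      may not claim more corroborated clones than the window actually
      holds (which is how degenerate fits inflate the missing class).

    Without ``observed`` data the incumbent model's expected count in
    the window stands in for ``B``.
    """
    if config.noise_sd_multiplier == 0:
        return True
    if incumbent.n_components == 0:
        return True
    from scipy.stats import poisson as _pois

    dist = np.abs(
        np.log(candidate.means)[:, None] - np.log(incumbent.means)[None, :]
    ).min(axis=1)
    j = int(np.argmax(dist))
    m_new = float(candidate.means[j])
    p_multi = 1.0 - math.exp(-m_new) - m_new * math.exp(-m_new)  # P(X >= 2)
    e_new = candidate.D_total * float(candidate.weights[j]) * p_multi
    lo = max(2, int(math.floor(m_new - 3 * math.sqrt(m_new))))
    hi = max(lo, int(math.ceil(m_new + 3 * math.sqrt(m_new))))
    if observed is not None:
        sizes = observed.observed_sizes
        counts = observed.observed_counts
        b = float(counts[(sizes >= lo) & (sizes <= hi)].sum())
    else:
        in_window = _pois.cdf(hi, incumbent.means) - _pois.cdf(lo - 1, incumbent.means)
        b = incumbent.D_total * float((incumbent.weights * in_window).sum())
    noise = config.noise_sd_multiplier * math.sqrt(max(b, 1.0))
    return bool(e_new > noise and e_new <= b + noise)


# --------------------------------------------------------------------------
# top-level reconstruction

@dataclass
class FitReport:
    """Full output of a reconstruction."""

    mixture: ParentMixture
    diversity_overall: dict
    diversity_sample: dict
    missing: float
    min_detected_clone_size: float | None
    upper_bound_U: float | None
    upper_bound_U_plus_richness: float | None
    log_likelihood: float
    aicc: float
    trajectory: list
    resampled_spectrum: CloneSizeDistribution
    config: AlgoConfig
    seed: int | None
    flags: list

    @property
    def scale(self):
        return self.mixture.scale


def _overall_diversity(mix: ParentMixture, orders=DEFAULT_ORDERS) -> dict:
    """Hill numbers of the reconstructed overall repertoire.

    Small clones sit at relative abundance m_j (their mean sampled
    cells), D_total*w_j clones apiece; directly-counted large clones sit
    at their observed sizes (same scale).
    """
    abund = np.concatenate([mix.means, mix.large_clone_sizes.astype(float)])
    mult = np.concatenate(
        [mix.D_total * mix.weights, np.ones(len(mix.large_clone_sizes))]
    )
    out = {}
    for q in orders:
        if q == 0:
            out[q] = mix.n_clones_overall
        else:
            out[q] = hill_from_abundances(abund, mult, q)
    return out


def reconstruct(
    observed: CloneSizeDistribution,
    scale: RepertoireScale | None = None,
    config: AlgoConfig = AlgoConfig(),
    seed: int | None = 0,
    orders=DEFAULT_ORDERS,
) -> FitReport:
    """Reconstruct the overall clone-size distribution from a sample spectrum.

    Splits the spectrum at the large-clone threshold, grows a truncated
    Poisson mixture over the small-clone part one component at a time
    (multi-start EM at each size; growth accepted only when AICc improves
    and the added component clears the noise threshold), estimates the
    missing clones by Horvitz-Thompson, and derives overall Hill
    diversities, the minimum detected clone size and a resampled
    spectrum.
    """
    observed = observed.drop_missing()
    if observed.n_clones <= 0:
        raise ValueError("no observed clones")
    flags: list[str] = []
    small, large = observed.split(config.large_clone_threshold)
    if scale is None:
        scale = RepertoireScale(N=None, S=observed.total_cells)

    # observed absences count as observations: one class per size 0..threshold
    thr = config.large_clone_threshold
    if math.isinf(thr):
        n_classes = int(observed.observed_sizes.max()) + 1
    else:
        n_classes = int(thr) + 1

    trajectory: list[dict] = []
    if small.n_clones == 0:
        # nothing to fit: every clone is counted directly
        mix = ParentMixture(
            weights=np.array([]), means=np.array([]),
            D_total=0.0, missing=0.0, n_observed_small=0.0,
            large_clone_sizes=large, scale=scale, loglik=0.0, adjusted_loglik=0.0,
        )
        best_aicc = math.nan
        flags.append("no small clones: EM layer skipped, all clones counted directly")
    else:
        if small.total_cells < 2:
            raise ValueError(
                "too few cells in small clones to fit; analyse more cells"
            )
        if np.all(small.observed_sizes == 1):
            flags.append("all small clones are singletons: low-confidence fit")
        best = scan_fit(small, 1, config, scale=scale)
        best_aicc = aicc(best.loglik, best.k_params, n_classes)
        trajectory.append(
            {"k": 1, "loglik": best.loglik, "aicc": best_aicc, "accepted": True}
        )
        for k in range(2, config.max_components + 1):
            try:
                cand = scan_fit(small, k, config, incumbent=best, scale=scale)
            except RuntimeError:
                break
            if cand.n_components <= best.n_components:
                trajectory.append(
                    {"k": k, "loglik": cand.loglik, "aicc": math.nan,
                     "accepted": False, "reason": "components collapsed"}
                )
                break
            cand_aicc = aicc(cand.loglik, cand.k_params, n_classes)
            ok_aicc = bool(cand_aicc < best_aicc)
            ok_noise = passes_noise_threshold(cand, best, config, observed=small)
            accepted = bool(ok_aicc and ok_noise)
            trajectory.append(
                {"k": k, "loglik": cand.loglik, "aicc": cand_aicc,
                 "accepted": accepted,
                 "reason": None if accepted else
                 ("aicc" if not ok_aicc else "noise threshold")}
            )
            if not accepted:
                break
            best, best_aicc = cand, cand_aicc
        mix = replace(best, large_clone_sizes=large, scale=scale)
        if not mix.converged:
            flags.append("EM did not fully converge; result flagged")

    mix.validate()
    div_overall = _overall_diversity(mix, orders)
    div_sample = {
        q: hill_from_abundances(observed.observed_sizes, observed.observed_counts, q)
        for q in orders
    }
    mdcs = None
    if mix.n_components and scale.N:
        mdcs = min_detected_clone_size(mix, scale)
    elif mix.n_components:
        flags.append("overall cell count N unknown: minimum detected clone size omitted")
    resampled = resample_from_fit(mix, int(round(scale.S)), seed=seed)
    return FitReport(
        mixture=mix,
        diversity_overall=div_overall,
        diversity_sample=div_sample,
        missing=mix.missing,
        min_detected_clone_size=mdcs,
        upper_bound_U=None,
        upper_bound_U_plus_richness=None,
        log_likelihood=mix.loglik,
        aicc=best_aicc,
        trajectory=trajectory,
        resampled_spectrum=resampled,
        config=config,
        seed=seed,
        flags=flags,
    )


def min_detected_clone_size(mixture: ParentMixture, scale: RepertoireScale) -> float | None:
    """Smallest overall clone size the fit can resolve: ``m_min * N / S``."""
    if scale is None or not scale.N or not scale.S:
        warnings.warn("N or S unknown; minimum detected clone size omitted", stacklevel=2)
        return None
    if mixture.n_components == 0:
        raise ValueError("mixture has no fitted components")
    return mixture.m_min * scale.N / scale.S


def upper_bound_U(mixture: ParentMixture, R_max: float, scale: RepertoireScale):
    """Strict upper bound on overall species richness including hiding clones.

    ``U = R_max * w_m * m_min * N / S``: all cells that could belong to
    clones below the minimum detected size are assumed to be singlets.
    ``R_max`` is the upper error bar on the species-richness estimate.
    Also returns ``U + R_max`` (hiding clones plus detected richness),
    since the bound may or may not be read as including detected clones.
    """
    if R_max is None or not np.isfinite(R_max):
        raise ValueError("upper error bar R_max required for U")
    mdcs = min_detected_clone_size(mixture, scale)
    if mdcs is None:
        raise ValueError("scale with N and S required for U")
    u = R_max * mixture.w_min * mdcs
    return u, u + R_max
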