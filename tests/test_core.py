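"""The reconstruction core: likelihood, EM, Horvitz-Thompson, model growth."""
import math

import numpy as np
import pytest

import recon
from recon.core import (
    AlgoConfig,
    ParentMixture,
    _scan_starts,
    aicc,
    conditional_loglik,
    fit_fixed_k,
    horvitz_thompson_missing,
    min_detected_clone_size,
    passes_noise_threshold,
    scan_fit,
    upper_bound_U,
)
from recon.sampling import RepertoireScale, expected_sample_spectrum


def mk_mixture(weights, means, D=1000.0, n_obs=1000.0, scale=None, large=()):
    w = np.asarray(weights, dtype=float)
    return ParentMixture(
        weights=w / w.sum(),
        means=np.asarray(means, dtype=float),
        D_total=D,
        missing=max(D - n_obs, 0.0),
        n_observed_small=n_obs,
        large_clone_sizes=np.asarray(large, dtype=np.int64),
        scale=scale,
    )


def spectrum_from_expectation(mix, max_size=30):
    """Round the expected sample spectrum into an observed (size>=1) spectrum."""
    exp = expected_sample_spectrum(mix, max_size)
    return recon.CloneSizeDistribution(
        {i: round(v) for i, v in exp.items() if i >= 1 and round(v) > 0}
    )


class TestAicc:
    def test_formula(self):
        assert aicc(-100.0, 3, 31) == pytest.approx(200 + 6 + 24 / 27)

    def test_zero_parameters_reduces_to_deviance(self):
        assert aicc(-50.0, 0, 31) == pytest.approx(100.0)

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_correction_exceeds_plain_aic(self, k):
        assert aicc(-10.0, k, 31) > -2 * -10.0 + 2 * k

    def test_insufficient_observations(self):
        with pytest.raises(ValueError, match="insufficient"):
            aicc(-10.0, 30, 31)


class TestHorvitzThompson:
    def test_single_component_analytic(self):
        d, miss = horvitz_thompson_missing(mk_mixture([1], [1.0]), 632)
        assert d == pytest.approx(632 / (1 - math.exp(-1)), rel=1e-12)
        assert miss == pytest.approx(d - 632)

    def test_full_detection_limit(self):
        d, miss = horvitz_thompson_missing(mk_mixture([1], [50.0]), 1000)
        assert d == pytest.approx(1000, rel=1e-9)
        assert miss == pytest.approx(0, abs=1e-6)

    def test_two_component_hand_value(self):
        d, _ = horvitz_thompson_missing(mk_mixture([0.5, 0.5], [1.0, 4.0]), 807)
        p0 = 0.5 * math.exp(-1) + 0.5 * math.exp(-4)
        assert d == pytest.approx(807 / (1 - p0), rel=1e-12)
        assert d == pytest.approx(1000.1, abs=0.2)

    def test_no_detection_probability(self):
        with pytest.raises(ValueError, match="detection"):
            horvitz_thompson_missing(mk_mixture([1], [1e-14]), 10)


class TestConditionalLoglik:
    def test_component_permutation_invariance(self):
        obs = recon.CloneSizeDistribution({1: 10, 2: 5, 5: 2})
        a = conditional_loglik(mk_mixture([0.3, 0.7], [1.0, 4.0]), obs)
        b = conditional_loglik(mk_mixture([0.7, 0.3], [4.0, 1.0]), obs)
        assert a == pytest.approx(b, rel=1e-12)

    def test_single_component_grid_oracle(self):
        """The fitted mean beats every grid value of the truncated likelihood."""
        true = mk_mixture([1.0], [2.0], D=10_000, n_obs=10_000)
        obs = spectrum_from_expectation(true)
        fit = fit_fixed_k(obs, 1, mk_mixture([1.0], [1.0]), AlgoConfig())
        best_ll = conditional_loglik(fit, obs)
        for m in np.linspace(0.2, 6, 120):
            assert conditional_loglik(mk_mixture([1.0], [m]), obs) <= best_ll + 1e-6

    def test_all_singletons_favors_vanishing_mean(self):
        obs = recon.CloneSizeDistribution({1: 10})
        lls = [
            conditional_loglik(mk_mixture([1.0], [m]), obs) for m in (2.0, 1.0, 0.5, 0.1)
        ]
        assert all(a < b + 1e-12 for a, b in zip(lls, lls[1:]))


class TestFitFixedK:
    def test_recovers_single_component_mean(self):
        true = mk_mixture([1.0], [2.0], D=10_000, n_obs=10_000)
        parent = recon.CloneSizeDistribution({1: 10_000})
        obs = recon.poisson_sample(parent, 20_000, seed=11, check=False).drop_missing()
        fit = fit_fixed_k(obs, 1, mk_mixture([1.0], [obs.total_cells / obs.n_clones]),
                          AlgoConfig())
        assert fit.means[0] == pytest.approx(2.0, rel=0.02)

    def test_recovers_two_well_separated_components(self):
        parent = recon.CloneSizeDistribution({1: 5000, 8: 5000})
        obs = recon.poisson_sample(parent, 45_000, seed=5, check=False).drop_missing()
        start = mk_mixture([0.5, 0.5], [0.5, 4.0])
        fit = fit_fixed_k(obs, 2, start, AlgoConfig())
        means = np.sort(fit.means)
        assert means[0] == pytest.approx(1.0, rel=0.1)
        assert means[1] == pytest.approx(8.0, rel=0.1)

    def test_self_consistent_missing(self):
        true = mk_mixture([1.0], [1.5], D=5000, n_obs=5000)
        obs = spectrum_from_expectation(true)
        fit = fit_fixed_k(obs, 1, mk_mixture([1.0], [1.0]), AlgoConfig())
        d, miss = horvitz_thompson_missing(fit, obs.n_clones)
        assert fit.missing == pytest.approx(miss, rel=1e-4)
        assert fit.D_total == pytest.approx(d, rel=1e-4)


class TestScanFit:
    def test_best_of_explicit_starts(self):
        true = mk_mixture([0.6, 0.4], [1.0, 6.0], D=20_000, n_obs=20_000)
        obs = spectrum_from_expectation(true)
        cfg = AlgoConfig(n_scan_starts=14)
        k1 = scan_fit(obs, 1, cfg)
        W0, M0 = _scan_starts(1, None, cfg)
        for w0, m0 in zip(W0, M0):
            single = fit_fixed_k(obs, 1, mk_mixture(w0, m0), cfg)
            assert single.loglik <= k1.loglik + 1e-6

    def test_single_start_equals_fit_fixed_k(self):
        obs = recon.CloneSizeDistribution({1: 50, 2: 40, 3: 20, 4: 8})
        cfg = AlgoConfig(n_scan_starts=1)
        scan = scan_fit(obs, 1, cfg)
        W0, M0 = _scan_starts(1, None, cfg)
        direct = fit_fixed_k(obs, 1, mk_mixture(W0[0], M0[0]), cfg)
        assert scan.means[0] == pytest.approx(direct.means[0], rel=1e-9)
        assert scan.loglik == pytest.approx(direct.loglik, rel=1e-12)

    def test_escapes_local_optimum_of_mean_start(self):
        """Multi-start beats the single mean-of-observations start on bimodal data."""
        parent = recon.CloneSizeDistribution({1: 8000, 12: 2000})
        obs = recon.poisson_sample(parent, 32_000, seed=2, check=False).drop_missing()
        small, _ = obs.split(30)
        cfg = AlgoConfig()
        mean_start = mk_mixture(
            [0.5, 0.5],
            [small.total_cells / small.n_clones] * 2 + np.array([0.0, 1e-3]),
        )
        single = fit_fixed_k(small, 2, mean_start, cfg)
        k1 = scan_fit(small, 1, cfg)
        scanned = scan_fit(small, 2, cfg, incumbent=k1)
        assert scanned.loglik >= single.loglik - 1e-6


class TestNoiseThreshold:
    def test_disabled_multiplier_always_passes(self):
        cand = mk_mixture([0.5, 0.5], [0.01, 2.0])
        inc = mk_mixture([1.0], [2.0])
        assert passes_noise_threshold(cand, inc, AlgoConfig(noise_sd_multiplier=0.0))

    def test_strong_component_passes_weak_component_fails(self):
        inc = mk_mixture([1.0], [3.0], D=1000, n_obs=1000)
        # new component at mean 2 with weight 0.4: hundreds of corroborated clones
        strong = mk_mixture([0.6, 0.4], [3.0, 1.0], D=1000, n_obs=1000)
        assert passes_noise_threshold(strong, inc, AlgoConfig())
        # near-degenerate singleton component: weight 0.4 but mean 0.01
        weak = mk_mixture([0.6, 0.4], [3.0, 0.01], D=1000, n_obs=1000)
        assert not passes_noise_threshold(weak, inc, AlgoConfig())


class TestReconstruct:
    def test_noise_free_fixed_point_recovers_mixture(self):
        true = mk_mixture([1.0], [3.0], D=5000, n_obs=5000)
        obs = spectrum_from_expectation(true)
        rep = recon.reconstruct(obs, seed=0)
        assert rep.mixture.D_total == pytest.approx(5000, rel=0.01)
        assert rep.mixture.means[0] == pytest.approx(3.0, rel=0.01)

    def test_single_large_clone_counted_directly(self):
        obs = recon.CloneSizeDistribution({100_000: 1})
        rep = recon.reconstruct(obs, seed=0)
        assert rep.mixture.n_components == 0
        assert rep.diversity_overall[0.0] == 1.0
        assert rep.missing == 0.0

    def test_large_clone_shortcut_equivalence_when_no_large_clones(self):
        true = mk_mixture([0.5, 0.5], [1.0, 5.0], D=4000, n_obs=4000)
        obs = spectrum_from_expectation(true)  # all sizes <= 30 by construction
        rep30 = recon.reconstruct(obs, config=AlgoConfig(), seed=0)
        repinf = recon.reconstruct(
            obs, config=AlgoConfig(large_clone_threshold=int(obs.observed_sizes.max())),
            seed=0,
        )
        assert rep30.diversity_overall[0.0] == pytest.approx(
            repinf.diversity_overall[0.0], rel=1e-9
        )

    def test_large_clone_shortcut_close_with_large_clones_present(self):
        parent = recon.CloneSizeDistribution({1: 5000, 40: 50})
        obs = recon.poisson_sample(parent, 10_000, seed=3, check=False).drop_missing()
        rep30 = recon.reconstruct(obs, seed=0)
        rep_full = recon.reconstruct(
            obs,
            config=AlgoConfig(large_clone_threshold=int(obs.observed_sizes.max())),
            seed=0,
        )
        a, b = rep30.diversity_overall[0.0], rep_full.diversity_overall[0.0]
        assert abs(a - b) / max(a, b) < 0.005

    def test_estimate_bounded_by_overall_cells(self):
        # 1000 singletons with a tiny declared repertoire: estimate capped at N
        obs = recon.CloneSizeDistribution({1: 1000, 2: 5})
        rep = recon.reconstruct(obs, scale=RepertoireScale(N=2000, S=1010), seed=0)
        assert rep.diversity_overall[0.0] <= 2000 + 1e-6

    def test_all_singletons_flagged_low_confidence(self):
        obs = recon.CloneSizeDistribution({1: 200})
        rep = recon.reconstruct(obs, seed=0)
        assert any("singleton" in f for f in rep.flags)

    def test_no_overfitting_on_single_component_data(self):
        parent = recon.CloneSizeDistribution({1: 3000})
        obs = recon.poisson_sample(parent, 4500, seed=1, check=False).drop_missing()
        rep = recon.reconstruct(obs, seed=0)
        assert rep.mixture.n_components <= 2

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no observed clones"):
            recon.reconstruct(recon.CloneSizeDistribution({}), seed=0)

    def test_richness_identity_and_report_fields(self):
        true = mk_mixture([1.0], [2.0], D=3000, n_obs=3000)
        obs = spectrum_from_expectation(true)
        rep = recon.reconstruct(obs, scale=RepertoireScale(N=10**9, S=6000), seed=0)
        mix = rep.mixture
        assert rep.diversity_overall[0.0] == pytest.approx(
            mix.D_total + len(mix.large_clone_sizes)
        )
        assert rep.min_detected_clone_size == pytest.approx(
            mix.m_min * 10**9 / 6000
        )
        assert rep.resampled_spectrum.n_clones > 0


class TestScaleDerivedQuantities:
    def test_min_detected_clone_size_formula(self):
        mix = mk_mixture([0.4, 0.6], [1.0, 5.0])
        assert min_detected_clone_size(
            mix, RepertoireScale(N=10**9, S=10**6)
        ) == pytest.approx(1000.0)
        assert min_detected_clone_size(
            mk_mixture([0.4, 0.6], [0.5, 5.0]), RepertoireScale(N=10**9, S=10**6)
        ) == pytest.approx(500.0)

    def test_sample_equals_repertoire(self):
        mix = mk_mixture([1.0], [1.7])
        scale = RepertoireScale(N=5000, S=5000)
        assert min_detected_clone_size(mix, scale) == pytest.approx(1.7)

    def test_upper_bound_formula(self):
        mix = mk_mixture([0.4, 0.6], [0.5, 5.0])
        scale = RepertoireScale(N=10**9, S=10**6)
        u, u_plus = upper_bound_U(mix, R_max=1000.0, scale=scale)
        assert u == pytest.approx(1000 * 0.4 * 0.5 * 1000)
        assert u_plus == pytest.approx(u + 1000.0)

    def test_upper_bound_requires_error_bar(self):
        mix = mk_mixture([1.0], [1.0])
        with pytest.raises(ValueError):
            upper_bound_U(mix, R_max=math.nan, scale=RepertoireScale(N=100, S=10))
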