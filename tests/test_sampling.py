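"""The Poisson sampling model: simulation, expectations and resampling."""
import math

import numpy as np
import pytest
from scipy import stats

import recon
from recon.core import ParentMixture


def mixture(weights, means, D, scale=None):
    w = np.asarray(weights, dtype=float)
    return ParentMixture(
        weights=w / w.sum(),
        means=np.asarray(means, dtype=float),
        D_total=D,
        missing=0.0,
        n_observed_small=D,
        scale=scale,
    )


class TestPoissonSample:
    def test_zero_sample_leaves_all_clones_missing(self, uniform_parent):
        s = recon.poisson_sample(uniform_parent, 0, seed=0)
        assert s.n_clones == 0
        assert s.missing == 2000

    def test_unit_coverage_missing_fraction_near_poisson_zero_class(self, uniform_parent):
        # lambda = 1 for every clone: expect 2000 * e^-1 = 735.8 missing
        missing = [
            recon.poisson_sample(uniform_parent, 2000, seed=s).missing for s in range(8)
        ]
        expect = 2000 * math.exp(-1)
        sd = math.sqrt(2000 * math.exp(-1) * (1 - math.exp(-1)))
        assert abs(np.mean(missing) - expect) < 4 * sd / math.sqrt(8)

    def test_high_coverage_leaves_almost_nothing_missing(self):
        # D=1000 uniform clones at lambda=10: expected missing 1000*e^-10 = 0.045
        parent = recon.CloneSizeDistribution({10_000: 1000})
        missing = [recon.poisson_sample(parent, 10_000, seed=s).missing for s in range(10)]
        assert max(missing) <= 2

    def test_deterministic_under_seed(self, uniform_parent):
        a = recon.poisson_sample(uniform_parent, 1000, seed=42)
        b = recon.poisson_sample(uniform_parent, 1000, seed=42)
        assert a == b

    def test_errors(self, uniform_parent):
        with pytest.raises(ValueError):
            recon.poisson_sample(uniform_parent, -1)
        with pytest.raises(ValueError):
            recon.poisson_sample(recon.CloneSizeDistribution({}), 10)

    def test_warns_when_sample_not_small_or_clone_dominates(self):
        parent = recon.CloneSizeDistribution({100: 10})
        with pytest.warns(UserWarning, match="fewer than 10x"):
            recon.poisson_sample(parent, 500, seed=0)
        dominant = recon.CloneSizeDistribution({900: 1, 1: 100})
        with pytest.warns(UserWarning, match="30%"):
            recon.poisson_sample(dominant, 10, seed=0)

    def test_clones_never_outnumber_cells(self, uniform_parent):
        for seed in range(5):
            s = recon.poisson_sample(uniform_parent, 500, seed=seed)
            assert s.n_clones <= s.total_cells


class TestExpectedSampleSpectrum:
    def test_single_component_poisson_counts(self):
        exp = recon.expected_sample_spectrum(mixture([1.0], [1.0], 1000), max_size=4)
        assert exp[0] == pytest.approx(1000 * math.exp(-1), rel=1e-9)
        assert exp[1] == pytest.approx(1000 * math.exp(-1), rel=1e-9)
        assert exp[2] == pytest.approx(1000 * math.exp(-1) / 2, rel=1e-9)

    def test_vanishing_mean_puts_all_mass_at_zero(self):
        exp = recon.expected_sample_spectrum(mixture([1.0], [1e-9], 100), max_size=3)
        assert exp[0] == pytest.approx(100, rel=1e-6)

    def test_two_component_zero_class(self):
        exp = recon.expected_sample_spectrum(mixture([0.5, 0.5], [1.0, 4.0], 100), 3)
        assert exp[0] == pytest.approx(50 * math.exp(-1) + 50 * math.exp(-4), rel=1e-9)

    def test_conservation_of_cells_in_expectation(self):
        mix = mixture([0.3, 0.7], [2.0, 5.0], 500)
        exp = recon.expected_sample_spectrum(mix, max_size=60)
        total = sum(i * v for i, v in exp.items())
        assert total == pytest.approx(500 * (0.3 * 2 + 0.7 * 5), rel=1e-8)
        assert sum(exp.values()) == pytest.approx(500, rel=1e-9)

    def test_simulation_converges_to_expectation(self):
        # pooled replicates vs expected spectrum, chi-square goodness of fit
        mix = mixture([1.0], [3.0], 1000)
        S = 3000  # each clone has frequency 1/1000 -> lambda = 3
        parent = recon.CloneSizeDistribution({1: 1000})
        pooled = np.zeros(40)
        reps = 40
        for seed in range(reps):
            smp = recon.poisson_sample(parent, S, seed=seed, check=False)
            for size, count in smp.as_dict().items():
                if size < 40:
                    pooled[int(size)] += count
        expect = recon.expected_sample_spectrum(mix, max_size=39)
        exp_arr = np.array([expect[i] for i in range(40)]) * reps
        keep = exp_arr > 5
        chi2 = ((pooled[keep] - exp_arr[keep]) ** 2 / exp_arr[keep]).sum()
        p = 1 - stats.chi2.cdf(chi2, df=keep.sum() - 1)
        assert p > 0.001


class TestResampleFromFit:
    def test_deterministic_and_missing_class_recorded(self):
        fit = mixture([1.0], [2.0], 500, scale=recon.RepertoireScale(N=None, S=1000))
        a = recon.resample_from_fit(fit, 1000, seed=9)
        b = recon.resample_from_fit(fit, 1000, seed=9)
        assert a == b
        # expected missing 500*e^-2 = 67.7
        missing = [recon.resample_from_fit(fit, 1000, seed=s).missing for s in range(12)]
        assert abs(np.mean(missing) - 500 * math.exp(-2)) < 4 * math.sqrt(67.7 / 12)

    def test_matches_direct_sampling_of_equivalent_parent(self):
        """Resampling a fit equal to a known parent reproduces direct Poisson sampling."""
        D, lam = 800, 2.5
        parent = recon.CloneSizeDistribution({1: D})
        fit = mixture([1.0], [lam], D, scale=recon.RepertoireScale(N=None, S=int(D * lam)))
        max_size = 12
        pooled_a = np.zeros(max_size)
        pooled_b = np.zeros(max_size)
        for seed in range(30):
            a = recon.poisson_sample(parent, int(D * lam), seed=seed, check=False)
            b = recon.resample_from_fit(fit, int(D * lam), seed=seed + 1000)
            for size, count in a.as_dict().items():
                pooled_a[min(int(size), max_size - 1)] += count
            for size, count in b.as_dict().items():
                pooled_b[min(int(size), max_size - 1)] += count
        table = np.vstack([pooled_a, pooled_b])
        keep = table.sum(axis=0) > 10
        _, p, _, _ = stats.chi2_contingency(table[:, keep])
        assert p > 0.01


def test_repertoire_scale_validation():
    with pytest.raises(ValueError):
        recon.RepertoireScale(N=10, S=100)
    scale = recon.RepertoireScale(N=10**9, S=10**6)
    assert scale.coverage(10**5) == pytest.approx(10.0)
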