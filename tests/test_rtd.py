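"""Residence-time distributions: stretched-exponential fitting machinery."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from statewell.rtd import (
    bootstrap_rtd,
    fit_stretched_exponential,
    kde_positive,
    sample_stretched_exponential,
    stretched_b,
    stretched_exp_pdf,
    successive_duration_correlation,
)


class TestStretchedForm:
    def test_b_constant_at_exponential_limit(self):
        # Gamma(2)/Gamma(1) = 1: the family reduces to (1/<t>) exp(-t/<t>)
        assert stretched_b(1.0) == pytest.approx(1.0)
        t = np.linspace(0.0, 500.0, 200)
        assert np.allclose(
            stretched_exp_pdf(t, 1.0, 100.0), np.exp(-t / 100.0) / 100.0
        )

    def test_b_constant_at_half(self):
        # Gamma(4)/Gamma(2) = 6
        assert stretched_b(0.5) == pytest.approx(6.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_density_self_consistency(self, seed):
        # unit mass and first moment <t> for random (alpha, <t>) pairs
        rng = np.random.default_rng(seed)
        for _ in range(4):
            alpha = rng.uniform(0.3, 2.0)
            mean_t = rng.uniform(10.0, 500.0)
            mass, _ = quad(stretched_exp_pdf, 0, np.inf, args=(alpha, mean_t),
                           limit=200)
            m1, _ = quad(lambda t: t * stretched_exp_pdf(t, alpha, mean_t),
                         0, np.inf, limit=200)
            assert mass == pytest.approx(1.0, abs=1e-6)
            assert m1 == pytest.approx(mean_t, rel=1e-3)


class TestSampler:
    def test_exponential_limit_mean(self):
        s = sample_stretched_exponential(1.0, 100.0, 10_000, seed=0)
        assert abs(s.mean() - 100.0) < 3 * 100.0 / np.sqrt(10_000)

    def test_heavy_tail_mean(self):
        s = sample_stretched_exponential(0.5, 100.0, 100_000, seed=1)
        se = s.std() / np.sqrt(len(s))
        assert abs(s.mean() - 100.0) < 3 * se

    def test_cdf_matches_quadrature(self):
        s = np.sort(sample_stretched_exponential(0.5, 100.0, 100_000, seed=2))
        grid = np.linspace(0.0, s[-1], 4000)
        pdf = stretched_exp_pdf(grid, 0.5, 100.0)
        cdf = np.cumsum((pdf[1:] + pdf[:-1]) / 2) * np.diff(grid)
        cdf = np.r_[0.0, cdf]
        emp = np.searchsorted(s, grid, side="right") / len(s)
        assert np.max(np.abs(emp - cdf)) < 0.01

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sample_stretched_exponential(2.5, 100.0, 10, seed=0)
        with pytest.raises(ValueError):
            sample_stretched_exponential(0.5, -1.0, 10, seed=0)


class TestKde:
    def test_exponential_sample_mean_recovered(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(100.0, 10_000)
        est = kde_positive(times)
        mean = np.trapezoid(est.grid * est.density, est.grid)
        mean /= np.exp(est.bandwidth**2 / 2)  # lognormal-kernel moment bias
        assert mean == pytest.approx(100.0, rel=0.03)

    def test_density_integrates_to_one(self):
        times = np.random.default_rng(4).exponential(50.0, 500)
        est = kde_positive(times)
        assert np.trapezoid(est.density, est.grid) == pytest.approx(1.0, abs=1e-3)
        assert est.density.min() >= 0.0

    def test_identical_durations_give_unit_mass_peak(self):
        est = kde_positive(np.full(10, 42.0))
        assert np.trapezoid(est.density, est.grid) == pytest.approx(1.0, abs=1e-6)
        assert est.grid[np.argmax(est.density)] == pytest.approx(42.0, rel=0.01)

    def test_too_few_or_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            kde_positive(np.array([1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(ValueError):
            kde_positive(np.array([1.0, 2.0, -3.0, 4.0, 5.0]))


class TestFit:
    def test_recovers_heavy_tail_parameters(self):
        times = sample_stretched_exponential(0.5, 100.0, 500, seed=5)
        fit = fit_stretched_exponential(times, seed=6)
        assert 0.4 <= fit.alpha <= 0.6
        assert abs(fit.mean_t - 100.0) / 100.0 <= 0.15
        assert fit.ks_p > 0.05

    def test_sampler_fitter_closure(self):
        # refitting draws from a fitted law recovers its parameters
        first = fit_stretched_exponential(
            sample_stretched_exponential(0.7, 50.0, 2000, seed=7), seed=8
        )
        redraw = sample_stretched_exponential(first.alpha, first.mean_t, 2000, seed=9)
        second = fit_stretched_exponential(redraw, seed=10)
        assert abs(second.alpha - first.alpha) <= 0.1
        assert abs(second.mean_t - first.mean_t) / first.mean_t <= 0.1

    def test_derived_constants_consistent(self):
        times = sample_stretched_exponential(0.8, 80.0, 1000, seed=11)
        fit = fit_stretched_exponential(times, seed=12)
        from scipy.special import gamma as G

        assert fit.b == pytest.approx(G(2 / fit.alpha) / G(1 / fit.alpha))
        assert fit.beta == pytest.approx((fit.b / fit.mean_t) ** fit.alpha)
        # K exp(-beta t^alpha) equals the normalized pdf
        t = np.array([10.0, 50.0, 200.0])
        assert np.allclose(
            fit.K * np.exp(-fit.beta * t**fit.alpha), fit.pdf(t), rtol=1e-10
        )


class TestBootstrap:
    def test_bands_are_reproducible(self):
        times = np.random.default_rng(13).exponential(100.0, 200)
        b1 = bootstrap_rtd(times, n_boot=50, seed=14)
        b2 = bootstrap_rtd(times, n_boot=50, seed=14)
        assert np.array_equal(b1.ci_lo, b2.ci_lo)
        assert np.array_equal(b1.ci_hi, b2.ci_hi)

    def test_single_resample_gives_degenerate_band(self):
        times = np.random.default_rng(15).exponential(100.0, 100)
        b = bootstrap_rtd(times, n_boot=1, seed=16)
        assert np.allclose(b.ci_lo, b.ci_hi)

    def test_band_covers_true_density(self):
        times = np.random.default_rng(17).exponential(100.0, 1000)
        b = bootstrap_rtd(times, n_boot=200, seed=18)
        true = np.where(b.grid >= 0, np.exp(-b.grid / 100.0) / 100.0, 0.0)
        inside = (true >= b.ci_lo) & (true <= b.ci_hi)
        # evaluate coverage where the density is non-negligible
        core = true > 1e-4
        assert inside[core].mean() >= 0.9


class TestSuccessiveCorrelation:
    def test_iid_durations_show_no_correlation(self):
        durations = np.random.default_rng(19).exponential(50.0, 400)
        (r, p), = successive_duration_correlation(durations, max_lag=1)
        assert abs(r) < 2 / np.sqrt(400)

    def test_ar1_log_durations_recover_rho(self):
        rng = np.random.default_rng(20)
        rho, n = 0.3, 4000
        z = np.empty(n)
        z[0] = rng.normal()
        for i in range(1, n):
            z[i] = rho * z[i - 1] + rng.normal() * np.sqrt(1 - rho**2)
        durations = np.exp(0.3 * z + 3.0)
        (r, p), = successive_duration_correlation(durations, max_lag=1)
        assert abs(r - 0.3) < 0.1
        assert p < 1e-4

    def test_alternating_sequence_strongly_negative(self):
        durations = np.tile([10.0, 200.0], 50)
        (r, _), = successive_duration_correlation(durations, max_lag=1)
        assert r < -0.9

    def test_constant_sequence_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            successive_duration_correlation(np.full(50, 5.0), max_lag=1)
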