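import numpy as np
import pytest

from aadkit import (
    autocorrelation,
    compare_powerlaw_exponential,
    fit_double_powerlaw,
    fit_powerlaw_mle,
    fit_stretched_exponential,
    gen_alpha_modulated_recording,
    gen_double_powerlaw_quiet_times,
    gen_truncated_powerlaw,
    log_bins,
    power_spectrum,
)
from aadkit.scaling_stats import log_binned_density


def grid_search_mle(x, xmin, xmax, alphas):
    """Brute-force likelihood oracle on an explicit exponent grid."""
    from aadkit.scaling_stats import _pl_logpdf
    ll = [float(_pl_logpdf(x, a, xmin, xmax).sum()) for a in alphas]
    return alphas[int(np.argmax(ll))]


class TestPowerlawMLE:
    def test_closed_form_exact(self):
        # every x = e * xmin => sum(ln x/xmin) = n => alpha = 1 + n/n = 2
        x = np.full(50, np.e)
        fit = fit_powerlaw_mle(x, xmin=1.0)
        assert fit.params["alpha"] == pytest.approx(2.0, abs=1e-12)

    def test_recovery_unbounded(self):
        x = gen_truncated_powerlaw(2.5, 1.0, np.inf, 20_000, seed=1)
        fit = fit_powerlaw_mle(x, 1.0)
        assert abs(fit.params["alpha"] - 2.5) < 3 * fit.params["se"]

    def test_finite_xmax_matches_grid_oracle(self):
        x = gen_truncated_powerlaw(1.969, 0.1, 1.0, 20_000, seed=2)
        fit = fit_powerlaw_mle(x, 0.1, 1.0)
        alphas = np.arange(1.5, 2.5, 1e-4)
        a_grid = grid_search_mle(x, 0.1, 1.0, alphas)
        assert abs(fit.params["alpha"] - a_grid) < 1e-3

    def test_alpha_below_one_recovered(self):
        x = gen_truncated_powerlaw(0.79, 0.0033, 0.1, 30_000, seed=3)
        fit = fit_powerlaw_mle(x, 0.0033, 0.1)
        assert abs(fit.params["alpha"] - 0.79) < 3 * fit.params["se"]

    @pytest.mark.parametrize("alpha", [0.8, 1.5, 2.0, 2.5])
    def test_bias_sweep(self, alpha):
        x = gen_truncated_powerlaw(alpha, 0.01, 10.0, 10_000, seed=int(alpha * 10))
        fit = fit_powerlaw_mle(x, 0.01, 10.0)
        assert abs(fit.params["alpha"] - alpha) < 2 * fit.params["se"] + 0.01

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fit_powerlaw_mle(np.linspace(0.5, 2, 20), xmin=1.0)


class TestModelComparison:
    def test_power_law_sample_prefers_power_law(self):
        x = gen_truncated_powerlaw(2.0, 1.0, np.inf, 5000, seed=4)
        R, p = compare_powerlaw_exponential(x, 1.0)
        assert R > 0 and p < 0.05

    def test_exponential_sample_prefers_exponential(self, rng):
        x = 1.0 + rng.exponential(2.0, size=5000)
        R, p = compare_powerlaw_exponential(x, 1.0)
        assert R < 0 and p < 0.05

    def test_type_one_error_rate_under_exponential_null(self):
        # false power-law preferences at p<0.05 should stay near/below 5%
        hits = 0
        n_rep = 200
        for k in range(n_rep):
            rng = np.random.default_rng(1000 + k)
            x = 1.0 + rng.exponential(1.0, size=300)
            R, p = compare_powerlaw_exponential(x, 1.0)
            hits += int(R > 0 and p < 0.05)
        assert hits <= n_rep * 0.05 + 3 * np.sqrt(n_rep * 0.05 * 0.95)


class TestDoublePowerlaw:
    def test_recovery_with_figure_exponents(self):
        dt = gen_double_powerlaw_quiet_times(0.79, 1.97, 0.1, 0.0033, 1.0,
                                             50_000, seed=5)
        lo, hi, xc = fit_double_powerlaw(dt)
        assert 0.07 <= xc <= 0.14
        assert abs(lo.params["alpha"] - 0.79) < 3 * lo.params["se"] + 0.03
        assert abs(hi.params["alpha"] - 1.97) < 3 * hi.params["se"] + 0.05

    def test_single_power_law_degenerates(self):
        dt = gen_double_powerlaw_quiet_times(2.0, 2.0, 0.1, 0.01, 1.0,
                                             30_000, seed=6)
        lo, hi, _ = fit_double_powerlaw(dt, crossover=0.1)
        joint = np.hypot(lo.params["se"], hi.params["se"])
        assert abs(lo.params["alpha"] - hi.params["alpha"]) < 3 * joint

    def test_grid_selection_consistent_with_forced_crossover(self):
        dt = gen_double_powerlaw_quiet_times(0.79, 1.97, 0.1, 0.0033, 1.0,
                                             50_000, seed=7)
        lo_g, hi_g, _ = fit_double_powerlaw(dt)
        lo_f, hi_f, _ = fit_double_powerlaw(dt, crossover=0.1)
        assert abs(lo_g.params["alpha"] - lo_f.params["alpha"]) < \
            lo_g.params["se"] + lo_f.params["se"] + 0.02
        assert abs(hi_g.params["alpha"] - hi_f.params["alpha"]) < \
            hi_g.params["se"] + hi_f.params["se"] + 0.05


class TestQuietTimeSampler:
    def test_ks_against_closed_form_cdf(self):
        x = gen_truncated_powerlaw(2.0, 1.0, np.inf, 100_000, seed=8)
        xs = np.sort(x)
        cdf = 1.0 - 1.0 / xs
        emp = np.arange(1, xs.size + 1) / xs.size
        assert np.max(np.abs(emp - cdf)) < 0.01

    def test_log_uniform_mean_matches_integral(self):
        # alpha = 1 on [1, e]: E[X] = int x * (1/x)/ln(e) dx = e - 1
        n = 100_000
        x = gen_truncated_powerlaw(1.0, 1.0, np.e, n, seed=9)
        se = x.std() / np.sqrt(n)
        assert abs(x.mean() - (np.e - 1.0)) < 3 * se

    def test_alpha_half_quantiles_match_numeric_inverse(self):
        from scipy.optimize import brentq
        alpha, lo, hi = 0.5, 0.01, 0.1
        a1 = 1 - alpha

        def cdf(v):
            return (v**a1 - lo**a1) / (hi**a1 - lo**a1)

        x = gen_truncated_powerlaw(alpha, lo, hi, 100_000, seed=10)
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            v_oracle = brentq(lambda v: cdf(v) - q, lo, hi)  # numeric root
            assert abs(np.quantile(x, q) - v_oracle) < 0.01 * v_oracle + 2e-4

    def test_density_continuity_at_crossover(self):
        dt = gen_double_powerlaw_quiet_times(0.79, 1.97, 0.1, 0.01, 1.0,
                                             1_000_000, seed=11)
        # histogram oracle: narrow bins flanking the crossover
        w = 0.004
        left = np.count_nonzero((dt > 0.1 - w) & (dt <= 0.1)) / w
        right = np.count_nonzero((dt > 0.1) & (dt <= 0.1 + w)) / w
        assert abs(left - right) / left < 0.05

    def test_piecewise_mass_split(self):
        from scipy.integrate import quad
        mu1, mu2, xc, lo, hi = 0.79, 1.97, 0.1, 0.0033, 1.0
        z1 = quad(lambda v: v**-mu1, lo, xc)[0]
        z2 = quad(lambda v: xc**(mu2 - mu1) * v**-mu2, xc, hi)[0]
        frac_oracle = z1 / (z1 + z2)
        n = 200_000
        dt = gen_double_powerlaw_quiet_times(mu1, mu2, xc, lo, hi, n, seed=12)
        frac = float(np.mean(dt < xc))
        se = np.sqrt(frac_oracle * (1 - frac_oracle) / n)
        assert abs(frac - frac_oracle) < 3 * se

    def test_nonnormalizable_rejected(self):
        with pytest.raises(ValueError):
            gen_truncated_powerlaw(1.0, 1.0, np.inf, 10)


class TestStretchedExponential:
    def test_noiseless_inversion(self):
        t = np.linspace(0.5, 20, 20)
        N = np.exp(-((t / 2.0) ** 0.25))
        fit = fit_stretched_exponential(t, N)
        assert fit.params["beta"] == pytest.approx(0.25, abs=1e-6)
        assert fit.params["tau_se"] == pytest.approx(2.0, abs=1e-5)

    def test_time_rescaling_covariance(self):
        t = np.linspace(0.5, 20, 25)
        N = 3.0 * np.exp(-((t / 2.0) ** 0.5))
        tau1 = fit_stretched_exponential(t, N).params["tau_se"]
        tau2 = fit_stretched_exponential(5 * t, N).params["tau_se"]
        assert tau2 == pytest.approx(5 * tau1, rel=1e-4)


class TestLogBins:
    def test_second_boundary(self):
        b = log_bins(0.01, 0.1, 1.0)
        assert b[1] == pytest.approx(0.01 * 10**0.1, rel=1e-12)

    def test_ten_windows_per_decade(self):
        b = log_bins(0.01, 0.1, 0.1)
        assert b.size - 1 == 10

    def test_strictly_increasing(self):
        b = log_bins(0.005, 0.07, 50.0)
        assert np.all(np.diff(b) > 0)


class TestAutocorrelation:
    def test_white_noise_null(self, rng):
        x = rng.standard_normal(4000)
        C = autocorrelation(x, 50)
        assert C[0] == pytest.approx(1.0)
        assert np.all(np.abs(C[1:]) < 3 / np.sqrt(x.size) + 0.02)

    def test_periodic_series(self):
        x = np.tile(np.arange(10.0), 40)
        C = autocorrelation(x, 20)
        assert C[10] == pytest.approx(1.0, abs=1e-9)

    def test_bounded_by_one(self, rng):
        x = np.cumsum(rng.standard_normal(2000))
        C = autocorrelation(x, 100)
        assert np.all(C <= 1 + 1e-12) and np.all(C >= -1 - 1e-12)


class TestPowerSpectrum:
    def test_pure_sinusoid_peak(self):
        from aadkit import MultichannelRecording
        fs = 200.0
        t = np.arange(int(20 * fs)) / fs
        rec = MultichannelRecording(np.sin(2 * np.pi * 10 * t)[None, :], fs)
        s = power_spectrum(rec)
        assert abs(s.f_alpha_max - 10.0) <= 0.5

    def test_alpha_recording_peak_matches_generator(self):
        rec = gen_alpha_modulated_recording(f_alpha=11.0, duration=30.0, seed=13)
        s = power_spectrum(rec)
        assert abs(s.f_alpha_max - 11.0) <= 0.5


def test_log_binned_density_slope_matches_exponent():
    x = gen_truncated_powerlaw(1.8, 0.01, 100.0, 200_000, seed=14)
    centers, dens = log_binned_density(x, c=0.1)
    # central decade, well inside the support
    ok = (centers > 0.1) & (centers < 1.0) & (dens > 0)
    slope = np.polyfit(np.log(centers[ok]), np.log(dens[ok]), 1)[0]
    assert abs(slope - (-1.8)) < 0.05
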