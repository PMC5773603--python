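"""Lifetime fitting, correction chain and calibration fits."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from azcal import flim
from azcal import synthetic


LT = flim.LifetimePair()


class TestConstants:
    def test_quantum_yield_part_is_lifetime_ratio(self):
        assert flim.brightness_factor(1.0, LT) == pytest.approx(14.1, abs=0.05)

    def test_brightness_factor_from_amplitude_ratio(self):
        assert flim.brightness_factor(1.99, LT) == pytest.approx(28.03,
                                                                 abs=0.01)

    def test_identical_states_give_unity(self):
        lt = flim.LifetimePair(1.0, 1.0 + 1e-12)
        assert flim.brightness_factor(1.0, lt) == pytest.approx(1.0)


class TestFitDecay:
    @staticmethod
    def _exgauss_curve(amplitudes, mu=12.2, fwhm_ps=110.0, n=1024, d=0.025):
        """Analytic bin-integrated Gaussian-IRF x exponential decay
        (exponentially modified Gaussian), independent of the fitter's
        discrete reconvolution path."""
        from scipy.stats import norm

        sigma = fwhm_ps * 1e-3 / (2 * math.sqrt(2 * math.log(2)))
        edges = np.arange(n + 1) * d

        def cdf(t, tau):
            u = (t - mu) / sigma
            return norm.cdf(u) - np.exp(
                -(t - mu) / tau + sigma**2 / (2 * tau**2)) * norm.cdf(
                    u - sigma / tau)

        counts = np.zeros(n)
        for alpha, tau in amplitudes:
            counts += alpha * tau / d * np.diff(cdf(edges, tau))
        return counts

    @pytest.mark.parametrize("au, ab", [(2000.0, 700.0), (500.0, 500.0),
                                        (5000.0, 100.0)])
    def test_noiseless_amplitudes_recovered_exactly(self, au, ab):
        irf = flim.gaussian_irf()
        counts = self._exgauss_curve([(au, LT.tau_free_ns),
                                      (ab, LT.tau_bound_ns)])
        fit = flim.fit_decay(flim.DecayHistogram(counts), irf)
        assert fit.alpha_free == pytest.approx(au, rel=1e-3)
        assert fit.alpha_bound == pytest.approx(ab, rel=1e-3)

    def test_pure_bound_sample_has_negligible_fast_channel(self):
        spec = synthetic.DecayGenSpec(ca_uM=1e9, photons=1e6, seed=0)
        hist, irf, _ = synthetic.gen_decay_histogram(spec)
        fit = flim.fit_decay(hist, irf)
        assert fit.F_U / (fit.F_U + fit.F_B) < 0.01

    @pytest.mark.parametrize("ca", [1.0, 20.0, 195.0])
    def test_mixture_recovered_within_poisson_error(self, ca):
        spec = synthetic.DecayGenSpec(ca_uM=ca, photons=2e5, seed=42)
        hist, irf, truth = synthetic.gen_decay_histogram(spec)
        fit = flim.fit_decay(hist, irf)
        for got, expect in [(fit.F_U, truth["F_free_expected"]),
                            (fit.F_B, truth["F_bound_expected"])]:
            assert abs(got - expect) < 3 * math.sqrt(expect) + 0.02 * expect

    def test_count_threshold_enforced(self):
        hist = flim.DecayHistogram(np.zeros(1024))
        with pytest.raises(flim.InsufficientSignalError):
            flim.fit_decay(hist, flim.gaussian_irf())

    def test_blanked_fit_freezes_first_pass_shift(self):
        spec = synthetic.DecayGenSpec(ca_uM=50.0, photons=5e5, seed=3)
        hist, irf, _ = synthetic.gen_decay_histogram(spec)
        full = flim.fit_decay(hist, irf)
        blanked = flim.fit_decay(hist, irf, blank_ps=300.0)
        assert blanked.shift_ps == pytest.approx(full.shift_ps, abs=1e-9)
        assert blanked.blank_ps == 300.0


class TestFitMonoexp:
    @pytest.mark.parametrize("tau", [3.24, 0.23])
    def test_lifetime_recovered(self, tau):
        rng = np.random.default_rng(5)
        irf = flim.gaussian_irf()
        t = 12.2 + rng.normal(0, 0.0467, 500_000) + rng.exponential(tau,
                                                                    500_000)
        counts, _ = np.histogram(t, bins=1024, range=(0, 25.6))
        fit = flim.fit_monoexp(flim.DecayHistogram(counts), irf)
        assert fit.tau_ns == pytest.approx(tau, abs=0.03)
        assert not fit.degenerate

    def test_pure_irf_flagged_degenerate(self):
        irf = flim.gaussian_irf()
        counts = np.round(irf.curve * 1e6)
        fit = flim.fit_monoexp(flim.DecayHistogram(counts), irf)
        assert fit.degenerate
        assert fit.tau_ns <= 0.025


class TestStedEfficiency:
    def test_zero_power_unity(self):
        s = flim.sted_efficiency_factor([1.0, 0.2], [1.0, 0.41])
        assert s[0] == 1.0

    def test_ratio(self):
        s = flim.sted_efficiency_factor([1.0, 0.2], [1.0, 0.41])
        assert s[1] == pytest.approx(0.488, abs=0.001)

    def test_equal_depletion_gives_unity(self):
        s = flim.sted_efficiency_factor([1.0, 0.5], [1.0, 0.5])
        assert np.allclose(s, 1.0)

    def test_inconsistent_curves_warn(self):
        with pytest.warns(UserWarning, match="inconsistent"):
            flim.sted_efficiency_factor([1.0, 0.6], [1.0, 0.5])


class TestScaledRatios:
    CORR = flim.CorrectionSet(b=28.02, s=0.491, r_min=0.04, r_max=0.6,
                              K_eff=195.0)

    def test_worked_example(self):
        est = flim.calcium_scaled_ratios(100.0, 280.2, self.CORR)
        assert est.ca_uM == pytest.approx(58.5, abs=0.1)

    def test_symmetric_midpoint_reports_keff(self):
        # F_B/b = F_U*s with r_min = 1 - r_max puts both rescaled
        # fractions at 1/2
        corr = flim.CorrectionSet(b=2.0, s=0.5, r_min=0.3, r_max=0.7,
                                  K_eff=195.0)
        est = flim.calcium_scaled_ratios(10.0, 10.0, corr)
        assert est.ca_uM == pytest.approx(195.0)

    def test_ratio_at_rmin_reports_zero(self):
        # choose F so that r_B exactly equals r_min
        corr = self.CORR
        F_U = 100.0
        F_B = corr.b * (corr.r_min / (1 - corr.r_min)) * F_U * corr.s
        est = flim.calcium_scaled_ratios(F_U, F_B, corr)
        assert est.ca_uM == pytest.approx(0.0, abs=1e-12)

    def test_saturation_flagged_infinite(self):
        est = flim.calcium_scaled_ratios(0.0, 1000.0, self.CORR)
        assert est.saturated
        assert math.isinf(est.ca_uM)

    def test_below_range_clipped_to_zero(self):
        est = flim.calcium_scaled_ratios(1000.0, 0.0, self.CORR)
        assert est.clipped
        assert est.ca_uM == 0.0

    @given(
        f_u=st.floats(0.1, 1e6),
        f_b=st.floats(0.1, 1e6),
        b=st.floats(1.5, 50),
        s=st.floats(0.2, 1.0),
    )
    def test_fraction_identities(self, f_u, f_b, b, s):
        corr = flim.CorrectionSet(b=b, s=s, r_min=0.04, r_max=0.6)
        est = flim.calcium_scaled_ratios(f_u, f_b, corr)
        inter = est.intermediates
        assert float(inter["r_B"] + inter["r_U"]) == pytest.approx(1.0)

    @given(st.floats(1.0, 1e5), st.floats(1.0, 1e5), st.floats(1.0, 1e5))
    def test_monotone_in_bound_photons(self, f_u, f_b, df):
        corr = self.CORR
        lo = flim.calcium_scaled_ratios(f_u, f_b, corr)
        hi = flim.calcium_scaled_ratios(f_u, f_b + df, corr)
        assert hi.ca_uM >= lo.ca_uM


class TestInsensitiveFraction:
    CORR = flim.CorrectionSet(b=28.02, s=0.491, r_min=0.04, r_max=0.6,
                              K_eff=195.0)

    def test_no_change_reports_zero(self):
        est = flim.calcium_insensitive_fraction(100.0, 100.0, 1000.0,
                                                self.CORR)
        assert est.ca_uM == 0.0

    def test_worked_example(self):
        est = flim.calcium_insensitive_fraction(500.0, 100.0, 1000.0,
                                                self.CORR)
        assert est.ca_uM == pytest.approx(10.68, abs=0.02)

    def test_half_denominator_reports_keff(self):
        corr = self.CORR
        F_U = 1000.0
        dfb = F_U * corr.b * corr.s * corr.R / 2.0
        est = flim.calcium_insensitive_fraction(dfb + 50.0, 50.0, F_U, corr)
        assert est.ca_uM == pytest.approx(195.0)

    def test_out_of_range_flagged(self):
        est = flim.calcium_insensitive_fraction(1e9, 0.0, 1.0, self.CORR)
        assert est.saturated

    @given(st.floats(0.0, 1e4), st.floats(1.0, 1e4))
    def test_monotone_in_bound_increase(self, dfb, f_u):
        corr = self.CORR
        a = flim.calcium_insensitive_fraction(100.0 + dfb, 100.0, f_u, corr)
        b = flim.calcium_insensitive_fraction(100.0 + dfb + 1.0, 100.0, f_u,
                                              corr)
        if not (a.saturated or b.saturated):
            assert b.ca_uM > a.ca_uM


class TestKeff:
    def test_noiseless_exact_recovery(self):
        ca = np.array([1.0, 10.0, 100.0, 1000.0, 10000.0])
        f = 1000.0 * ca / (ca + 195.0)
        fit = flim.fit_keff(ca, f)
        assert fit.K_eff == pytest.approx(195.0, rel=1e-6)
        assert fit.F_slow_max == pytest.approx(1000.0, rel=1e-6)

    def test_midpoint_identity(self):
        fit = flim.fit_keff(np.array([1.0, 10.0, 195.0, 1e4]),
                            1000 * np.array([1.0, 10.0, 195.0, 1e4])
                            / (np.array([1.0, 10.0, 195.0, 1e4]) + 195.0))
        assert 1000 * 195.0 / (195.0 + fit.K_eff) == pytest.approx(500.0,
                                                                   rel=1e-6)

    def test_noisy_calibration_series_recovery(self):
        # the in vitro design: 12 points log-spaced 0.01 .. 80000 uM,
        # 5% multiplicative noise
        ca = np.logspace(math.log10(0.01), math.log10(80_000), 12)
        ests = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            f = 1000 * ca / (ca + 195.0) * rng.normal(1.0, 0.05, ca.size)
            ests.append(flim.fit_keff(ca, f).K_eff)
        assert np.median(ests) == pytest.approx(195.0, rel=0.15)

    def test_unbracketed_series_warns(self):
        ca = np.array([1.0, 2.0, 3.0, 4.0])
        f = 1000 * ca / (ca + 195.0)
        with pytest.warns(UserWarning, match="ill-conditioned"):
            fit = flim.fit_keff(ca, f)
        assert fit.ill_conditioned


class TestTimeGate:
    def test_450ps_gate_removes_most_free_signal(self):
        g = flim.time_gate(flim.DecayHistogram(np.zeros(1024)), 450.0, LT)
        assert g.removed_fraction_free == pytest.approx(0.859, abs=0.001)
        assert 0.80 <= g.removed_fraction_free <= 0.90

    def test_bound_signal_sacrifice(self):
        g = flim.time_gate(flim.DecayHistogram(np.zeros(1024)), 450.0, LT)
        assert g.removed_fraction_bound == pytest.approx(0.130, abs=0.001)

    def test_zero_gate_removes_nothing(self):
        counts = np.arange(1024, 0, -1.0)
        g = flim.time_gate(flim.DecayHistogram(counts), 0.0, LT)
        assert g.removed_fraction_free == 0.0
        assert np.array_equal(g.gated.counts, counts)

    def test_gated_histogram_zeroes_gate_window(self):
        spec = synthetic.DecayGenSpec(ca_uM=10.0, photons=1e5, seed=0)
        hist, _, _ = synthetic.gen_decay_histogram(spec)
        g = flim.time_gate(hist, 450.0, LT)
        onset = int(np.argmax(hist.counts))
        assert g.gated.counts[onset:onset + 18].sum() == 0
        assert g.gated.total < hist.total
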