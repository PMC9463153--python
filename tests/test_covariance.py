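"""Covariance models: normalization, positivity, limits, conditioning."""

import numpy as np
import pytest

from quenchfp import (CovarianceSpec, PastObservation, condition_on_past,
                      conditioned_spec, sigma_quench, sigma_stationary,
                      scaling_function, fbm_two_sided_cov)


class TestQuenchCovariance:
    def test_starts_at_fixed_point(self):
        assert sigma_quench(5.0, 0.0, H=0.375, T=0.3) == pytest.approx(0.0)

    def test_brownian_at_half_for_every_temperature(self):
        t, tp = np.meshgrid(np.geomspace(0.1, 50, 12),
                            np.geomspace(0.1, 50, 12))
        ref = np.minimum(t, tp)
        for T in (0.0, 0.5, 1.0, 2.0):
            assert np.allclose(sigma_quench(t, tp, H=0.5, T=T), ref,
                               rtol=1e-12)

    def test_pure_fbm_value(self):
        # T = 1: sigma(2, 1) = (2^{2H} + 1 - 1)/2
        val = sigma_quench(2.0, 1.0, H=0.375, T=1.0)
        assert val == pytest.approx(2.0**0.75 / 2.0, rel=1e-12)

    def test_msd_normalization(self):
        t = np.geomspace(1e-3, 1e3, 13)
        for T in (0.0, 0.7, 2.0):
            for H in (0.375, 0.55):
                assert np.allclose(sigma_quench(t, t, H=H, T=T), t ** (2 * H),
                                   rtol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sigma_quench(1.0, 1.0, H=1.2, T=0.0)
        with pytest.raises(ValueError):
            sigma_quench(-1.0, 1.0, H=0.5, T=0.0)
        with pytest.raises(ValueError):
            sigma_quench(1.0, 1.0, H=0.5, T=-0.5)

    @pytest.mark.parametrize("kind,T", [("quench", 0.0), ("quench", 2.0),
                                        ("stationary", 1.0)])
    def test_positive_semidefinite_on_random_grids(self, kind, T):
        rng = np.random.default_rng(7)
        for H in (0.375, 0.55):
            spec = CovarianceSpec(H=H, kind=kind, T=T)
            for _ in range(50):
                npts = rng.integers(4, 64)
                times = np.sort(rng.uniform(0.01, 100.0, npts))
                C = spec.matrix(times)
                ev = np.linalg.eigvalsh(C)
                assert ev[0] >= -1e-8 * ev[-1]

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0.1, 10, 20), rng.uniform(0.1, 10, 20)
        assert np.allclose(sigma_quench(a, b, 0.42, 0.3),
                           sigma_quench(b, a, 0.42, 0.3))


class TestStationaryLimit:
    def test_normalized_unit_lag(self):
        assert sigma_stationary(1.0, 1.0, H=0.375, amp=0.5) == \
            pytest.approx(1.0)

    def test_zero_lag(self):
        assert sigma_stationary(3.0, 0.0, H=0.61) == pytest.approx(0.0)

    def test_quench_increments_converge_to_stationary(self):
        # the T-dependent part cancels identically; the rest decays
        H, T = 0.375, 0.0
        spec = CovarianceSpec(H=H, kind="quench", T=T)
        t = 1e4
        tau, taup = 1.0, 2.0
        inc = (spec.sigma(t + tau, t + taup) - spec.sigma(t + tau, t)
               - spec.sigma(t, t + taup) + spec.sigma(t, t))
        ref = spec.sigma_s(tau, taup)
        assert abs(inc - ref) / ref < 1e-3

    def test_increment_convergence_rate(self):
        # error decays as t^{2H-2}: fitted exponent within 0.2
        H = 0.375
        spec = CovarianceSpec(H=H, kind="quench", T=0.0)
        ts = np.geomspace(1e2, 1e5, 8)
        errs = []
        for t in ts:
            inc = (spec.sigma(t + 1, t + 2) - spec.sigma(t + 1, t)
                   - spec.sigma(t, t + 2) + spec.sigma(t, t))
            errs.append(abs(inc - spec.sigma_s(1.0, 2.0)))
        slope = np.polyfit(np.log(ts), np.log(errs), 1)[0]
        assert abs(slope - (2 * H - 2)) < 0.2


class TestScalingFunction:
    def test_unity_at_equal_times(self):
        spec = CovarianceSpec(H=0.375, kind="quench", T=0.3)
        assert scaling_function(spec, 1.0) == pytest.approx(1.0)

    def test_fbm_closed_form(self):
        spec = CovarianceSpec(H=0.375, kind="quench", T=1.0)
        u = np.array([0.1, 0.5, 0.9])
        ref = 0.5 * (1 + u**0.75 - (1 - u) ** 0.75)
        assert np.allclose(scaling_function(spec, u), ref, rtol=1e-12)

    def test_exact_scale_freedom(self):
        spec = CovarianceSpec(H=0.375, kind="quench", T=0.0)
        g1 = scaling_function(spec, 0.5, t_ref=1e3)
        g2 = scaling_function(spec, 0.5, t_ref=2e3)
        assert abs(g1 - g2) < 1e-6

    def test_G_smooth_m1_matches_direct(self):
        for kind, T in (("quench", 0.0), ("quench", 2.0),
                        ("stationary", 1.0)):
            spec = CovarianceSpec(H=0.42, kind=kind, T=T)
            u = np.array([0.2, 0.8, 1.0 - 1e-7])
            direct = spec.G_smooth(u) - 1.0
            assert np.allclose(spec.G_smooth_m1(u), direct, atol=1e-9)
            # near 1 the stable form resolves the O(1-u) deviation
            u = 1.0 - 1e-10
            assert spec.G_smooth_m1(u) == pytest.approx(
                -spec.g1 * 1e-10, rel=1e-3)


class TestConditioning:
    def test_markov_case_reduces_to_brownian(self):
        past = PastObservation.geometric(H=0.5, T_past=100.0, n=60, seed=0)
        fut = np.geomspace(0.1, 10.0, 15)
        cm = condition_on_past(past, fut)
        ref = np.minimum(fut[:, None], fut[None, :])
        assert np.allclose(cm.cov, ref, atol=1e-8)
        assert np.allclose(cm.mean, 0.0, atol=1e-8)

    def test_empty_past_is_unconditional(self):
        past = PastObservation(np.array([0.0]), np.array([0.0]), H=0.7)
        fut = np.geomspace(0.1, 10.0, 8)
        cm = condition_on_past(past, fut)
        ref = fbm_two_sided_cov(fut[:, None], fut[None, :], 0.7)
        assert np.allclose(cm.cov, ref)

    def test_variance_reduction(self):
        past = PastObservation.geometric(H=0.75, T_past=1e3, n=200, seed=1)
        cm = condition_on_past(past, np.array([1.0]))
        assert 0.0 < cm.cov[0, 0] < 1.0   # unconditional variance is 1

    def test_conditional_dominated_by_unconditional(self):
        past = PastObservation.geometric(H=0.6, T_past=100.0, n=80, seed=2)
        fut = np.geomspace(0.2, 5.0, 10)
        cm = condition_on_past(past, fut)
        diff = fbm_two_sided_cov(fut[:, None], fut[None, :], 0.6) - cm.cov
        assert np.linalg.eigvalsh(diff)[0] >= -1e-9

    def test_mean_linear_in_past(self):
        t = np.append(-np.geomspace(50, 0.5, 40), 0.0)
        x1 = PastObservation(t, np.sin(t), H=0.7)
        x2 = PastObservation(t, 2.0 * np.sin(t), H=0.7)
        fut = np.array([0.5, 2.0])
        m1 = condition_on_past(x1, fut).mean
        m2 = condition_on_past(x2, fut).mean
        assert np.allclose(m2, 2.0 * m1, rtol=1e-9)

    def test_conditioned_spec_scaling_table(self):
        spec = conditioned_spec(H=0.6, past_decades=(-5.0, 4.0),
                                n_per_decade=16, u_min=1e-5)
        assert spec.G(1.0) == pytest.approx(1.0)
        # far-future increments recover plain fBM increments: the
        # diagonal of the scaled covariance is flat in the table
        u = np.geomspace(1e-3, 1.0, 10)
        g = spec.G(u)
        assert np.all(np.isfinite(g)) and g[-1] == pytest.approx(1.0)
        assert spec.s_amp == pytest.approx(0.5 / spec.meta["c_inf"],
                                           rel=1e-9)


class TestSerialization:
    def test_spec_roundtrip(self):
        spec = CovarianceSpec(H=0.44, kind="quench", T=1.7, d=2)
        again = CovarianceSpec.from_dict(spec.to_dict())
        u = np.geomspace(1e-3, 1, 9)
        assert np.allclose(spec.G(u), again.G(u))

    def test_past_tsv_roundtrip(self, tmp_path):
        past = PastObservation.geometric(H=0.6, T_past=10.0, n=20, seed=3)
        path = tmp_path / "past.tsv"
        past.to_tsv(path)
        again = PastObservation.from_tsv(path, H=0.6)
        assert np.allclose(past.times, again.times)
        assert np.allclose(past.positions, again.positions)

    def test_invalid_past_rejected(self):
        with pytest.raises(ValueError):
            PastObservation(np.array([-2.0, -1.0]), np.zeros(2), H=0.5)
        with pytest.raises(ValueError):
            PastObservation(np.array([-1.0, 0.5]), np.zeros(2), H=0.5)
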