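"""Exact mode-based simulators: spectra, Hurst exponents, OU exactness."""

import numpy as np
import pytest

from quenchfp import (CovarianceSpec, ModeSystem, interface_modes,
                      rouse_chain, vicsek_network, network_modes,
                      sample_tagged, sample_gaussian, msd_from_modes,
                      cov_from_modes, hurst_fit, sigma_quench,
                      condition_on_past, PastObservation)
from quenchfp.simulate import scaling_window


class TestNetworks:
    def test_vicsek_star_spectrum(self):
        net = vicsek_network(4, 1)
        ev = np.linalg.eigvalsh(net.laplacian)
        assert np.allclose(ev, [0, 1, 1, 1, 5], atol=1e-10)

    def test_vicsek_generation_3_connected(self):
        net = vicsek_network(4, 3)
        assert net.n_beads == 125
        ev = np.linalg.eigvalsh(net.laplacian)
        assert np.sum(ev < 1e-8) == 1      # single zero mode

    def test_vicsek_odd_functionality_connected(self):
        net = vicsek_network(3, 3)
        assert net.n_beads == 64
        ev = np.linalg.eigvalsh(net.laplacian)
        assert np.sum(ev < 1e-8) == 1

    def test_rouse_chain_is_path_graph(self):
        net = rouse_chain(5)
        deg = np.diag(net.laplacian)
        assert list(deg) == [1, 2, 2, 2, 1]

    def test_interface_eigenvalue_scaling(self):
        for model, z in (("EW", 2), ("MH", 4)):
            ms = interface_modes(model, L=64.0, M=16)
            lam = ms.eigenvalues
            assert lam[3] / lam[1] == pytest.approx(2.0**z, rel=1e-12)


class TestHurstExponents:
    @pytest.mark.parametrize("builder,H_ref", [
        (lambda: interface_modes("MH", L=512.0), 0.375),
        (lambda: interface_modes("EW", L=512.0), 0.25),
        (lambda: network_modes(rouse_chain(512)), 0.25),
        (lambda: network_modes(vicsek_network(4, 4)), 0.203),
    ])
    def test_mode_sum_msd_slope(self, builder, H_ref):
        ms = builder()
        lo, hi = scaling_window(ms)
        t = np.geomspace(lo, hi, 60)
        H, err = hurst_fit(t, msd_from_modes(ms, t))
        assert H == pytest.approx(H_ref, abs=0.02)


class TestExactSampling:
    def test_seeded_determinism(self):
        ms = interface_modes("EW", L=32.0, M=8)
        g = np.geomspace(0.1, 10, 12)
        e1 = sample_tagged(ms, g, n=16, seed=5)
        e2 = sample_tagged(ms, g, n=16, seed=5)
        assert np.array_equal(e1.positions, e2.positions)

    def test_single_mode_ou_statistics(self):
        lam = 0.7
        ms = ModeSystem(np.array([lam]), np.array([1.0]), T=1.0)
        grid = np.array([1.0, 1.0 + 1.5])
        ens = sample_tagged(ms, grid, n=60000, seed=8)
        # displacement x(t)-x(0) of a stationary OU mode:
        # Var = 2(1 - e^{-lam t})/lam
        x = ens.positions[:, :, 0]
        v_ref = 2 * (1 - np.exp(-lam * grid)) / lam
        assert np.allclose(np.var(x, axis=0), v_ref, rtol=0.03)
        # fourth moment Gaussian: kurtosis 3
        k = np.mean(x[:, 1] ** 4) / np.var(x[:, 1]) ** 2
        assert k == pytest.approx(3.0, abs=0.12)

    def test_quench_two_time_covariance_matches_scaling_form(self):
        """Deterministic check: the mode-sum two-time covariance of a
        quenched interface matches the normalized quench covariance in
        the scaling window to < 5% after a single amplitude fit."""
        for T in (0.0, 2.0):
            ms = interface_modes("MH", L=512.0, T=T)
            lo, hi = scaling_window(ms)
            t = np.geomspace(10 * lo, hi / 10, 8)
            pairs = [(a, b) for a in t for b in t if b <= a]
            num = np.array([cov_from_modes(ms, a, b) for a, b in pairs])
            ref = np.array([sigma_quench(a, b, H=0.375, T=T)
                            for a, b in pairs])
            amp = np.dot(num, ref) / np.dot(ref, ref)
            assert np.max(np.abs(num - amp * ref) / np.max(num)) < 0.05

    def test_msd_mode_sum_vs_ensemble(self):
        ms = network_modes(rouse_chain(64), T=0.0)
        grid = np.geomspace(0.5, 50, 10)
        ens = sample_tagged(ms, grid, n=4000, seed=2)
        ref = msd_from_modes(ms, grid)
        est = np.var(ens.positions[:, :, 0], axis=0)
        se = ref * np.sqrt(2.0 / 4000)
        assert np.all(np.abs(est - ref) < 5 * se + 1e-12)


class TestGaussianSampler:
    def test_sample_covariance_matches_target(self):
        spec = CovarianceSpec(H=0.375, kind="quench", T=0.0)
        grid = np.geomspace(0.1, 50, 48)
        ens = sample_gaussian(spec, grid, n=6000, seed=11)
        C = np.cov(ens.positions[:, :, 0].T)
        ref = spec.matrix(grid)
        scale = np.sqrt(np.outer(np.diag(ref), np.diag(ref)))
        err = (C - ref) / scale
        assert np.max(np.abs(err)) < 5 * np.sqrt(2.0 / 6000) * 3

    def test_brownian_increments_are_independent(self):
        spec = CovarianceSpec(H=0.5, kind="quench", T=2.0)
        grid = np.linspace(1.0, 33.0, 33)
        ens = sample_gaussian(spec, grid, n=8000, seed=12)
        inc = np.diff(ens.positions[:, :, 0], axis=1)
        corr = np.corrcoef(inc[:, :-1].ravel(), inc[:, 1:].ravel())[0, 1]
        assert abs(corr) < 0.02

    def test_conditioned_mean_reproduced(self):
        past = PastObservation.geometric(H=0.7, T_past=50.0, n=60, seed=3)
        cm = condition_on_past(past, np.geomspace(0.2, 5.0, 12))
        ens = sample_gaussian(cm, n=6000, seed=13)
        est = ens.positions[:, :, 0].mean(axis=0)
        sd = np.sqrt(np.diag(cm.cov) / 6000)
        assert np.all(np.abs(est - cm.mean) < 5 * sd + 1e-9)

    def test_d_components_independent_and_identical(self):
        spec = CovarianceSpec(H=0.375, kind="quench", T=0.0, d=2)
        grid = np.geomspace(0.1, 10, 16)
        ens = sample_gaussian(spec, grid, n=5000, seed=14)
        x, y = ens.positions[:, -1, 0], ens.positions[:, -1, 1]
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.05
        assert np.var(x) == pytest.approx(np.var(y), rel=0.15)
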