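"""Survival curves, exponent fits, and post-first-passage statistics."""

import numpy as np
import pytest

from quenchfp import (CovarianceSpec, TargetSpec, SurvivalCurve,
                      first_passage, survival, fit_theta,
                      post_fpt_statistics, empirical_z,
                      conditional_persistence, PastObservation,
                      sample_gaussian)
from quenchfp.simulate import TrajectoryEnsemble


class TestFirstPassage:
    def test_monotone_escape_is_censored(self):
        grid = np.linspace(1.0, 10.0, 10)
        # one trajectory drifting away from the threshold, one crossing
        x = np.stack([-np.linspace(0, 9, 10), np.linspace(0, 9, 10)])
        ens = TrajectoryEnsemble(grid, x.copy())
        fpt, cen = first_passage(ens, TargetSpec(d=1, b=5.0), bridge=False)
        assert cen[0] and not cen[1]
        # linear path from 0 to 9: crosses 5 at t = 1 + 5
        assert fpt[1] == pytest.approx(6.0)

    def test_all_censored_raises(self):
        grid = np.linspace(1.0, 5.0, 5)
        x = -np.ones((4, 5))
        ens = TrajectoryEnsemble(grid, x)
        with pytest.raises(RuntimeError):
            first_passage(ens, TargetSpec(d=1, b=2.0), bridge=False)

    def test_grid_refinement_bias_bounded(self):
        """Doubling the grid density changes the median Brownian FPT by
        only a few percent (the bridge correction removes most of the
        undershoot; the residual includes Monte Carlo scatter)."""
        spec = CovarianceSpec(H=0.5, kind="quench", T=1.0)
        med = {}
        for nt in (300, 600):
            grid = np.geomspace(0.02, 200.0, nt)
            ens = sample_gaussian(spec, grid, n=12000, seed=21)
            fpt, cen = first_passage(ens, TargetSpec(d=1, b=1.0), seed=4)
            med[nt] = np.median(fpt[~cen])
        assert abs(med[600] - med[300]) / med[600] < 0.04

    def test_d2_radial_entry(self):
        grid = np.linspace(1.0, 3.0, 3)
        # walker starts at (1, 0) relative to the target at the origin;
        # moves straight at it in one trajectory
        x = np.zeros((1, 3, 2))
        x[0, :, 0] = [0.0, -0.5, -0.95]
        ens = TrajectoryEnsemble(grid, x)
        fpt, cen = first_passage(ens, TargetSpec(d=2, a=0.2, x0=1.0),
                                 bridge=False)
        assert not cen[0] and 2.0 < fpt[0] <= 3.0


class TestSurvivalAndFit:
    def test_survival_monotone_normalized(self, brownian_ensemble):
        ens, _ = brownian_ensemble
        fpt, cen = first_passage(ens, TargetSpec(d=1, b=0.5), seed=5)
        cv = survival(fpt, cen)
        assert np.all(np.diff(cv.S) <= 1e-12)
        assert cv.S[0] <= 1.0 and np.all(cv.S >= 0)

    def test_fitter_identity_on_exact_power_law(self):
        t = np.geomspace(1.0, 1e4, 200)
        curve = SurvivalCurve(times=t, S=t**-0.7,
                              n_at_risk=np.full(200, 10**6),
                              censor_time=1e6)
        theta, err, _ = fit_theta(curve, window=(1.0, 1e4))
        assert theta == pytest.approx(0.7, abs=1e-6)

    def test_brownian_theta(self, brownian_ensemble):
        ens, _ = brownian_ensemble
        fpt, cen = first_passage(ens, TargetSpec(d=1, b=0.5), seed=5)
        theta, errb, _ = fit_theta(survival(fpt, cen), fpt=fpt,
                                   censored=cen, n_boot=80, seed=6)
        assert theta == pytest.approx(0.5, abs=max(0.04, 3 * errb))

    def test_threshold_invariance(self, fbm_ensemble):
        """The exponent does not depend on the threshold level."""
        ens, _ = fbm_ensemble
        out = {}
        for b in (0.5, 1.0):
            fpt, cen = first_passage(ens, TargetSpec(d=1, b=b), seed=7)
            out[b] = fit_theta(survival(fpt, cen), fpt=fpt, censored=cen,
                               n_boot=60, seed=8)
        th1, e1, _ = out[0.5]
        th2, e2, _ = out[1.0]
        assert abs(th1 - th2) < 2.5 * np.hypot(e1, e2) + 0.02

    def test_compact_censoring_vanishes_with_horizon(self):
        spec = CovarianceSpec(H=0.375, kind="quench", T=0.0, d=2)
        cen_frac = {}
        for tmax in (200.0, 4000.0):
            grid = np.geomspace(0.05, tmax, 300)
            ens = sample_gaussian(spec, grid, n=3000, seed=22)
            _, cen = first_passage(ens, TargetSpec(d=2, a=0.3, x0=1.0),
                                   seed=9)
            cen_frac[tmax] = cen.mean()
        assert cen_frac[4000.0] < cen_frac[200.0]


class TestPostFPT:
    def test_post_fpt_diagonal_growth_and_scaling(self, fbm_ensemble):
        """The covariance excess of trajectories after the FPT grows as
        t^{2H-theta}; its implied exponent is consistent with the
        survival-curve exponent at loose (sampling-limited) tolerance."""
        ens, spec = fbm_ensemble
        fpt, cen = first_passage(ens, TargetSpec(d=1, b=0.5), seed=5)
        est = post_fpt_statistics(ens, fpt, cen,
                                  times=np.geomspace(0.2, 60.0, 30))
        u, zhat, theta_pi = empirical_z(est, spec, theta=0.625)
        # diagonal excess is nonzero and z-hat is bounded (no blow-up)
        assert np.isfinite(zhat).all()
        finite_small = np.abs(zhat[u < 0.05])
        assert np.median(finite_small) < 10 * np.median(np.abs(zhat))
        if np.isfinite(theta_pi):
            assert abs(theta_pi - 0.625) < 0.35

    def test_insufficient_paths_raises(self):
        grid = np.linspace(1, 10, 10)
        ens = TrajectoryEnsemble(grid, np.random.default_rng(0)
                                 .normal(size=(20, 10)))
        with pytest.raises(RuntimeError):
            post_fpt_statistics(ens, np.full(20, 1.0),
                                np.zeros(20, dtype=bool))


class TestConditionalPersistence:
    def test_markov_case(self):
        """At H = 1/2 the observation of the past is irrelevant and the
        crossing of the predicted mean has the Brownian exponent."""
        past = PastObservation.geometric(H=0.5, T_past=200.0, n=80, seed=31)
        grid = np.geomspace(0.02, 500.0, 300)
        th, err, _ = conditional_persistence(past, grid, n=6000, seed=32)
        assert th == pytest.approx(0.5, abs=max(0.06, 3 * err))

    def test_independent_of_past_realization(self):
        """theta_II depends on the fact of observation, not on the
        particular observed trajectory."""
        grid = np.geomspace(0.02, 200.0, 250)
        out = []
        for seed in (41, 42):
            past = PastObservation.geometric(H=0.65, T_past=500.0, n=100,
                                             seed=seed)
            out.append(conditional_persistence(past, grid, n=5000,
                                               seed=seed + 10))
        (t1, e1, _), (t2, e2, _) = out
        assert abs(t1 - t2) < 2.5 * np.hypot(e1, e2) + 0.03
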