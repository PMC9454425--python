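"""Sliding-mode and synergetic drug laws and their stability certificates."""

import math

import numpy as np
import pytest

from tumorctl import (
    DoseSchedule,
    ModelParams,
    SCConfig,
    SMCConfig,
    SystemState,
    integrate,
    lyapunov_closed_form,
    lyapunov_value,
    reaching_margin,
    sc_closed_form_x2,
    sc_control,
    sc_macro_variable,
    sliding_surface,
    smc_control,
    smc_gain_rho,
    tumor_rhs,
)
from tumorctl.fixtures import generate_fixture

from conftest import random_params


class TestSlidingSurface:
    def test_initial_state_value(self):
        st = SystemState(0, 0.9, 0.25, 0.25, 0.0)
        assert sliding_surface(st, SMCConfig(m1=1.0)) == pytest.approx(0.5)

    def test_origin_is_on_surface(self):
        assert sliding_surface(SystemState(0, 0.5, 0.0, 0.0, 0.0), SMCConfig()) == 0.0

    def test_linearity(self):
        cfg = SMCConfig(m1=2.0)
        a = sliding_surface(SystemState(0, 0, 0.1, 0.2, 0), cfg)
        b = sliding_surface(SystemState(0, 0, 0.3, 0.1, 0), cfg)
        ab = sliding_surface(SystemState(0, 0, 0.4, 0.3, 0), cfg)
        assert ab == pytest.approx(a + b)


class TestSwitchingGain:
    def test_empty_state_reduces_to_immune_influx(self, params):
        st = SystemState(0, 0, 0, 0, 0)
        cfg = SMCConfig(m1=1.0, eta=0.0)
        assert smc_gain_rho(st, params, cfg) == pytest.approx(params.alpha)

    def test_nondecreasing_in_eta(self, params):
        st = SystemState(0, 0.9, 0.25, 0.25, 0.5)
        lo = smc_gain_rho(st, params, SMCConfig(eta=0.0))
        hi = smc_gain_rho(st, params, SMCConfig(eta=0.4))
        assert hi == pytest.approx(lo + 0.4)

    def test_nonnegative_on_random_states(self, params):
        for st in generate_fixture("random_state_sweep", 3, count=200):
            assert smc_gain_rho(st, params, SMCConfig()) >= 0.0


class TestSMCControl:
    def test_zero_surface_zero_partial_gives_zero(self, params):
        st = SystemState(0, 0.5, 0.0, 0.0, 0.0)
        cfg = SMCConfig(partial=0.0, smoothing_width=0.0)
        assert smc_control(st, params, cfg) == 0.0

    def test_drug_law_composition(self):
        p = ModelParams(d1=1.0, a1=1.7)
        st = SystemState(0, 0.5, 0.25, 0.3, 0.0)
        cfg = SMCConfig(partial=1.0, smoothing_width=0.0)
        rho = smc_gain_rho(st, p, cfg)
        # sigma > 0 so the sign term contributes -rho
        assert smc_control(st, p, cfg) == pytest.approx(-rho - 1.7 * 0.25 * 0.75)

    def test_closed_loop_structural_identity(self, params):
        # mu substituted into the cancer equation leaves the scaled growth term
        cfg = SMCConfig(partial=0.6, smoothing_width=0.0)
        for st in generate_fixture("random_state_sweep", 5, count=100):
            mu = smc_control(st, params, cfg, hard_sign=True)
            dx2 = tumor_rhs(st, params, mu=mu)[1]
            rho = smc_gain_rho(st, params, cfg)
            sigma = sliding_surface(st, cfg)
            sgn = math.copysign(1.0, sigma) if sigma != 0 else 0.0
            expected = ((1 - cfg.partial) * params.a1 * st.x2 * (1 - params.d1 * st.x2)
                        - rho * sgn - params.e2 * st.x3 * st.x2
                        - params.e3 * st.x2 * st.x1 - params.r2 * st.C)
            assert dx2 == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestReachingCondition:
    def test_zero_surface_zero_margin(self, params):
        st = SystemState(0, 0.5, 0.0, 0.0, 0.0)
        assert reaching_margin(st, params, SMCConfig()) == 0.0

    def test_margin_nonpositive_on_random_sweep(self, params):
        cfg = SMCConfig(eta=0.0, smoothing_width=0.0)
        for st in generate_fixture("random_state_sweep", 7, count=1000):
            assert reaching_margin(st, params, cfg) <= 1e-12

    def test_eta_strengthens_the_bound(self, params):
        cfg = SMCConfig(eta=0.5, smoothing_width=0.0)
        for st in generate_fixture("random_state_sweep", 7, count=1000):
            sigma = sliding_surface(st, cfg)
            assert reaching_margin(st, params, cfg) <= -0.5 * abs(sigma) + 1e-9

    def test_surface_attracts_until_tumor_extinction(self, params):
        # hard-sign closed loop: sigma decreases while the clamp is inactive
        traj = integrate(params, DoseSchedule.constant(),
                         SMCConfig(smoothing_width=0.0), horizon=2.0, step=1e-3)
        sigma = traj.x2 + traj.x3
        alive = np.nonzero(traj.x2 > 0.0)[0]
        assert np.all(np.diff(sigma[alive]) <= 1e-9)

    def test_smoothing_converges_to_hard_sign(self):
        # zero immune influx so the boundary layer around sigma=0 is visited
        p = ModelParams(alpha=0.0)
        start = SystemState(0, 0.9, 0.25, 0.0, 0.0)
        hard = integrate(p, DoseSchedule.none(), SMCConfig(smoothing_width=0.0),
                         horizon=3.0, step=1e-3, start=start)
        devs = []
        for w in (0.3, 0.1, 0.03, 0.01, 0.003):
            tr = integrate(p, DoseSchedule.none(), SMCConfig(smoothing_width=w),
                           horizon=3.0, step=1e-3, start=start)
            devs.append(float(np.max(np.abs(tr.x2 - hard.x2))))
        assert all(a >= b for a, b in zip(devs, devs[1:]))
        assert devs[-1] < 1e-3


class TestSynergetic:
    def test_macro_variable_examples(self):
        assert sc_macro_variable(SystemState(0, 0, 0.25, 0, 0),
                                 SCConfig(m2=1.0)) == pytest.approx(0.25)
        assert sc_macro_variable(SystemState(0, 0, 0.0, 0, 0), SCConfig()) == 0.0
        assert sc_macro_variable(SystemState(0, 0, 0.25, 0, 0),
                                 SCConfig(m2=3.0)) == pytest.approx(0.75)

    def test_control_cancels_model_terms(self, params, rng):
        cfg = SCConfig(tau_a=0.05)
        for st in generate_fixture("random_state_sweep", 9, count=100):
            mu = sc_control(st, params, cfg)
            dx2 = tumor_rhs(st, params, mu=mu)[1]
            assert dx2 == pytest.approx(-st.x2 / cfg.tau_a, rel=1e-10, abs=1e-10)

    def test_closed_loop_decay_rate_at_initial_state(self, params):
        st = SystemState(0, 0.9, 0.25, 0.25, 0.0)
        mu = sc_control(st, params, SCConfig(tau_a=0.01))
        assert tumor_rhs(st, params, mu=mu)[1] == pytest.approx(-25.0)

    def test_control_vanishes_at_origin(self, params):
        st = SystemState(0, 0.0, 0.0, 0.0, 0.0)
        assert sc_control(st, params, SCConfig()) == 0.0

    def test_closed_form_examples(self):
        assert sc_closed_form_x2(0.0, 0.25, 0.01) == pytest.approx(0.25)
        tau = 0.04
        assert sc_closed_form_x2(tau * math.log(2), 0.25, tau) == pytest.approx(0.125)
        assert sc_closed_form_x2(20 * tau, 0.25, tau) == pytest.approx(
            0.25 * math.exp(-20), rel=1e-12)

    def test_integrated_tumor_matches_closed_form_any_params(self, rng):
        # the drug law cancels every model term: exactness is parameter-free
        for _ in range(5):
            p = random_params(rng)
            traj = integrate(p, DoseSchedule.constant(), SCConfig(tau_a=0.1),
                             horizon=2.0, step=1e-3)
            exact = 0.25 * np.exp(-traj.times / 0.1)
            assert np.max(np.abs(traj.x2 - exact) / exact) < 1e-6


class TestLyapunov:
    def test_quadratic_value(self):
        assert lyapunov_value(0.25) == pytest.approx(0.03125)

    def test_decay_along_simulated_closed_loop(self, params):
        cfg = SCConfig(tau_a=0.1)
        traj = integrate(params, DoseSchedule.constant(), cfg, horizon=1.0, step=1e-3)
        L = 0.5 * (cfg.m2 * traj.x2) ** 2
        assert np.all(np.diff(L) <= 1e-15)
        expected = lyapunov_closed_form(traj.times[-1], L[0], cfg.tau_a)
        assert L[-1] == pytest.approx(expected, rel=1e-4)

    def test_closed_form_matches_simulation_pointwise(self, params):
        cfg = SCConfig(tau_a=0.1)
        traj = integrate(params, DoseSchedule.constant(), cfg, horizon=1.0, step=1e-3)
        L = 0.5 * (cfg.m2 * traj.x2) ** 2
        expected = np.array([lyapunov_closed_form(t, L[0], cfg.tau_a)
                             for t in traj.times])
        assert np.max(np.abs(L - expected) / expected) < 1e-4


class TestConfigValidation:
    def test_partial_bounds(self):
        with pytest.raises(ValueError):
            SMCConfig(partial=1.2)

    def test_m1_positive(self):
        with pytest.raises(ValueError):
            SMCConfig(m1=0.0)

    def test_sc_positivity(self):
        with pytest.raises(ValueError):
            SCConfig(tau_a=0.0)
        with pytest.raises(ValueError):
            SCConfig(m2=-1.0)
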