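"""Benchmark system registry, right-hand sides and integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fgpgm
from fgpgm.systems import system_from_config

ALL_SYSTEMS = [
    "lotka_volterra",
    "fitzhugh_nagumo",
    "protein_transduction",
    "indirect_exp",
]

SPANS = {
    "lotka_volterra": 2.0,
    "fitzhugh_nagumo": 10.0,
    "protein_transduction": 100.0,
    "indirect_exp": 5.0,
}


class TestRegistry:
    def test_printed_truth_values(self):
        pt = fgpgm.registry_get("protein_transduction")
        assert pt.default_initial_state == (1.0, 0.0, 1.0, 0.0, 0.0)
        assert pt.default_true_params == (0.07, 0.6, 0.05, 0.3, 0.017, 0.3)
        lv = fgpgm.registry_get("lotka_volterra")
        assert lv.default_true_params == (2.0, 1.0, 4.0, 1.0)
        assert lv.default_initial_state == (5.0, 3.0)

    def test_unknown_name_is_lookup_error(self):
        with pytest.raises(KeyError, match="lotka_volterra"):
            fgpgm.registry_get("foo")

    @pytest.mark.parametrize("name", ALL_SYSTEMS)
    def test_truth_inside_domain(self, name):
        sy = fgpgm.registry_get(name)
        assert fgpgm.in_domain(sy, sy.default_true_params)


class TestEvaluateRhs:
    def test_lv_hand_arithmetic(self):
        lv = fgpgm.registry_get("lotka_volterra")
        out = fgpgm.evaluate_rhs(lv, (5, 3), (2, 1, 4, 1))
        # 2*5 - 1*5*3 = -5 ; -4*3 + 1*5*3 = 3
        np.testing.assert_allclose(out, [-5.0, 3.0])

    def test_fhn_standard_form(self):
        # c(x1 - x1^3/3 + x2) and -(x1 - a + b x2)/c at the resting origin
        fhn = fgpgm.registry_get("fitzhugh_nagumo")
        out = fgpgm.evaluate_rhs(fhn, (0.0, 0.0), (0.2, 0.2, 3.0))
        np.testing.assert_allclose(out, [0.0, 0.2 / 3.0])

    @given(
        x=st.lists(st.floats(-2, 2), min_size=5, max_size=5),
        th=st.lists(st.floats(0.01, 2), min_size=6, max_size=6),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_protein_mass_conservation_rows(self, x, th):
        pt = fgpgm.registry_get("protein_transduction")
        out = fgpgm.evaluate_rhs(pt, np.abs(x), th)
        assert abs(out[2] + out[3] + out[4]) < 1e-12

    def test_vectorized_call_matches_scalar(self):
        lv = fgpgm.registry_get("lotka_volterra")
        X = np.array([[5.0, 3.0], [1.0, 2.0], [0.5, 0.1]])
        batch = fgpgm.evaluate_rhs(lv, X, (2, 1, 4, 1))
        for row, fx in zip(X, batch):
            np.testing.assert_allclose(fgpgm.evaluate_rhs(lv, row, (2, 1, 4, 1)), fx)

    def test_contract_errors(self):
        lv = fgpgm.registry_get("lotka_volterra")
        with pytest.raises(ValueError, match="components"):
            fgpgm.evaluate_rhs(lv, (1, 2, 3), (2, 1, 4, 1))
        with pytest.raises(ValueError, match="domain"):
            fgpgm.evaluate_rhs(lv, (1, 2), (-1, 1, 4, 1))


class TestIntegrate:
    @pytest.mark.parametrize("name", ALL_SYSTEMS)
    def test_initial_row_identity(self, name):
        sy = fgpgm.registry_get(name)
        tt = np.linspace(0, SPANS[name], 7)
        traj = fgpgm.integrate(sy, sy.default_true_params,
                               sy.default_initial_state, tt)
        np.testing.assert_array_equal(traj[0], sy.default_initial_state)

    def test_protein_conservation(self, protein_system):
        tt = np.linspace(0, 100, 200)
        traj = fgpgm.integrate(protein_system,
                               protein_system.default_true_params,
                               protein_system.default_initial_state, tt)
        assert np.max(np.abs(traj[:, 2:].sum(axis=1) - 1.0)) < 1e-6

    def test_lv_against_tolerance_halving_oracle(self, lv_system):
        # reference by tightening until the endpoint is stable to 8 digits
        tt = np.array([0.0, 2.0])
        prev = None
        rtol = 1e-6
        while True:
            cur = fgpgm.integrate(
                lv_system, (2, 1, 4, 1), (5, 3), tt,
                fgpgm.SolverConfig("rk45", rtol=rtol, atol=rtol * 1e-2),
            )[-1]
            if prev is not None and np.all(
                np.abs(cur - prev) <= 1e-8 * np.maximum(np.abs(cur), 1)
            ):
                break
            prev, rtol = cur, rtol / 10
            assert rtol > 1e-14, "oracle failed to stabilize"
        default = fgpgm.integrate(lv_system, (2, 1, 4, 1), (5, 3), tt)[-1]
        np.testing.assert_allclose(default, cur, rtol=1e-6)

    @pytest.mark.parametrize("name", ALL_SYSTEMS)
    def test_tolerance_tightening_convergence(self, name):
        sy = fgpgm.registry_get(name)
        tt = np.linspace(0, SPANS[name], 20)
        base = fgpgm.SolverConfig("rk45", rtol=1e-7, atol=1e-9)
        a = fgpgm.integrate(sy, sy.default_true_params, sy.default_initial_state,
                            tt, base)
        b = fgpgm.integrate(sy, sy.default_true_params, sy.default_initial_state,
                            tt, base.tightened(10))
        scale = np.max(np.abs(a), axis=0)
        assert np.max(np.abs(a - b) / scale) < 1e-5

    def test_rhs_consistent_with_trajectory_slope(self, lv_system):
        tt = np.linspace(0, 2, 2001)
        traj = fgpgm.integrate(lv_system, (2, 1, 4, 1), (5, 3), tt)
        slope = np.gradient(traj, tt, axis=0)
        f = lv_system.rhs(traj, np.array([2.0, 1, 4, 1]), tt)
        assert np.max(np.abs(slope[1:-1] - f[1:-1])) < 5e-4

    def test_fixed_step_rk4_matches_rk45(self, fhn_system):
        tt = np.linspace(0, 10, 30)
        a = fgpgm.integrate(fhn_system, (0.2, 0.2, 3), (-1, 1), tt,
                            fgpgm.SolverConfig("rk4", n_steps=2000))
        b = fgpgm.integrate(fhn_system, (0.2, 0.2, 3), (-1, 1), tt)
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_non_monotone_times_rejected(self, lv_system):
        with pytest.raises(ValueError, match="increasing"):
            fgpgm.integrate(lv_system, (2, 1, 4, 1), (5, 3), [0.0, 1.0, 0.5])

    def test_blowup_raises_integration_error(self):
        sy = system_from_config({
            "name": "explode", "states": ["u"], "params": ["a"],
            "rhs": {"u": "a*u*u"}, "initial_state": [1.0], "true_params": [1.0],
        })
        with pytest.raises(fgpgm.IntegrationError):
            fgpgm.integrate(sy, [1.0], [1.0], np.linspace(0, 5, 10),
                            fgpgm.SolverConfig("rk4", n_steps=2000))


class TestUserDefinedSystems:
    def test_expression_clone_matches_builtin(self, lv_system):
        clone = system_from_config({
            "name": "lv_clone",
            "states": ["x1", "x2"],
            "params": ["a", "b", "c", "d"],
            "rhs": {
                "x1": "a*x1 - b*x1*x2",
                "x2": "-c*x2 + d*x1*x2",
            },
            "domain": {"a": [0, 100], "b": [0, 100], "c": [0, 100], "d": [0, 100]},
        })
        X = np.array([[5.0, 3.0], [0.3, 2.2]])
        th = np.array([2.0, 1.0, 4.0, 1.0])
        np.testing.assert_allclose(clone.rhs(X, th, 0.0), lv_system.rhs(X, th, 0.0))

    def test_power_and_exp_grammar(self):
        sy = system_from_config({
            "name": "g", "states": ["u"], "params": ["k"],
            "rhs": {"u": "exp(-k*u^2) + 1"},
        })
        out = sy.rhs(np.array([2.0]), np.array([0.5]), 0.0)
        np.testing.assert_allclose(out, [np.exp(-2.0) + 1])

    def test_unsafe_expression_rejected(self):
        with pytest.raises(ValueError, match="allowed|unknown identifier"):
            system_from_config({
                "name": "bad", "states": ["u"], "params": [],
                "rhs": {"u": "__import__('os').system('true')"},
            })
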