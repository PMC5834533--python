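import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fhnring.controller import (
    ControllerConfig,
    EstimateState,
    RegressorBundle,
    SyncErrors,
    adaptation_nominal,
    adaptation_robust,
    build_regressors,
    compute_sync_errors,
    control_inputs,
    true_parameter_vector,
)
from fhnring.model import InvalidParameterError, network_rhs
from fhnring.verification import regressor_identity_check


class TestSyncErrors:
    def test_identical_states_give_zero_errors(self):
        s = np.tile([0.3, -0.2, 1.0], 4)[:12]
        s = np.concatenate([np.full(4, 0.3), np.full(4, -0.2), np.full(4, 1.0)])
        e = compute_sync_errors(s)
        assert np.all(e.ex == 0.0) and np.all(e.ey == 0.0)

    def test_hand_subtraction(self):
        s = np.concatenate([[0.2, 0.1, 0.3, 0.2], np.zeros(8)])
        e = compute_sync_errors(s)
        assert np.allclose(e.ex, [0.1, -0.1, 0.0])
        assert np.allclose(e.ey, 0.0)


class TestRegressors:
    def test_zero_state_leaves_constant_entries(self, network):
        s = np.zeros(12)
        for ch in (1, 2, 3):
            reg = build_regressors(s, network, 0.0, ch)
            assert np.allclose(reg.gamma, [0, 0, 0, 0, -1, 1, 0, 0])
            assert np.allclose(reg.upsilon, 0.0)
            assert reg.F == 0.0

    def test_identical_states_kill_offset_and_coupling_entries(self, network):
        s = np.concatenate([np.full(4, 0.4), np.zeros(4), np.full(4, 2.0)])
        for ch in (1, 2, 3):
            reg = build_regressors(s, network, 0.0, ch)
            assert reg.F == 0.0
            assert reg.gamma[6] == 0.0 and reg.gamma[7] == 0.0

    def test_invalid_channel_rejected(self, network):
        with pytest.raises(InvalidParameterError):
            build_regressors(np.zeros(12), network, 0.0, 4)

    def test_identity_against_direct_error_derivatives(self, network):
        """Factorized error dynamics reproduce the direct state differences
        (the module's master oracle)."""
        assert regressor_identity_check(n_states=200, seed=7, network=network) < 1e-10


class TestTrueParameters:
    def test_study_values_channel_1(self, network):
        pv = true_parameter_vector(network, np.zeros(4), 1)
        assert np.allclose(pv.phi, [10, 10.2, 1, 1.01, 0, 0, 0.001, 0.002])
        assert np.allclose(pv.psi, [1, 1.01])

    def test_study_values_channel_3(self, network):
        pv = true_parameter_vector(network, np.zeros(4), 3)
        assert np.allclose(pv.phi, [10, 10.6, 1, 1.03, 0, 0, 0.001, 0.004])
        assert np.allclose(pv.psi, [1, 1.03])

    def test_y0_entries_carried(self, network):
        pv = true_parameter_vector(network, [0.5, -0.25, 0.0, 0.75], 2)
        assert pv.phi[4] == 0.5 and pv.phi[5] == 0.0


def _zero_regs():
    return [
        RegressorBundle(np.zeros(8), np.zeros(2), 0.0, 0.0) for _ in range(3)
    ]


class TestControlInputs:
    def test_all_zero_in_gives_zero_out(self):
        cfg = ControllerConfig()
        errors = SyncErrors(np.zeros(3), np.zeros(3))
        ux, uy = control_inputs(errors, _zero_regs(), EstimateState.zeros(), cfg)
        assert np.all(ux == 0.0) and np.all(uy == 0.0)

    def test_hand_dot_product(self):
        cfg = ControllerConfig(K=(20.0, 20.0, 20.0))
        gamma = np.array([0, 0, 0, 0, -1.0, 1.0, 0, 0])
        regs = _zero_regs()
        regs[0] = RegressorBundle(gamma, np.zeros(2), 0.0, 0.0)
        est = EstimateState.zeros()
        est.phi_hat[0, 4] = 2.0
        est.phi_hat[0, 5] = 3.0
        errors = SyncErrors(np.array([0.1, 0.0, 0.0]), np.zeros(3))
        ux, uy = control_inputs(errors, regs, est, cfg)
        assert ux[0] == pytest.approx(3.0)

    def test_recovery_offset_adds_to_ux_only(self):
        cfg = ControllerConfig()
        errors = SyncErrors(np.zeros(3), np.zeros(3))
        ux, uy = control_inputs(errors, _zero_regs(), EstimateState.zeros(), cfg,
                                recovery_offsets=[1.0, -2.0, 0.5])
        assert np.allclose(ux, [1.0, -2.0, 0.5])
        assert np.all(uy == 0.0)


class TestAdaptationLaws:
    def test_zero_errors_freeze_estimates(self):
        cfg = ControllerConfig()
        errors = SyncErrors(np.zeros(3), np.zeros(3))
        dphi, dpsi = adaptation_nominal(errors, _zero_regs(), cfg)
        assert np.all(dphi == 0.0) and np.all(dpsi == 0.0)
        est = EstimateState(np.ones((3, 8)), np.ones((3, 2)))
        dphi, dpsi = adaptation_robust(errors, _zero_regs(), est, cfg)
        assert np.all(dphi == 0.0) and np.all(dpsi == 0.0)

    def test_nominal_hand_scaling(self):
        cfg = ControllerConfig(p=1.0, q=1.0, l=1.0, m=1.0)
        gamma = np.array([0, 0, 0, 0, -1.0, 1.0, 0, 0])
        regs = _zero_regs()
        regs[0] = RegressorBundle(gamma, np.zeros(2), 0.0, 0.0)
        errors = SyncErrors(np.array([0.5, 0, 0]), np.zeros(3))
        dphi, _ = adaptation_nominal(errors, regs, cfg)
        assert np.allclose(dphi[0], [0, 0, 0, 0, -0.5, 0.5, 0, 0])

    @given(st.floats(0.1, 10))
    @settings(derandomize=True, max_examples=25)
    def test_nominal_is_linear_in_p(self, scale):
        base = ControllerConfig(p=1.0)
        scaled = ControllerConfig(p=scale)
        gamma = np.linspace(-1, 1, 8)
        regs = [RegressorBundle(gamma, np.array([0.3, -0.4]), 0.0, 0.0)] * 3
        errors = SyncErrors(np.array([0.2, -0.1, 0.05]), np.array([0.1, 0.0, -0.3]))
        d1, _ = adaptation_nominal(errors, regs, base)
        d2, _ = adaptation_nominal(errors, regs, scaled)
        assert np.allclose(d2, scale * d1)

    def test_robust_reduces_to_nominal_without_leakage(self, rng):
        cfg = ControllerConfig(kc=0.0)
        regs = [
            RegressorBundle(rng.normal(size=8), rng.normal(size=2), 0.0, 0.0)
            for _ in range(3)
        ]
        errors = SyncErrors(rng.normal(size=3), rng.normal(size=3))
        est = EstimateState(rng.normal(size=(3, 8)), rng.normal(size=(3, 2)))
        dn = adaptation_nominal(errors, regs, cfg)
        dr = adaptation_robust(errors, regs, est, cfg)
        assert np.allclose(dn[0], dr[0]) and np.allclose(dn[1], dr[1])

    def test_leakage_hand_value(self):
        cfg = ControllerConfig(p=1.0, q=1.0, kc=5.0)
        est = EstimateState.zeros()
        est.phi_hat[0, 0] = 1.0
        errors = SyncErrors(np.array([0.1, 0, 0]), np.zeros(3))
        dphi, _ = adaptation_robust(errors, _zero_regs(), est, cfg)
        assert dphi[0, 0] == pytest.approx(-0.5)

    def test_signed_leakage_flips_with_error_sign(self):
        cfg = ControllerConfig(kc=5.0, leakage_signed=True)
        est = EstimateState.zeros()
        est.phi_hat[0, 0] = 1.0
        plus = SyncErrors(np.array([0.1, 0, 0]), np.zeros(3))
        minus = SyncErrors(np.array([-0.1, 0, 0]), np.zeros(3))
        dp, _ = adaptation_robust(plus, _zero_regs(), est, cfg)
        dm, _ = adaptation_robust(minus, _zero_regs(), est, cfg)
        assert dp[0, 0] == pytest.approx(-dm[0, 0])

    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            ControllerConfig(p=0.0)
        with pytest.raises(InvalidParameterError):
            ControllerConfig(m=-1.0)


class TestStabilityValidator:
    def test_violated_gain_condition_warns(self):
        with pytest.warns(UserWarning, match="p\\(K_1\\+1\\)"):
            ControllerConfig(K=(-2.0, 20.0, 20.0))

    def test_study_gains_do_not_warn(self, recwarn):
        ControllerConfig()
        assert not any("stability" in str(w.message) for w in recwarn.list)
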