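"""Structural kinetic model: derivatives, solving, derived quantities."""

import math

import numpy as np
import pytest

from lupsma.model_core import (IndividualParameters, effective_half_life, pk_rhs,
                               renal_clearance, solve_pk, tumor_concentration)
from lupsma.params import LAMBDA_PHYS, PKParameters
from lupsma.simulation import custom_regimen

from conftest import rk4_oracle


def _ip(pk: PKParameters, n_cycles: int = 4, tv: float = 0.0443) -> IndividualParameters:
    return IndividualParameters(pk_by_cycle=[pk] * n_cycles, tumor_volume=tv)


class TestPkRhs:
    def test_closed_system_has_zero_derivatives(self):
        p = PKParameters(**{k: 0.0 for k in PKParameters.RATE_NAMES})
        state = np.array([100.0, 5.0, 3.0, 2.0, 50.0, 0.0, 140.0])
        assert np.allclose(pk_rhs(state, p, decay_mode="corrected"), 0.0)

    def test_saturation_linear_limit(self):
        """With B_MAX → ∞ the salivary flux reduces to k12·A1 − k21·A2."""
        p = PKParameters(B_MAX_sal=1e12)
        state = np.array([5000.0, 40.0, 10.0, 5.0, 900.0, 0.0, 140.0])
        d = pk_rhs(state, p, decay_mode="corrected")
        expected_dA2 = p.k12 * state[0] - p.k21 * state[1]
        assert d[1] == pytest.approx(expected_dA2, rel=1e-9)

    def test_saturation_slows_uptake(self):
        p = PKParameters()
        empty = pk_rhs(np.array([1000.0, 0, 0, 0, 0, 0, 1]), p)
        halffull = pk_rhs(np.array([1000.0, 67.0, 0, 0, 0, 0, 1]), p)
        assert halffull[1] < empty[1]

    def test_mass_leaves_only_via_k10_and_decay(self):
        p = PKParameters(k10=0.0)
        state = np.array([1000.0, 50.0, 20.0, 10.0, 300.0, 0.0, 140.0])
        d_corr = pk_rhs(state, p, decay_mode="corrected")
        assert d_corr[:5].sum() == pytest.approx(0.0, abs=1e-10)
        d_phys = pk_rhs(state, p, decay_mode="physical")
        assert d_phys[:5].sum() == pytest.approx(-LAMBDA_PHYS * state[:5].sum())

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            pk_rhs(np.array([-1.0, 0, 0, 0, 0, 0, 1]), PKParameters())

    def test_nonpositive_bmax_rejected_at_construction(self):
        with pytest.raises(ValueError, match="B_MAX"):
            PKParameters(B_MAX_sal=0.0)


class TestSolvePk:
    def test_monoexponential_closed_form(self):
        """Only renal elimination: C1(t) = (dose/V1)·exp(−k10·t)."""
        p = PKParameters(**{**{k: 0.0 for k in PKParameters.RATE_NAMES}, "k10": 0.253})
        reg = custom_regimen([0.0], [7400.0])
        t = np.linspace(0.0, 48.0, 25)
        traj = solve_pk(reg, _ip(p), t, decay_mode="corrected")
        c1 = traj.A1 / p.V1
        assert c1[0] == pytest.approx(7400.0 / 10.3, rel=1e-9)
        assert c1[0] == pytest.approx(718.4, abs=0.1)
        assert np.allclose(c1, 718.446601941 * np.exp(-0.253 * t), rtol=1e-7)

    def test_zero_doses_flat(self):
        reg = custom_regimen([], [], horizon=100.0)
        traj = solve_pk(reg, _ip(PKParameters()), np.linspace(0, 100, 11))
        assert np.all(traj.states[:, :5] == 0.0)

    def test_superposition_linear_model(self):
        """Linearized (B_MAX→∞) trajectories superpose across doses."""
        p = PKParameters(B_MAX_sal=1e12)
        t = np.linspace(0.0, 400.0, 81)
        tight = {"rtol": 1e-11, "atol": 1e-13}
        two = solve_pk(custom_regimen([0.0, 48.0], [3700.0, 3700.0]), _ip(p), t,
                       decay_mode="corrected", **tight)
        one = solve_pk(custom_regimen([0.0], [3700.0]), _ip(p), t,
                       decay_mode="corrected", **tight)
        mask = t >= 48.0
        lagged = solve_pk(custom_regimen([0.0], [3700.0]), _ip(p), t[mask] - 48.0,
                          decay_mode="corrected", **tight)
        shifted = np.zeros_like(one.states)
        shifted[mask] = lagged.states
        combined = one.states[:, :5] + shifted[:, :5]
        scale = np.maximum(np.abs(combined), 1e-6)
        assert np.all(np.abs(two.states[:, :5] - combined) / scale < 1e-8)

    def test_salivary_amount_regression_fixture(self):
        """A2 at 24 h after a 7400 MBq bolus, frozen from an independent
        high-accuracy RK4 reference integration (physical decay)."""
        reg = custom_regimen([0.0], [7400.0])
        traj = solve_pk(reg, _ip(PKParameters()), np.array([0.0, 24.0]))
        assert traj.A2[-1] == pytest.approx(31.563109862147606, rel=1e-6)
        assert traj.A4[-1] == pytest.approx(106.41072591484217, rel=1e-6)

    def test_mass_balance_without_excretion(self):
        p = PKParameters(k10=0.0)
        reg = custom_regimen([0.0, 336.0], [7400.0, 7400.0])
        t = np.linspace(0.0, 1000.0, 51)
        traj = solve_pk(reg, _ip(p), t, decay_mode="corrected")
        total = traj.states[:, :5].sum(axis=1)
        expected = np.where(t >= 336.0, 14800.0, 7400.0)
        assert np.allclose(total, expected, rtol=1e-7)

    def test_physical_mode_activity_bounded_and_decaying(self):
        p = PKParameters(k10=0.0)
        reg = custom_regimen([0.0], [7400.0])
        t = np.linspace(0.0, 500.0, 26)
        traj = solve_pk(reg, _ip(p), t, decay_mode="physical")
        total = traj.states[:, :5].sum(axis=1)
        assert np.all(total <= 7400.0 * (1 + 1e-9))
        # with internal transfer only, decay proceeds at exactly lambda
        assert np.allclose(total, 7400.0 * np.exp(-LAMBDA_PHYS * t), rtol=1e-7)

    def test_agrees_with_rk4_oracle_over_week(self):
        """Adaptive solve matches the independent fixed-step oracle to 1e-6."""
        reg = custom_regimen([0.0], [7400.0])
        outs = [24.0, 72.0, 168.0]
        traj = solve_pk(reg, _ip(PKParameters()), np.array(outs))
        oracle = rk4_oracle([(0.0, 7400.0)], [1.0], 168.0, h=0.01, out_times=outs)
        for i, t in enumerate(outs):
            ref = oracle[t][:5]
            got = traj.states[i, :5]
            assert np.all(np.abs(got - ref) / np.maximum(np.abs(ref), 1e-3) < 1e-6)

    def test_nonincreasing_dose_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            custom_regimen([0.0, 0.0], [7400.0, 7400.0])


class TestDerivedQuantities:
    @pytest.mark.parametrize(
        "k, expected, tol",
        [(0.0150, 46.2, 0.05), (0.0629, 11.0, 0.05), (math.log(2), 1.0, 1e-12)],
    )
    def test_effective_half_life(self, k, expected, tol):
        assert effective_half_life(k) == pytest.approx(expected, abs=tol)

    def test_half_life_requires_positive_rate(self):
        with pytest.raises(ValueError):
            effective_half_life(0.0)

    @pytest.mark.parametrize(
        "k10, v1, expected",
        [(0.253, 10.3, 2.606), (0.0, 10.3, 0.0), (1.0, 1.0, 1.0)],
    )
    def test_renal_clearance(self, k10, v1, expected):
        assert renal_clearance(PKParameters(k10=k10, V1=v1)) == pytest.approx(
            expected, abs=0.001)

    def test_tumor_concentration_modes(self):
        assert tumor_concentration(0.0, 0.0443) == 0.0
        assert tumor_concentration(44.3, 0.0443) == pytest.approx(1000.0)
        # one physical half-life of decay correction halves the concentration
        half = tumor_concentration(44.3, 0.0443, t_abs=159.528,
                                   decay_mode="corrected")
        assert half == pytest.approx(500.0, rel=1e-12)
        with pytest.raises(ValueError):
            tumor_concentration(1.0, 0.0)
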