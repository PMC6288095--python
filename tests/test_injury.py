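"""Adaptation/injury ODEs: rates, composition, bounds, and oracles.

The independent oracle for the four saturating states is the closed-form
solution of the linear ODE at constant drive d:

    x(t) = x_max * (1 - exp(-d*t/tau)),   x(0) = 0

and for the sieving integrator the linear ramp x(t) = d*t/tau.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from nephrosim.injury import (InjuryParams, InjuryState, InjurySwitches,
                              afferent_dilatation_rate, compose_K_albumin,
                              compose_Kf, damage_signal, hypertrophy_rate,
                              injury_rates, nephron_loss_rate, sclerosis_rate,
                              sieving_damage)

P = InjuryParams()


class TestDamageSignal:
    def test_at_reference(self):
        assert damage_signal(37.5, 37.5) == 0.0

    def test_twenty_percent_excess(self):
        assert damage_signal(45.0, 37.5) == pytest.approx(0.2)

    def test_no_negative_damage(self):
        assert damage_signal(30.0, 37.5) == 0.0


class TestRates:
    def test_dilatation_zero_at_nominal_glucose(self):
        assert afferent_dilatation_rate(0.1, 90.0, P) == 0.0

    def test_dilatation_zero_at_ceiling(self):
        assert afferent_dilatation_rate(0.25, 500.0, P) == 0.0

    def test_hypertrophy_saturates_at_half(self):
        assert hypertrophy_rate(0.5, 0.3, P) == 0.0
        assert hypertrophy_rate(0.0, 0.0, P) == 0.0

    def test_sclerosis_much_slower_than_hypertrophy(self):
        d = 0.2
        ratio = hypertrophy_rate(0.0, d, P) / (sclerosis_rate(0.0, d, P) / 2)
        # tau_perm/tau_SA = 4e4/750 ~ 53, ceilings 0.5 vs 1.0
        assert ratio == pytest.approx(4e4 / 750, rel=1e-9)

    def test_nephron_loss_saturation(self):
        assert nephron_loss_rate(1.0, 0.5, P) == 0.0

    def test_sieving_is_pure_integrator(self):
        r1, k1 = sieving_damage(0.0, 0.3, P)
        r2, _ = sieving_damage(0.5, 0.3, P)   # rate independent of state
        assert r1 == r2 == pytest.approx(0.3 / P.tau_albumin)
        assert k1 == pytest.approx(6e-4)


class TestComposition:
    @pytest.mark.parametrize("dsa,dperm,expected", [
        (0.0, 0.0, 3.9), (0.5, 0.0, 5.85), (0.5, 1.0, 1.95)])
    def test_compose_kf(self, dsa, dperm, expected):
        assert compose_Kf(3.9, dsa, dperm) == pytest.approx(expected)

    def test_kf_clamped_nonnegative(self):
        assert compose_Kf(3.9, 0.0, 1.0) == 0.0

    def test_sieving_additive(self):
        assert compose_K_albumin(6e-4, 2e-3) == pytest.approx(2.6e-3)


def _integrate(switches, damage, bg, t_end_weeks, rtol=1e-11):
    def rhs(t, y):
        return injury_rates(InjuryState.from_array(y), damage, bg, P,
                            switches)
    sol = solve_ivp(rhs, (0.0, t_end_weeks), np.zeros(5), rtol=rtol,
                    atol=1e-14, dense_output=True)
    return sol.y[:, -1]


class TestClosedFormOracle:
    """Each slow ODE at constant drive matches its exponential/linear
    solution to high accuracy (integrator correctness)."""

    def test_saturating_states(self):
        d, bg, t = 0.25, 500.0, 12.0
        y = _integrate(InjurySwitches(), d, bg, t)
        tu = P.time_unit_weeks
        expected = [
            0.25 * (1 - np.exp(-(bg - 90.0) * t / (P.tau_daa * tu))),
            0.50 * (1 - np.exp(-d * t / (P.tau_sa * tu))),
            1.00 * (1 - np.exp(-d * t / (P.tau_perm * tu))),
            1.00 * (1 - np.exp(-d * t / (P.tau_nephron_loss * tu))),
        ]
        for got, exp in zip(y[:4], expected):
            assert got == pytest.approx(exp, rel=1e-6)

    def test_sieving_linear_ramp(self):
        d, t = 0.4, 10.0
        y = _integrate(InjurySwitches(), d, 90.0, t)
        assert y[4] == pytest.approx(d * t / (P.tau_albumin *
                                              P.time_unit_weeks), rel=1e-6)

    def test_switches_freeze_states(self):
        y = _integrate(InjurySwitches.all_off(), 0.5, 500.0, 10.0)
        assert np.all(y == 0.0)
        y = _integrate(InjurySwitches.adaptive_only(), 0.5, 500.0, 10.0)
        assert y[0] > 0 and y[1] > 0 and np.all(y[2:] == 0.0)


class TestBoundsProperty:
    @given(damages=st.lists(st.floats(0.0, 2.0), min_size=2, max_size=6),
           bg=st.floats(90.0, 600.0))
    @settings(max_examples=25, deadline=None)
    def test_states_respect_bounds_and_monotonicity(self, damages, bg):
        """Piecewise-constant nonnegative damage: every state stays in its
        interval and never decreases (no healing)."""
        y = np.zeros(5)
        prev = y.copy()
        for d in damages:
            def rhs(t, yy):
                return injury_rates(InjuryState.from_array(yy), d, bg, P,
                                    InjurySwitches())
            sol = solve_ivp(rhs, (0.0, 3.0), y, rtol=1e-9, atol=1e-13)
            y = sol.y[:, -1]
            assert np.all(y >= prev - 1e-9)
            prev = y.copy()
            InjuryState.from_array(np.clip(y, 0, None)).validate(P, tol=1e-7)

    def test_validate_rejects_out_of_bounds(self):
        with pytest.raises(ValueError):
            InjuryState(dSA=0.7).validate(P)
        with pytest.raises(ValueError):
            InjuryState(dK_albumin=-0.1).validate(P)


def test_saturation_ordering_under_disease(dbdb_run):
    """Sclerosis lags far behind both adaptive processes: at every time the
    fractional saturation of dilatation and hypertrophy exceeds that of
    permeability loss, and both adaptive states reach 90% of their ceilings
    within the simulation while sclerosis does not."""
    f = dbdb_run.frame[dbdb_run.frame["week"] > 0.5]
    assert np.all(f["dSA"] / 0.5 >= f["dPerm"] / 1.0)
    assert np.all(f["dD_aa"] / 0.25 >= f["dPerm"] / 1.0)
    assert f["dSA"].iloc[-1] / 0.5 > 0.9
    assert f["dD_aa"].iloc[-1] / 0.25 > 0.9
    assert f["dPerm"].iloc[-1] < 0.9
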