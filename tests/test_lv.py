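"""Lotka-Volterra model: derivatives, integration, equilibria, outcomes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lvcoex.lv import (
    DegenerateEquilibriumError,
    LVParams,
    State,
    classify_outcome,
    coexistence_equilibrium,
    derivative,
    simulate,
)

from conftest import logistic_with_dilutions


def sym(a, K=1.0, r=1.0):
    return LVParams(r1=r, r2=r, K1=K, K2=K, a12=a, a21=a)


class TestDerivative:
    @pytest.mark.parametrize(
        "state, params, expected",
        [
            (State(1.0, 0.0), sym(0.5), (0.0, 0.0)),  # carrying-capacity fixed point
            (State(0.0, 0.0), sym(0.5), (0.0, 0.0)),  # extinction fixed point
            (State(0.5, 0.5), sym(0.5), (0.125, 0.125)),  # 0.5*(1 - 0.75)
        ],
    )
    def test_fixed_points_and_hand_value(self, state, params, expected):
        assert derivative(state, params) == pytest.approx(expected, abs=1e-15)

    def test_rejects_invalid_params(self):
        with pytest.raises(ValueError):
            LVParams(r1=-1, r2=1, K1=1, K2=1, a12=0, a21=0)
        with pytest.raises(ValueError):
            LVParams(r1=1, r2=1, K1=1, K2=1, a12=-0.1, a21=0)


class TestSimulate:
    def test_uncoupled_species_match_logistic_closed_form(self):
        p = LVParams(r1=0.8, r2=1.3, K1=2e7, K2=5e7, a12=0.0, a21=0.0)
        t = np.linspace(0, 20, 11)
        traj = simulate(p, State(1e5, 3e5), t)
        for col, (r, K, n0) in enumerate([(0.8, 2e7, 1e5), (1.3, 5e7, 3e5)]):
            expected = K / (1 + (K - n0) / n0 * np.exp(-r * t))
            np.testing.assert_allclose(traj[:, col], expected, rtol=1e-6)

    def test_dilution_events_match_analytic_oracle(self):
        r, K, n0, f = 1.5, 8.44e7, 2.52e5, 0.96
        p = LVParams(r1=r, r2=r, K1=K, K2=K, a12=0.0, a21=0.0)
        days = np.array([1.0, 3.0, 5.0, 8.0, 10.0, 12.0, 15.0])
        traj = simulate(
            p,
            State(n0, 0.0),
            np.concatenate([[0.0], days]),
            dilution_events=[(d, f) for d in days],
            sample_before_events=True,
        )
        oracle = logistic_with_dilutions(r, K, n0, days, days, f)
        np.testing.assert_allclose(traj[1:, 0], oracle, rtol=1e-6)

    def test_dilution_conserves_concentration(self):
        p = sym(0.0, K=1e7, r=1.0)
        pre = simulate(p, State(1e6, 0), [0.0, 5.0], [(5.0, 0.96)], sample_before_events=True)
        post = simulate(p, State(1e6, 0), [0.0, 5.0], [(5.0, 0.96)], sample_before_events=False)
        assert post[1, 0] == pytest.approx(0.96 * pre[1, 0], rel=1e-12)

    def test_neutral_model_conserves_ratio(self):
        p = sym(1.0, K=1e8, r=1.2)
        t = np.linspace(0, 40, 81)
        traj = simulate(p, State(2e5, 1e5), t)
        ratio = traj[:, 0] / traj[:, 1]
        np.testing.assert_allclose(ratio, 2.0, rtol=1e-6)
        assert traj[-1].sum() == pytest.approx(1e8, rel=1e-4)

    def test_zero_length_grid_returns_init(self):
        traj = simulate(sym(0.5), State(0.3, 0.2), [0.0])
        np.testing.assert_array_equal(traj, [[0.3, 0.2]])

    def test_rejects_non_monotone_grid(self):
        with pytest.raises(ValueError):
            simulate(sym(0.5), State(0.1, 0.1), [0.0, 2.0, 1.0])


class TestCoexistenceEquilibrium:
    def test_symmetric_half(self):
        eq = coexistence_equilibrium(sym(0.5))
        assert (eq.N1, eq.N2) == (pytest.approx(2 / 3), pytest.approx(2 / 3))

    def test_no_competition_gives_carrying_capacities(self):
        p = LVParams(r1=1, r2=1, K1=3.0, K2=7.0, a12=0.0, a21=0.0)
        eq = coexistence_equilibrium(p)
        assert (eq.N1, eq.N2) == (pytest.approx(3.0), pytest.approx(7.0))

    def test_asymmetric_linear_solve(self):
        p = LVParams(r1=1, r2=1, K1=2.0, K2=1.0, a12=0.5, a21=0.25)
        eq = coexistence_equilibrium(p)
        assert eq.N1 == pytest.approx(12 / 7)
        assert eq.N2 == pytest.approx(4 / 7)

    def test_degenerate_product_one_raises(self):
        with pytest.raises(DegenerateEquilibriumError):
            coexistence_equilibrium(sym(1.0))
        with pytest.raises(DegenerateEquilibriumError):
            coexistence_equilibrium(
                LVParams(r1=1, r2=1, K1=1, K2=2, a12=2.0, a21=0.5)
            )

    def test_no_interior_solution_returns_none(self):
        # strong asymmetry: species 2 excluded
        p = LVParams(r1=1, r2=1, K1=1.0, K2=1.0, a12=0.1, a21=3.0)
        assert coexistence_equilibrium(p) is None


class TestClassifyOutcome:
    @pytest.mark.parametrize(
        "params, expected",
        [
            (sym(0.5), "stable_coexistence"),
            (LVParams(r1=1, r2=1, K1=1, K2=1, a12=2.0, a21=0.1), "exclusion_2_wins"),
            (LVParams(r1=1, r2=1, K1=1, K2=1, a12=0.1, a21=2.0), "exclusion_1_wins"),
            (LVParams(r1=1, r2=1, K1=1, K2=1, a12=1.5, a21=1.5), "founder_control"),
            (sym(1.0), "neutral"),
        ],
    )
    def test_invasion_criteria(self, params, expected):
        assert classify_outcome(params) == expected

    def test_equal_alphas_unequal_K_is_not_neutral(self):
        p = LVParams(r1=1, r2=1, K1=1.0, K2=2.0, a12=1.0, a21=1.0)
        assert classify_outcome(p) != "neutral"


stable_params = st.builds(
    LVParams,
    r1=st.floats(0.5, 3.0),
    r2=st.floats(0.5, 3.0),
    K1=st.floats(1e6, 1e9),
    K2=st.floats(1e6, 1e9),
    a12=st.floats(0.0, 0.7),
    a21=st.floats(0.0, 0.7),
).filter(
    lambda p: p.a12 < p.K1 / p.K2 and p.a21 < p.K2 / p.K1
)


class TestProperties:
    @given(stable_params)
    def test_equilibrium_is_fixed_point(self, p):
        eq = coexistence_equilibrium(p)
        assert eq is not None
        d1, d2 = derivative(eq, p)
        tol = 1e-9 * max(p.K1, p.K2)
        assert abs(d1) < tol and abs(d2) < tol

    @pytest.mark.parametrize("a12, a21", [(0.3, 0.5), (0.0, 0.0), (0.6, 0.2)])
    def test_interior_start_converges_to_equilibrium(self, a12, a21):
        p = LVParams(r1=1.0, r2=1.4, K1=5e7, K2=3e7, a12=a12, a21=a21)
        eq = coexistence_equilibrium(p)
        t_end = 50.0 / min(p.r1, p.r2)
        traj = simulate(p, State(1e6, 2e6), [0.0, t_end])
        dist = np.hypot(traj[-1, 0] - eq.N1, traj[-1, 1] - eq.N2)
        assert dist < 1e-4 * max(p.K1, p.K2)
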