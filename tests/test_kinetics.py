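import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from filtergate.constants import E_CHARGE
from filtergate.gating import nernst_potential
from filtergate.kinetics import (
    SingularGeneratorError,
    build_generator,
    edge_rate,
    iv_curve,
    steady_current,
    steady_state,
)
from filtergate.king_altman import closed_form_current, spanning_tree_oracle
from filtergate.models import Condition, Edge, EyringBarrier, ModelSpec, RateParameterSet, load_model_spec

from conftest import random_rate_params


def toy_two_state():
    return ModelSpec(
        name="toy2",
        states=["A", "B"],
        occupancy={},
        edges=[Edge("A", "B", "a"), Edge("B", "A", "b")],
        transport_cycle=["A", "B", "A"],
    )


def uniform_five_cycle():
    states = ["1", "2", "3", "4", "5"]
    edges = []
    for i in range(5):
        s, t = states[i], states[(i + 1) % 5]
        edges.append(Edge(s, t, f"f{i}"))
        edges.append(Edge(t, s, f"b{i}"))
    return ModelSpec(
        name="cycle5",
        states=states,
        occupancy={},
        edges=edges,
        transport_cycle=states + ["1"],
    )


class TestEdgeRate:
    def test_eyring_forward_is_base_rate_at_zero_voltage(self, truth, model):
        cond = Condition(V=0.0, c_in=100, c_out=100)
        e23 = model.edge("2", "3")
        assert edge_rate(model, e23, truth.params, cond) == pytest.approx(
            truth.params.base_rates["k23"]
        )

    def test_characteristic_voltage_gives_e_fold_increase(self):
        # s = 1 and V = V_char must multiply the forward rate by exactly e
        model = load_model_spec("five_state_roux")
        params = RateParameterSet(
            base_rates={e.param: 1e8 for e in model.edges},
            eyring={"23": EyringBarrier(s=1.0, v_char=40.0), "51": EyringBarrier(s=0.5, v_char=50.0)},
        )
        cond = Condition(V=40.0, c_in=100, c_out=100)
        e23 = model.edge("2", "3")
        assert edge_rate(model, e23, params, cond) == pytest.approx(1e8 * math.e)

    def test_binding_rate_proportional_to_activity(self, truth, model):
        # the uptake rate tracks internal activity linearly: k12 = k12,1 * a_in
        e12 = model.edge("1", "2")
        for c_in in (50.0, 250.0, 1500.0):
            cond = Condition(V=-60.0, c_in=c_in, c_out=100)
            r = edge_rate(model, e12, truth.params, cond)
            assert r == pytest.approx(truth.params.base_rates["k12"] * cond.a_in, rel=1e-12)
            assert r / cond.a_in == pytest.approx(truth.params.base_rates["k12"], rel=1e-12)

    def test_eyring_backward_form(self, truth, model):
        # reverse edge carries exp(-(1-s)V/V_char) with the shared barrier
        cond = Condition(V=-80.0, c_in=100, c_out=100)
        e32 = model.edge("3", "2")
        barrier = truth.params.eyring["23"]
        expected = truth.params.base_rates["k32"] * math.exp(
            -(1 - barrier.s) * cond.V / barrier.v_char
        )
        assert edge_rate(model, e32, truth.params, cond) == pytest.approx(expected, rel=1e-12)


class TestGenerator:
    def test_two_state_toy_matrix(self):
        model = toy_two_state()
        params = RateParameterSet(base_rates={"a": 3.0, "b": 7.0})
        Q = build_generator(model, params, Condition(V=0, c_in=100, c_out=100))
        assert np.allclose(Q, [[-3.0, 3.0], [7.0, -7.0]])

    def test_row_sums_vanish_on_random_instance(self, model):
        rng = np.random.default_rng(11)
        params = random_rate_params(model, rng)
        Q = build_generator(model, params, Condition(V=-60.0, c_in=250, c_out=100))
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-6 * np.abs(Q).max())

    def test_generator_matches_hand_evaluated_rate_laws(self, truth, model):
        # direct evaluation of the binding/Eyring rate laws at -160 mV, 100/100
        cond = Condition(V=-160.0, c_in=100, c_out=100)
        Q = build_generator(model, truth.params, cond)
        br = truth.params.base_rates
        b23, b51 = truth.params.eyring["23"], truth.params.eyring["51"]
        ix = model.state_index
        a = 100.0 * 0.770
        assert Q[ix("1"), ix("2")] == pytest.approx(br["k12"] * a, rel=1e-12)
        assert Q[ix("5"), ix("4")] == pytest.approx(br["k54"] * a, rel=1e-12)
        assert Q[ix("2"), ix("3")] == pytest.approx(
            br["k23"] * math.exp(b23.s * -160.0 / b23.v_char), rel=1e-12
        )
        assert Q[ix("3"), ix("2")] == pytest.approx(
            br["k32"] * math.exp(-(1 - b23.s) * -160.0 / b23.v_char), rel=1e-12
        )
        assert Q[ix("5"), ix("1")] == pytest.approx(
            br["k51"] * math.exp(b51.s * -160.0 / b51.v_char), rel=1e-12
        )
        assert Q[ix("3"), ix("4")] == pytest.approx(br["k34"], rel=1e-12)


class TestSteadyState:
    def test_uniform_five_cycle_is_equidistributed(self):
        model = uniform_five_cycle()
        params = RateParameterSet(base_rates={e.param: 1.0 for e in model.edges})
        Q = build_generator(model, params, Condition(V=0, c_in=100, c_out=100))
        occ = steady_state(Q, model.states)
        assert np.allclose(occ.P, 0.2, atol=1e-14)

    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_normalisation_on_random_instances(self, model, truth, seed):
        rng = np.random.default_rng(seed)
        params = random_rate_params(model, rng)
        cond = Condition(
            V=float(rng.uniform(-160, 160)),
            c_in=float(rng.uniform(20, 1500)),
            c_out=float(rng.uniform(20, 1500)),
        )
        occ = steady_state(build_generator(model, params, cond), model.states)
        assert abs(occ.P.sum() - 1.0) < 1e-12
        assert np.all(occ.P >= 0)

    def test_reducible_generator_raises(self):
        Q = np.zeros((4, 4))
        Q[0, 1] = Q[1, 0] = 1.0
        Q[2, 3] = Q[3, 2] = 1.0
        np.fill_diagonal(Q, -Q.sum(axis=1))
        with pytest.raises(SingularGeneratorError):
            steady_state(Q)

    @pytest.mark.parametrize("model_name", ["five_state_roux", "four_state"])
    def test_linear_solve_matches_spanning_tree_oracle(self, model_name):
        # the production path (dense solve) against exhaustive King-Altman
        # enumeration on random instances of both shipped small models
        model = load_model_spec(model_name)
        rng = np.random.default_rng(17 if model_name == "five_state_roux" else 18)
        for _ in range(20):
            params = random_rate_params(model, rng)
            cond = Condition(
                V=float(rng.uniform(-160, 160)),
                c_in=float(rng.uniform(20, 1500)),
                c_out=float(rng.uniform(20, 1500)),
            )
            occ = steady_state(build_generator(model, params, cond), model.states)
            oracle = spanning_tree_oracle(model, params, cond)
            assert np.max(np.abs(occ.P - oracle.P) / oracle.P) < 1e-10


class TestCurrent:
    def test_equilibrium_current_vanishes(self, truth, model):
        # symmetric activities at 0 mV with the consistency constraint on
        res = steady_current(model, truth.params, Condition(V=0.0, c_in=100, c_out=100))
        assert abs(res.current_pA) < 1e-12

    def test_flux_identical_on_every_cycle_edge(self, model):
        rng = np.random.default_rng(3)
        params = random_rate_params(model, rng)
        cond = Condition(V=-120.0, c_in=500, c_out=100)
        # check_flux asserts 1e-8-relative agreement internally
        steady_current(model, params, cond, check_flux=True)

    def test_closed_form_matches_general_solver(self, model):
        rng = np.random.default_rng(4)
        for _ in range(10):
            params = random_rate_params(model, rng)
            cond = Condition(
                V=float(rng.uniform(-160, 160)),
                c_in=float(rng.uniform(20, 1500)),
                c_out=float(rng.uniform(20, 1500)),
            )
            general = steady_current(model, params, cond).current_pA
            closed = closed_form_current(model, params, cond)
            assert general == pytest.approx(closed, rel=1e-10)

    def test_current_is_charge_times_flux(self, truth, model):
        res = steady_current(model, truth.params, Condition(V=-160, c_in=100, c_out=100))
        assert res.current_pA == pytest.approx(E_CHARGE * res.cycle_flux * 1e12, rel=1e-14)

    def test_iv_curve_reverses_at_nernst_potential(self, truth, model):
        # under the consistency constraint the zero crossing sits at E_K
        for c_in, c_out in ((1000.0, 100.0), (100.0, 750.0)):
            e_k = nernst_potential(Condition(V=0, c_in=c_in, c_out=c_out))

            def current_at(v):
                return iv_curve(model, truth.params, [Condition(V=v, c_in=c_in, c_out=c_out)])[0]

            root = brentq(current_at, e_k - 30, e_k + 30, xtol=1e-9)
            assert abs(root - e_k) < 0.1

    def test_empty_condition_list_rejected(self, truth, model):
        with pytest.raises(ValueError):
            iv_curve(model, truth.params, [])
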