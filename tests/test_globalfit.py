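import math
from dataclasses import replace

import numpy as np
import pytest

from filtergate.constants import thermal_voltage_mV
from filtergate.gating import GatingLink, predict_kOM
from filtergate.globalfit import (
    FitConfig,
    ParamTransform,
    compare_gating_links,
    default_links,
    global_objective,
    run_global_fit,
)
from filtergate.kinetics import build_generator, steady_current, steady_state
from filtergate.models import Condition, EyringBarrier, RateParameterSet, load_model_spec
from filtergate.nernst import (
    apply_nernst_constraint,
    cycle_base_rate_ratio,
    cycle_vchar_deficit,
)
from filtergate.synthetic import GroundTruth, KMOCurve, OFDuty, generate_dataset


class TestGlobalObjective:
    def test_zero_at_generating_truth_on_clean_data(self, truth, model, clean_dataset):
        err, per_curve = global_objective(
            model, truth.params, truth.link.w, truth.link, clean_dataset, FitConfig()
        )
        assert err < 1e-12

    def test_matches_naive_double_loop(self, truth, model, design):
        # independent oracle: per-point loop through single-condition calls
        ds = generate_dataset(truth, design, noise=True, seed=9)
        config = FitConfig(weight_current=1.3, weight_rate=0.7)
        err, _ = global_objective(model, truth.params, truth.link.w, truth.link, ds, config)
        naive = 0.0
        for curve in ds:
            for v, i_data, k_data in zip(curve.V, curve.I_OF, curve.k_OM):
                cond = Condition(V=float(v), c_in=curve.c_in, c_out=curve.c_out)
                i_model = steady_current(model, truth.params, cond).current_pA
                naive += config.weight_current * (i_model - i_data) ** 2
                if v < 0:
                    occ = steady_state(build_generator(model, truth.params, cond), model.states)
                    k_model = predict_kOM(truth.link, occ)
                    naive += config.weight_rate * (math.log(k_model) - math.log(k_data)) ** 2
        assert err == pytest.approx(naive, rel=1e-9)

    def test_positive_voltage_kom_points_are_masked(self, truth, model, clean_dataset):
        err0, _ = global_objective(
            model, truth.params, truth.link.w, truth.link, clean_dataset, FitConfig()
        )
        tampered = clean_dataset
        for curve in tampered:
            curve.k_OM[curve.V > 0] *= 37.0  # must not matter
        err1, _ = global_objective(
            model, truth.params, truth.link.w, truth.link, tampered, FitConfig()
        )
        assert err0 == err1
        for curve in tampered:  # restore the session fixture
            curve.k_OM[curve.V > 0] /= 37.0

    def test_doubling_current_weight_doubles_iv_component(self, truth, model, design):
        ds = generate_dataset(truth, design, noise=True, seed=10)
        _, per1 = global_objective(model, truth.params, truth.link.w, truth.link, ds, FitConfig())
        _, per2 = global_objective(
            model, truth.params, truth.link.w, truth.link, ds, FitConfig(weight_current=2.0)
        )
        for sid in per1:
            assert per2[sid]["iv"] == pytest.approx(2 * per1[sid]["iv"], rel=1e-12)
            assert per2[sid]["kom"] == pytest.approx(per1[sid]["kom"], rel=1e-12)

    def test_deterministic(self, truth, model, noisefree_dataset):
        a = global_objective(model, truth.params, truth.link.w, truth.link, noisefree_dataset, FitConfig())
        b = global_objective(model, truth.params, truth.link.w, truth.link, noisefree_dataset, FitConfig())
        assert a[0] == b[0] and a[1] == b[1]

    def test_error_sum_equals_breakdown(self, truth, model, noisefree_dataset):
        err, per_curve = global_objective(
            model, truth.params, truth.link.w, truth.link, noisefree_dataset, FitConfig()
        )
        total = sum(v["iv"] + v["kom"] for v in per_curve.values())
        assert err == pytest.approx(total, rel=1e-9)


class TestParamTransform:
    def test_round_trip_constrained(self, truth, model):
        tr = ParamTransform(model, constrained=True)
        x = tr.pack(truth.params, 3e4)
        params, w = tr.unpack(x)
        for name, v in truth.params.base_rates.items():
            assert params.base_rates[name] == pytest.approx(v, rel=1e-12)
        assert w == pytest.approx(3e4, rel=1e-12)

    def test_unpack_always_satisfies_constraint(self, model):
        tr = ParamTransform(model, constrained=True)
        rng = np.random.default_rng(8)
        for _ in range(20):
            params, _ = tr.unpack(rng.normal(0, 3, size=tr.n_params) + 18.0)
            assert cycle_base_rate_ratio(model, params) == pytest.approx(1.0, rel=1e-9)
            assert abs(cycle_vchar_deficit(model, params)) < 1e-12 / thermal_voltage_mV()

    def test_round_trip_unconstrained(self, truth, model):
        tr = ParamTransform(model, constrained=False)
        params, w = tr.unpack(tr.pack(truth.params, 1.0))
        for name, v in truth.params.base_rates.items():
            assert params.base_rates[name] == pytest.approx(v, rel=1e-12)
        for g, b in truth.params.eyring.items():
            assert params.eyring[g].s == pytest.approx(b.s, rel=1e-9)
            assert params.eyring[g].v_char == pytest.approx(b.v_char, rel=1e-12)


class TestNernstConstraint:
    def test_apply_sets_products_equal(self, model, truth):
        assert cycle_base_rate_ratio(model, truth.params) == pytest.approx(1.0, rel=1e-12)
        assert abs(cycle_vchar_deficit(model, truth.params)) < 1e-15

    def test_vchar_budget_violation_rejected(self, model):
        params = RateParameterSet(
            base_rates={e.param: 1e8 for e in model.edges},
            eyring={"23": EyringBarrier(0.5, 20.0), "51": EyringBarrier(0.5, 60.0)},
        )
        with pytest.raises(ValueError, match="budget"):
            apply_nernst_constraint(model, params, adjust_group="51")


class TestModelSelection:
    def test_four_state_truth_recovered_by_inverse_link(self):
        # data generated under k_OM = w / P3 on the four-state model: the
        # inverse-P3 link must attain the smallest error sum among the
        # four-state candidates
        model = load_model_spec("four_state")
        params = RateParameterSet(
            base_rates={
                "k12": 2.0e6,
                "k21": 1.0e8,  # reset by the constraint
                "k23": 2.5e8,
                "k32": 2.0e8,
                "k35": 4.0e8,
                "k53": 2.0e6,
                "k51": 4.0e8,
                "k15": 3.0e8,
            },
            eyring={"23": EyringBarrier(0.25, 80.0), "51": EyringBarrier(0.7, 40.0)},
        )
        params = apply_nernst_constraint(model, params, adjust_group="51")
        truth4 = GroundTruth(
            model_name="four_state",
            params=params,
            link=GatingLink("inverse", "3", w=2.0e3),
            of_duty=OFDuty(k_OF=0.0),
            kmo=KMOCurve(),
        )
        ds = generate_dataset(truth4, noise=False, seed=2)
        links = default_links(model)
        assert len(links) == 8  # no P4/P3 candidate without state 4
        config = FitConfig(seed=0, restarts=1, simplex_maxfev=800, polish_top=1)
        table = compare_gating_links(ds, model, links=links, config=config)
        assert table.argmin == "1/P3"

    def test_duplicate_links_share_error_sum(self, truth, model, clean_dataset):
        link = GatingLink("ratio", "4", "3")
        config = FitConfig(seed=5, restarts=1, simplex_maxfev=300, polish_top=1)
        table = compare_gating_links(clean_dataset, model, links=[link, link], config=config)
        assert len(table.rows) == 1  # identical label, identical (seeded) fit


class TestRunGlobalFit:
    def test_restart_seeds_reproduce(self, truth, model, clean_dataset):
        config = FitConfig(seed=4, restarts=2, simplex_maxfev=300, polish_top=1)
        link = GatingLink("ratio", "4", "3")
        a = run_global_fit(clean_dataset, model, link, config)
        b = run_global_fit(clean_dataset, model, link, config)
        assert a.error_sum == b.error_sum
        assert a.restart_errors == b.restart_errors
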