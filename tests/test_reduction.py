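"""Reduction plans, reduced-model assembly and accuracy scoring."""

import numpy as np
import pytest

import phasereduce as pr
from phasereduce.reduction import PlanError, ReductionAction, ReductionPlan

from conftest import TOY_PROTOCOL, cascade_protocol


@pytest.fixture(scope="module")
def toy_reduction():
    """Toy pipeline at threshold 0.1 (the A–B loop area is ~0.091)."""
    toy = pr.make_toy_model()
    tc = pr.simulate_transient(toy, TOY_PROTOCOL)
    am = pr.pairwise_area_matrix(pr.normalize(tc))
    _, direct = pr.classify_pairs(am, direct_pairs=toy.direct_pairs())
    plan = pr.propose_plan(am, direct, toy, threshold=0.1)
    curve = pr.concentration_clamp(
        toy, "A", pr.default_sweep(tc, "A"), "B", {"k1": 100.0})
    fits = {"B": pr.fit_relation(curve)}
    reduced = pr.apply_plan(toy, plan, fits)
    return toy, plan, fits, reduced


class TestProposePlan:
    def test_toy_reduces_b_keeps_a_and_c(self, toy_reduction):
        _, plan, _, _ = toy_reduction
        by_target = {a.target: a for a in plan.actions}
        assert by_target["B"].action == "ode_to_algebraic"
        assert by_target["B"].driver == "A"
        assert by_target["A"].action == "keep_ode"
        assert by_target["C"].action == "keep_ode"

    def test_zero_threshold_is_identity_plan(self, toy, toy_am):
        _, direct = pr.classify_pairs(toy_am, direct_pairs=toy.direct_pairs())
        plan = pr.propose_plan(toy_am, direct, toy, threshold=0.0)
        assert plan.reduced_states == []

    def test_higher_threshold_reduces_more(self, toy, toy_am):
        _, direct = pr.classify_pairs(toy_am, direct_pairs=toy.direct_pairs())
        lo = pr.propose_plan(toy_am, direct, toy, threshold=0.1)
        hi = pr.propose_plan(toy_am, direct, toy, threshold=0.6)
        assert set(lo.reduced_states) <= set(hi.reduced_states)
        assert "C" in hi.reduced_states

    def test_mutually_dependent_pair_noted_not_reduced(self, toy_am):
        rev = pr.build_model(
            "reversible",
            odes={"A": "u - kf*A + kr*B", "B": "kf*A - kr*B"},
            params={"u": 0.0, "kf": 10.0, "kr": 10.0})
        _, direct = pr.classify_pairs(toy_am, direct_pairs=[("A", "B")])
        plan = pr.propose_plan(toy_am, direct, rev, threshold=0.1)
        assert plan.reduced_states == []
        assert any("mutually dependent" in n for n in plan.notes)

    def test_cyclic_plan_rejected_with_cycle_reported(self):
        with pytest.raises(PlanError, match="cyclic"):
            ReductionPlan(actions=[
                ReductionAction("A", "assume_equal", driver="B"),
                ReductionAction("B", "assume_equal", driver="A"),
            ], threshold=0.1)

    def test_duplicate_target_rejected(self):
        with pytest.raises(PlanError, match="two actions"):
            ReductionPlan(actions=[
                ReductionAction("A", "keep_ode"),
                ReductionAction("A", "assume_negligible"),
            ], threshold=0.1)


class TestApplyPlan:
    def test_reduced_model_structure(self, toy_reduction):
        _, plan, _, reduced = toy_reduction
        assert reduced.ode_states == ["A", "C"]
        assert reduced.explicit_states == ["B"]
        # structural count: ode count drops by exactly the reductions
        assert len(reduced.ode_states) == 3 - len(plan.reduced_states)

    def test_reduced_b_follows_fitted_relation(self, toy_reduction):
        _, _, fits, reduced = toy_reduction
        tc = pr.simulate_transient(reduced, TOY_PROTOCOL)
        np.testing.assert_allclose(tc["B"], fits["B"].predict(tc["A"]),
                                   atol=1e-9)

    def test_reduced_c_tracks_original_closely(self, toy_reduction):
        toy, _, _, reduced = toy_reduction
        t1 = pr.simulate_transient(toy, TOY_PROTOCOL)
        t2 = pr.simulate_transient(reduced, TOY_PROTOCOL)
        rng = t1["C"].max() - t1["C"].min()
        assert np.max(np.abs(t1["C"] - t2["C"])) / rng < 0.05

    def test_identity_plan_changes_nothing(self, toy):
        plan = ReductionPlan(
            actions=[ReductionAction(s, "keep_ode") for s in toy.states],
            threshold=0.0)
        same = pr.apply_plan(toy, plan, {})
        t1 = pr.simulate_transient(toy, TOY_PROTOCOL)
        t2 = pr.simulate_transient(same, TOY_PROTOCOL)
        np.testing.assert_allclose(t1.data.to_numpy(), t2.data.to_numpy(),
                                   rtol=0, atol=1e-12)

    def test_missing_fit_rejected(self, toy_reduction):
        toy, plan, _, _ = toy_reduction
        with pytest.raises(PlanError, match="fitted relation"):
            pr.apply_plan(toy, plan, {})

    def test_conservation_and_total_actions(self, binding_model):
        plan = ReductionPlan(actions=[
            ReductionAction("C", "keep_ode"),
        ], threshold=0.0)
        # E is already explicit (Etot - C); replace it via the action instead
        m = pr.build_model(
            "binding_ode",
            odes={"C": "kon*E*S - koff*C", "E": "koff*C - kon*E*S"},
            parameterized=["S"],
            params={"kon": 1.0, "koff": 0.1, "Etot": 1.0, "S": 0.0},
            conserved=[("Etot", ["E", "C"])], initial={"E": 1.0})
        plan = ReductionPlan(actions=[
            ReductionAction("E", "conservation_eliminate", driver="Etot",
                            members=("C",)),
            ReductionAction("C", "keep_ode"),
        ], threshold=0.0)
        red = pr.apply_plan(m, plan, {})
        assert red.ode_states == ["C"]
        ss = pr.find_steady_state(red, {"S": 1.0}, x0={"C": 0.0})
        assert ss["E"] + ss["C"] == pytest.approx(1.0, rel=1e-9)
        assert ss["C"] == pytest.approx(1.0 / 1.1, rel=1e-6)

    def test_reduced_model_round_trips_declarative_format(
            self, toy_reduction, tmp_path):
        _, _, _, reduced = toy_reduction
        path = tmp_path / "reduced.model"
        pr.dump_model_file(reduced, path)
        back = pr.load_model_file(path)
        t1 = pr.simulate_transient(reduced, TOY_PROTOCOL)
        t2 = pr.simulate_transient(back, TOY_PROTOCOL)
        # reloaded models list ODE states first; compare per state
        for s in reduced.states:
            np.testing.assert_allclose(t1[s], t2[s], rtol=1e-9, atol=1e-9)


class TestScoreReduction:
    def test_self_comparison_scores_zero(self, toy):
        rep = pr.score_reduction(toy, toy, TOY_PROTOCOL)
        assert all(v == 0.0 for v in rep.per_state.values())
        assert rep.overall == 0.0

    def test_untouched_state_has_near_zero_error(self, toy_reduction):
        toy, _, _, reduced = toy_reduction
        rep = pr.score_reduction(toy, reduced, TOY_PROTOCOL)
        assert rep.per_state["A"] < 1e-6
        assert 0.0 < rep.per_state["B"] < 5.0
        assert rep.overall == pytest.approx(
            np.mean(list(rep.per_state.values())))

    def test_steady_state_agreement_within_fit_rmse(self, toy_reduction):
        toy, _, fits, reduced = toy_reduction
        ss_full = pr.find_steady_state(toy, {"k1": 100.0})
        ss_red = pr.find_steady_state(reduced, {"k1": 100.0})
        for s in toy.states:
            assert abs(ss_red[s] - ss_full[s]) <= fits["B"].rmse + 1e-6

    def test_relative_metric_available(self, toy_reduction):
        toy, _, _, reduced = toy_reduction
        rep = pr.score_reduction(toy, reduced, TOY_PROTOCOL,
                                 metric="relative")
        assert rep.metric == "relative"
        assert rep.per_state["B"] > 0


class TestPerturbationSuite:
    def test_halved_input_still_tracks(self, toy_reduction):
        toy, _, _, reduced = toy_reduction
        base = pr.score_reduction(toy, reduced, TOY_PROTOCOL)
        half = pr.Scenario("half_input", pr.StimulusProtocol(
            parameter="k1", on_value=50.0, t_off=10.0, t_end=20.0,
            n_out=2000))
        reports = pr.run_perturbation_suite(toy, reduced, [half])
        assert reports["half_input"].overall < 5 * max(base.overall, 0.5)

    def test_training_scenario_reproduces_training_score(self, toy_reduction):
        toy, _, _, reduced = toy_reduction
        base = pr.score_reduction(toy, reduced, TOY_PROTOCOL)
        sc = pr.Scenario("training", TOY_PROTOCOL)
        reports = pr.run_perturbation_suite(toy, reduced, [sc])
        assert reports["training"].overall == pytest.approx(base.overall,
                                                            rel=1e-9)

    def test_structural_insensitivity_detected(self):
        """A reduction that hard-codes a parameter away cannot respond to
        perturbations of that parameter."""
        m = pr.build_model(
            "two_step",
            odes={"A": "u - ka*A", "B": "ka*A - kb*P*B"},
            params={"u": 0.0, "ka": 1.0, "kb": 10.0, "P": 1.0})
        proto = pr.StimulusProtocol(parameter="u", on_value=10.0,
                                    t_off=10.0, t_end=20.0, n_out=500)
        tc = pr.simulate_transient(m, proto)
        curve = pr.concentration_clamp(m, "A", pr.default_sweep(tc, "A"),
                                       "B", {"u": 10.0})
        fit = pr.fit_relation(curve, candidate_forms=("linear",))
        plan = ReductionPlan(actions=[
            ReductionAction("B", "ode_to_algebraic", driver="A"),
            ReductionAction("A", "keep_ode")], threshold=0.1)
        reduced = pr.apply_plan(m, plan, {"B": fit})
        # the fitted B(A) bakes in P = 1; drop P from the reduced params to
        # model its structural elimination
        del reduced.params["P"]
        knock = pr.Scenario("p_knockout", pr.StimulusProtocol(
            parameter="P", on_value=0.5, off_value=1.0, t_off=10.0,
            t_end=20.0, n_out=500), overrides={"u": 10.0})
        reports = pr.run_perturbation_suite(m, reduced, [knock],
                                            excluded=["A"])
        rep = reports["p_knockout"]
        assert "P" in rep.insensitive_params
        assert rep.per_state["B"] > 1.0  # original responds, reduced cannot


class TestSoundness:
    def test_aggressive_reduction_never_more_accurate(self):
        """Across random cascades, the conservative plan (threshold 0.05)
        scores at or below the aggressive plan (threshold 0.5)."""
        errs = {0.05: [], 0.5: []}
        for seed in (1, 2):
            spec = pr.random_cascade_spec(4, seed=seed)
            model = pr.generate_cascade(spec)
            proto = cascade_protocol(spec, n_out=500)
            tc = pr.simulate_transient(model, proto)
            am = pr.pairwise_area_matrix(pr.normalize(tc))
            _, direct = pr.classify_pairs(am,
                                          direct_pairs=model.direct_pairs())
            for thr in (0.05, 0.5):
                plan = pr.propose_plan(am, direct, model, threshold=thr)
                fits = {}
                for a in plan.actions:
                    if a.action != "ode_to_algebraic":
                        continue
                    curve = pr.concentration_clamp(
                        model, a.driver, pr.default_sweep(tc, a.driver, 10),
                        a.target, {"u": spec.input_magnitude})
                    fits[a.target] = pr.fit_relation(
                        curve, candidate_forms=("linear",))
                reduced = pr.apply_plan(model, plan, fits)
                errs[thr].append(
                    pr.score_reduction(model, reduced, proto).overall)
        assert np.mean(errs[0.05]) <= np.mean(errs[0.5]) + 1e-9
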