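"""Jacobian linearization and modal timescale decomposition."""

import numpy as np
import pytest

import phasereduce as pr


TOY_J = np.array([[-1.0, 0.0, 0.0],
                  [1.0, -10.0, 0.0],
                  [0.0, 10.0, -1.0]])


@pytest.fixture(scope="module")
def distinct_cascade():
    """Chain with well-separated distinct rates: diagonalizable Jacobian."""
    model = pr.generate_cascade(pr.SyntheticCascadeSpec(3, (1.0, 10.0, 100.0)))
    ss = pr.find_steady_state(model, {"u": 100.0})
    J = pr.jacobian_at(model, ss, {"u": 100.0})
    return model, ss, J


class TestJacobianAt:
    def test_toy_jacobian_is_the_hand_derived_bidiagonal(self, toy, toy_ss_on):
        J = pr.jacobian_at(toy, toy_ss_on, {"k1": 100.0})
        np.testing.assert_allclose(J, TOY_J, atol=1e-6)

    def test_linear_model_jacobian_independent_of_state(self, toy):
        ss1 = pr.find_steady_state(toy, {"k1": 100.0})
        ss2 = pr.find_steady_state(toy, {"k1": 40.0})
        J1 = pr.jacobian_at(toy, ss1, {"k1": 100.0})
        J2 = pr.jacobian_at(toy, ss2, {"k1": 40.0})
        np.testing.assert_allclose(J1, J2, atol=1e-6)

    def test_finite_difference_matches_analytic_ladder(self, distinct_cascade):
        _, _, J = distinct_cascade
        analytic = np.array([[-1.0, 0.0, 0.0],
                             [1.0, -10.0, 0.0],
                             [0.0, 10.0, -100.0]])
        np.testing.assert_allclose(J, analytic, rtol=1e-6, atol=1e-6)

    def test_off_steady_state_rejected(self, toy):
        with pytest.raises(ValueError, match="not at steady state"):
            pr.jacobian_at(toy, {"A": 5.0, "B": 5.0, "C": 5.0},
                           {"k1": 100.0})

    def test_dae_jacobian_covers_combined_system(self, dae_toy):
        ss = pr.find_steady_state(dae_toy, {"k1": 100.0})
        J = pr.jacobian_at(dae_toy, ss, {"k1": 100.0})
        assert J.shape == (3, 3)
        assert np.all(np.isfinite(J))
        # residual row for B: d(k2*A - k3*B)/d(A, C, B) = (1, 0, -10)
        i = dae_toy.dynamic_states.index("B")
        np.testing.assert_allclose(
            J[i], [1.0, 0.0, -10.0], atol=1e-6)


class TestModalDecomposition:
    def test_toy_timescales_are_one_one_tenth(self, toy, toy_ss_on):
        J = pr.jacobian_at(toy, toy_ss_on, {"k1": 100.0})
        rep = pr.modal_decomposition(J, toy.dynamic_states,
                                     steady_state=toy_ss_on)
        np.testing.assert_allclose(sorted(rep.timescales), [0.1, 1.0, 1.0],
                                   rtol=1e-9)
        # slow -> fast ordering
        assert rep.timescales == sorted(rep.timescales, reverse=True)

    def test_toy_fastest_mode_dominated_by_b(self, toy, toy_ss_on):
        J = pr.jacobian_at(toy, toy_ss_on, {"k1": 100.0})
        rep = pr.modal_decomposition(J, toy.dynamic_states)
        assert rep.dominant_species[-1][0] == "B"

    def test_diagonal_jacobian_has_single_species_modes(self):
        rep = pr.modal_decomposition(np.diag([-1.0, -5.0, -20.0]),
                                     ["a", "b", "c"])
        assert rep.timescales == pytest.approx([1.0, 0.2, 0.05])
        assert rep.dominant_species == [["a"], ["b"], ["c"]]
        for row in rep.modal_rows:
            assert sorted(np.abs(row)) == pytest.approx([0.0, 0.0, 1.0])

    def test_reconstruction_and_trace_identity(self, distinct_cascade):
        _, _, J = distinct_cascade
        lam, M = np.linalg.eig(J)
        rec = M @ np.diag(lam) @ np.linalg.inv(M)
        assert np.linalg.norm(rec - J) / np.linalg.norm(J) < 1e-8
        assert np.sum(lam).real == pytest.approx(np.trace(J), rel=1e-8)

    def test_eigenvalue_sum_matches_trace_for_toy(self, toy, toy_ss_on):
        J = pr.jacobian_at(toy, toy_ss_on, {"k1": 100.0})
        rep = pr.modal_decomposition(J, toy.dynamic_states)
        assert np.sum(rep.eigenvalues).real == pytest.approx(np.trace(J),
                                                             rel=1e-8)

    def test_stability_of_cascade_steady_states(self):
        for seed in (3, 4):
            spec = pr.random_cascade_spec(4, seed=seed)
            model = pr.generate_cascade(spec)
            ss = pr.find_steady_state(model, {"u": 100.0})
            J = pr.jacobian_at(model, ss, {"u": 100.0})
            rep = pr.modal_decomposition(J, model.dynamic_states)
            assert np.all(rep.eigenvalues.real < 0)
            assert all(t > 0 for t in rep.timescales)

    def test_defective_matrix_flagged_unreliable(self, toy, toy_ss_on):
        # the toy Jacobian has a repeated eigenvalue with a 1-D eigenspace
        J = pr.jacobian_at(toy, toy_ss_on, {"k1": 100.0})
        rep = pr.modal_decomposition(J, toy.dynamic_states)
        assert rep.unreliable

    def test_millisecond_modes_labeled_algebraic(self):
        rep = pr.modal_decomposition(np.diag([-1.0, -1e4]), ["slow", "alg"])
        assert rep.mode_labels == ["dynamic", "algebraic"]

    def test_table_export(self, distinct_cascade, tmp_path):
        model, ss, J = distinct_cascade
        rep = pr.modal_decomposition(J, model.dynamic_states,
                                     steady_state=ss)
        rep.to_csv(tmp_path / "t.csv")
        import pandas as pd
        t = pd.read_csv(tmp_path / "t.csv")
        assert list(t.columns[:2]) == ["timescale_s", "dominant_species"]
        assert t["timescale_s"].iloc[0] == pytest.approx(1.0, rel=1e-6)


class TestCompareMethods:
    def test_toy_b_fast_by_both_methods(self, toy, toy_ss_on, toy_am):
        J = pr.jacobian_at(toy, toy_ss_on, {"k1": 100.0})
        rep = pr.modal_decomposition(J, toy.dynamic_states)
        # the toy A–B area (~0.091) sits just above the default 0.05 cut;
        # with the fast bin widened to 0.1 both methods agree on B
        classes, _ = pr.classify_pairs(toy_am,
                                       pr.SpeedThresholds(0.1, 0.5))
        table = pr.compare_methods(rep, toy_am, classes)
        row = table[table.species == "B"].iloc[0]
        assert row.jacobian_fastest_mode
        assert row.phase_fastest_pair_class == "fast"
        assert row.agree

    def test_single_species_model_trivially_agrees(self):
        rep = pr.modal_decomposition(np.array([[-2.0]]), ["X"])
        import pandas as pd
        am = pr.AreaMatrix(matrix=pd.DataFrame(
            [[0.0, 0.02], [0.02, 0.0]], index=["X", "Y"],
            columns=["X", "Y"]))
        table = pr.compare_methods(rep, am, {("X", "Y"): "fast"})
        assert table.iloc[0].agree

    def test_hundredfold_faster_step_flagged_by_both(self):
        spec = pr.SyntheticCascadeSpec(3, (1.0, 100.0, 1.0))
        model = pr.generate_cascade(spec)
        ss = pr.find_steady_state(model, {"u": 100.0})
        J = pr.jacobian_at(model, ss, {"u": 100.0})
        rep = pr.modal_decomposition(J, model.dynamic_states)
        assert "X2" in rep.fastest_mode_species()
        proto = pr.StimulusProtocol(parameter="u", on_value=100.0,
                                    t_off=10.0, t_end=20.0, n_out=1000)
        am = pr.pairwise_area_matrix(pr.normalize(
            pr.simulate_transient(model, proto)))
        classes, _ = pr.classify_pairs(am)
        table = pr.compare_methods(rep, am, classes)
        row = table[table.species == "X2"].iloc[0]
        assert row.jacobian_fastest_mode
        assert row.phase_fastest_pair_class == "fast"
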