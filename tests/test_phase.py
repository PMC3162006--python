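"""Loop areas, the pairwise matrix, classification and the histogram."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phasereduce as pr
from phasereduce.phase import split_loop_area

from conftest import TOY_PROTOCOL, cascade_protocol


def unit_square():
    return pr.PhaseLoop([0.0, 1.0, 1.0, 0.0], [0.0, 0.0, 1.0, 1.0])


def circle_loop(n=1000, r=0.5):
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return pr.PhaseLoop(0.5 + r * np.cos(th), 0.5 + r * np.sin(th))


class TestLoopArea:
    def test_unit_square_is_maximal(self):
        assert pr.loop_area(unit_square()) == pytest.approx(1.0)

    def test_degenerate_diagonal_sweep_has_zero_area(self):
        x = np.concatenate([np.linspace(0, 1, 50), np.linspace(1, 0, 50)])
        assert pr.loop_area(pr.PhaseLoop(x, x)) == pytest.approx(0.0, abs=1e-12)

    def test_inscribed_circle_area_is_quarter_pi(self):
        assert pr.loop_area(circle_loop()) == pytest.approx(np.pi / 4, abs=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pr.loop_area(pr.PhaseLoop([0.0, 1.0], [0.0, 1.0]))

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            pr.loop_area(pr.PhaseLoop([0.0, np.nan, 1.0], [0.0, 1.0, 0.0]))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 999), st.integers(3, 40))
    def test_cyclic_rotation_and_swap_invariance(self, seed, npts):
        rng = np.random.default_rng(seed)
        loop = pr.PhaseLoop(rng.random(npts), rng.random(npts))
        base = pr.loop_area(loop)
        k = int(rng.integers(1, npts))
        rotated = pr.PhaseLoop(np.roll(loop.x, k), np.roll(loop.y, k))
        assert pr.loop_area(rotated) == pytest.approx(base, abs=1e-12)
        assert pr.loop_area(loop.swapped()) == pytest.approx(base, abs=1e-12)

    def test_bowtie_split_mode_recovers_lobe_areas(self):
        # self-crossing bowtie: the two triangular lobes have opposite
        # orientation, so their signed areas cancel but each covers 1/4
        bowtie = pr.PhaseLoop([0.0, 1.0, 1.0, 0.0], [0.0, 1.0, 0.0, 1.0])
        assert pr.loop_area(bowtie) == pytest.approx(0.0, abs=1e-12)
        assert split_loop_area(bowtie) == pytest.approx(0.5, abs=1e-9)

    def test_split_mode_agrees_on_simple_loops(self):
        assert split_loop_area(unit_square()) == pytest.approx(1.0)
        assert split_loop_area(circle_loop(200)) == pytest.approx(
            pr.loop_area(circle_loop(200)), abs=1e-12)


class TestAreaMatrix:
    def test_toy_ordering_fast_pair_below_slow_pair(self, toy_am):
        assert toy_am.area("A", "B") < toy_am.area("B", "C")

    def test_symmetric_zero_diagonal_bounded(self, toy_am):
        m = toy_am.matrix.to_numpy()
        np.testing.assert_allclose(m, m.T)
        assert np.all(np.diag(m) == 0.0)
        assert np.all((m >= 0.0) & (m <= 1.0 + 1e-6))

    def test_grid_convergence_of_areas(self, toy, toy_am):
        dense = pr.StimulusProtocol(parameter="k1", on_value=100.0,
                                    t_off=10.0, t_end=20.0, n_out=4000)
        am2 = pr.pairwise_area_matrix(pr.normalize(
            pr.simulate_transient(toy, dense)))
        for a, b in (("A", "B"), ("B", "C"), ("A", "C")):
            assert abs(am2.area(a, b) - toy_am.area(a, b)) < 1e-3

    def test_static_states_excluded_and_listed(self):
        m = pr.build_model("with_static",
                           odes={"A": "u - A", "B": "A - 2*B", "D": "0"},
                           params={"u": 0.0}, initial={"D": 1.0})
        proto = pr.StimulusProtocol(parameter="u", on_value=10.0,
                                    t_off=5.0, t_end=10.0, n_out=200)
        tc = pr.simulate_transient(m, proto,
                                   initial_state={"A": 0, "B": 0, "D": 1.0})
        am = pr.pairwise_area_matrix(pr.normalize(tc))
        assert am.excluded == ["D"]
        assert set(am.states) == {"A", "B"}

    def test_area_decreases_with_downstream_rate(self):
        """Faster draining of X2 means tighter X1–X2 equilibration."""
        areas = []
        for k in (1.0, 3.0, 10.0, 30.0, 100.0):
            spec = pr.SyntheticCascadeSpec(2, (1.0, k))
            tc = pr.simulate_transient(pr.generate_cascade(spec),
                                       cascade_protocol(spec, n_out=800))
            ntc = pr.normalize(tc)
            areas.append(pr.loop_area(
                pr.PhaseLoop(ntc["X1"], ntc["X2"], "X1", "X2")))
        assert all(a > b for a, b in zip(areas, areas[1:]))


class TestClassification:
    @pytest.mark.parametrize("area,expected", [
        (0.03, "fast"), (0.2, "medium"), (0.7, "slow"),
        (0.05, "fast"),   # boundary: fast bin is closed above
        (0.5, "medium"),  # boundary: medium bin is closed above
    ])
    def test_threshold_bins(self, area, expected):
        assert pr.classify_area(area) == expected

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            pr.SpeedThresholds(fast_max=0.6, slow_min=0.5)

    def test_direct_restriction(self, toy, toy_am):
        classes, direct = pr.classify_pairs(toy_am,
                                            direct_pairs=toy.direct_pairs())
        assert set(classes) == {("A", "B"), ("A", "C"), ("B", "C")}
        assert set(direct) == {("A", "B"), ("B", "C")}

    def test_every_pair_labeled(self, toy_am):
        classes, _ = pr.classify_pairs(toy_am)
        assert all(c in ("fast", "medium", "slow") for c in classes.values())


class TestHistogram:
    def test_counts_conserved(self, toy_am):
        h = pr.area_histogram(toy_am)
        n = len(toy_am.states)
        assert h["count"].sum() == n * (n - 1) // 2

    def test_nonpositive_bin_width_rejected(self, toy_am):
        with pytest.raises(ValueError):
            pr.area_histogram(toy_am, bin_width=0.0)

    def test_two_rate_groups_separate_into_low_and_high_bins(self):
        """Cascade (100, 100, 1, 1): equal-rate adjacent pairs sit in a
        moderate band while the fast→slow boundary pair (X2–X3, a 100-fold
        slowdown) shows near-complete hysteresis."""
        spec = pr.SyntheticCascadeSpec(4, (100.0, 100.0, 1.0, 1.0))
        tc = pr.simulate_transient(pr.generate_cascade(spec),
                                   cascade_protocol(spec, n_out=800))
        ntc = pr.normalize(tc)
        am = pr.pairwise_area_matrix(ntc)
        adjacent = {(i, i + 1): am.area(f"X{i}", f"X{i+1}") for i in (1, 2, 3)}
        low = [adjacent[(1, 2)], adjacent[(3, 4)]]
        high = adjacent[(2, 3)]
        assert max(low) < 0.6
        assert high > 0.9


def test_global_portrait_figure_renders(toy_ntc, toy_am, tmp_path):
    fig = pr.plot_global_phase_portrait(toy_ntc, toy_am,
                                        tmp_path / "grid.svg")
    assert (tmp_path / "grid.svg").stat().st_size > 0
    import matplotlib.pyplot as plt
    plt.close(fig)
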