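"""Tests for lattice geometry, VEGF fields, cell coupling and pattern metrics."""

import numpy as np
import pytest

from notchsim import (
    VegfFieldSpec,
    build_lattice,
    classify_tip_stalk,
    pattern_metrics,
    simulate_tissue,
    trans_inputs,
    vegf_field,
)
from notchsim.model_core import _Trans, _rhs1_core, integrate


class TestBuildLattice:
    def test_two_cell_line_each_has_one_neighbour(self):
        lat = build_lattice("line", 1, 2)
        assert lat.neighbours == [[1], [0]]

    def test_line_interior_cells_have_two_neighbours(self):
        lat = build_lattice("line", 1, 5)
        assert [len(n) for n in lat.neighbours] == [1, 2, 2, 2, 1]

    def test_hex_centre_cell_has_six_neighbours(self):
        lat = build_lattice("hex", 3, 3)
        centre = 1 * 3 + 1
        assert len(lat.neighbours[centre]) == 6

    def test_hex_row_spacing_and_column_spacing(self):
        lat = build_lattice("hex", 3, 3)
        c = lat.cell_centres
        assert c[3, 1] - c[0, 1] == pytest.approx(1.5)          # rows 1.5 apart
        assert c[1, 0] - c[0, 0] == pytest.approx(np.sqrt(3.0))  # cols sqrt(3) apart
        assert c[3, 0] - c[0, 0] == pytest.approx(np.sqrt(3.0) / 2)  # odd-row offset

    def test_adjacency_is_symmetric(self):
        lat = build_lattice("hex", 4, 5)
        for i, nbrs in enumerate(lat.neighbours):
            for j in nbrs:
                assert i in lat.neighbours[j]

    def test_neighbours_touch_geometrically(self):
        lat = build_lattice("hex", 4, 4)
        for i, nbrs in enumerate(lat.neighbours):
            for j in nbrs:
                d = np.linalg.norm(lat.cell_centres[i] - lat.cell_centres[j])
                assert d == pytest.approx(np.sqrt(3.0))

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            build_lattice("hex", 0, 3)
        with pytest.raises(ValueError):
            build_lattice("line", 2, 3)
        with pytest.raises(ValueError):
            build_lattice("triangle", 2, 2)


class TestVegfField:
    def test_front_row_receives_full_level(self):
        lat = build_lattice("hex", 3, 3)
        v = vegf_field(lat, VegfFieldSpec(Vext=2500.0, a=1.0, y0=0.0))
        np.testing.assert_allclose(v[:3], 2500.0)

    def test_flat_gradient_is_uniform(self):
        lat = build_lattice("hex", 3, 3)
        v = vegf_field(lat, VegfFieldSpec(Vext=2500.0, a=0.0))
        np.testing.assert_allclose(v, 2500.0)

    def test_exponential_decay_with_depth(self):
        lat = build_lattice("hex", 2, 1)
        # second row centre sits 1.5 below the front: V = Vext * exp(-1.5)
        v = vegf_field(lat, VegfFieldSpec(Vext=2500.0, a=1.0))
        assert v[1] == pytest.approx(2500.0 * np.exp(-1.5))

    def test_unit_depth_value(self):
        lat = build_lattice("hex", 2, 1)
        v = vegf_field(lat, VegfFieldSpec(Vext=2500.0, a=1.0, y0=0.5))
        assert v[1] == pytest.approx(2500.0 / np.e)  # cell 1.0 below the front row

    def test_line_geometry_is_uniform_at_front_level(self):
        lat = build_lattice("line", 1, 6)
        v = vegf_field(lat, VegfFieldSpec(Vext=2500.0, a=1.0))
        np.testing.assert_allclose(v, 2500.0)


class TestTransInputs:
    def test_two_cell_line_slot_average_halves_single_neighbour(self):
        lat = build_lattice("line", 1, 2)
        states = np.zeros((2, 5))
        states[:, 0] = [100.0, 40.0]
        t = trans_inputs(lat, states)  # slot rule: off-lattice slot contributes 0
        np.testing.assert_allclose(t.Dext, [20.0, 50.0])

    def test_truncate_boundary_divides_by_realized_neighbours(self):
        lat = build_lattice("line", 1, 2)
        states = np.zeros((2, 5))
        states[:, 0] = [100.0, 40.0]
        t = trans_inputs(lat, states, boundary="truncate")
        np.testing.assert_allclose(t.Dext, [40.0, 100.0])

    def test_isolated_cell_sees_nothing(self):
        lat = build_lattice("line", 1, 1)
        t = trans_inputs(lat, np.full((1, 5), 50.0))
        assert t.Dext[0] == 0.0 and t.Jext[0] == 0.0 and t.Next[0] == 0.0

    def test_external_stripe_addition(self):
        lat = build_lattice("line", 1, 3)
        lat.external_ligand = (np.zeros(3), np.array([0.0, 200.0, 0.0]))
        t = trans_inputs(lat, np.zeros((3, 5)))
        np.testing.assert_allclose(t.Jext, [0.0, 200.0, 0.0])

    def test_hex_interior_average_over_six_slots(self):
        lat = build_lattice("hex", 3, 3)
        states = np.zeros((9, 5))
        states[:, 0] = np.arange(9.0)
        t = trans_inputs(lat, states)
        centre = 4
        expected = np.mean([states[j, 0] for j in lat.neighbours[centre]])
        assert t.Dext[centre] == pytest.approx(expected)


class TestClassifyAndMetrics:
    def test_midpoint_split(self):
        np.testing.assert_array_equal(
            classify_tip_stalk(np.array([4000.0, 50.0])), ["tip", "stalk"]
        )
        np.testing.assert_array_equal(
            classify_tip_stalk(np.array([10.0, 11.0, 1000.0])),
            ["stalk", "stalk", "tip"],
        )

    def test_flat_population_is_uniform(self):
        labels = classify_tip_stalk(np.full(5, 123.0))
        assert np.all(labels == "uniform")

    def test_alternation_index_extremes(self):
        lat = build_lattice("line", 1, 10)
        alternating = np.array(["tip", "stalk"] * 5, dtype=object)
        same = np.full(10, "tip", dtype=object)
        assert pattern_metrics(alternating, lat).front_alternation_index == 1.0
        assert pattern_metrics(same, lat).front_alternation_index == 0.0
        assert pattern_metrics(alternating, lat).tip_fraction == 0.5

    def test_random_labels_alternate_about_half_the_time(self, rng):
        """Independent fair-coin labels produce an expected alternation of 1/2."""
        lat = build_lattice("line", 1, 200)
        labels = np.where(rng.random(200) < 0.5, "tip", "stalk").astype(object)
        idx = pattern_metrics(labels, lat).front_alternation_index
        assert idx == pytest.approx(0.5, abs=0.12)


class TestSimulateTissue:
    def test_deterministic_given_seed(self, table1):
        lat = build_lattice("hex", 3, 3)
        t1, s1 = simulate_tissue(lat, table1, model=2, t_end=20.0, h=0.05, seed=7)
        t2, s2 = simulate_tissue(lat, table1, model=2, t_end=20.0, h=0.05, seed=7)
        np.testing.assert_array_equal(t1.states, t2.states)
        assert list(s1.labels) == list(s2.labels)

    def test_different_seeds_differ(self, table1):
        lat = build_lattice("hex", 3, 3)
        t1, _ = simulate_tissue(lat, table1, model=2, t_end=5.0, h=0.05, seed=1)
        t2, _ = simulate_tissue(lat, table1, model=2, t_end=5.0, h=0.05, seed=2)
        assert np.any(t1.states != t2.states)

    def test_identical_cells_stay_uniform_under_truncate_boundary(self, table1):
        """With identical initial conditions and neighbour-count averaging,
        the perfectly symmetric tissue never desymmetrizes."""
        lat = build_lattice("hex", 3, 3)
        W = lat.coupling_matrix("truncate")

        def rhs(y):
            t = _Trans(W @ y[:, 0], W @ y[:, 1], W @ y[:, 3])
            return _rhs1_core(y, table1, t)

        y0 = np.full((9, 5), 50.0)
        traj = integrate(rhs, y0, h=0.05, t_end=50.0, steady_tol=0.0)
        spread = traj.states.max(axis=1) - traj.states.min(axis=1)
        # identical up to float summation order in the neighbour average
        assert np.max(spread) < 1e-9

    def test_lattice_mirror_symmetry_permutes_trajectory(self, table1):
        """Reversing a line of cells (a lattice automorphism) commutes with
        time evolution."""
        lat = build_lattice("line", 1, 4)
        W = lat.coupling_matrix()

        def rhs(y):
            t = _Trans(W @ y[:, 0], W @ y[:, 1], W @ y[:, 3])
            return _rhs1_core(y, table1, t)

        rng = np.random.default_rng(3)
        y0 = rng.uniform(0, 100, size=(4, 5))
        fwd = integrate(rhs, y0, h=0.05, t_end=20.0, steady_tol=0.0, record_every=1)
        rev = integrate(rhs, y0[::-1], h=0.05, t_end=20.0, steady_tol=0.0,
                        record_every=1)
        np.testing.assert_allclose(fwd.states, rev.states[:, ::-1, :], atol=1e-12)

    def test_trans_jag1_inert_when_affinity_zero(self, table1):
        """With alpha = 0, engineered trans-JAG1 stripes leave VEGFR2 activity
        untouched, while trans-DLL4 stripes suppress it in the stripe cells."""
        p = table1.with_(alpha=0.0)
        lat = build_lattice("line", 1, 8)
        base_traj, base = simulate_tissue(lat, p, model=2, t_end=1000.0, h=0.02, seed=5)
        stripe = np.zeros(8)
        stripe[2:4] = 200.0

        lat_j = build_lattice("line", 1, 8)
        lat_j.external_ligand = (np.zeros(8), stripe)
        _, with_j = simulate_tissue(lat_j, p, model=2, t_end=1000.0, h=0.02, seed=5)
        rel = np.abs(with_j.per_cell_final[:, 6] - base.per_cell_final[:, 6]) / (
            np.abs(base.per_cell_final[:, 6]) + 1e-12
        )
        assert np.max(rel) < 1e-6

        lat_d = build_lattice("line", 1, 8)
        lat_d.external_ligand = (25.0 * stripe, np.zeros(8))  # up to 5000 trans-DLL4
        _, with_d = simulate_tissue(lat_d, p, model=2, t_end=1000.0, h=0.02, seed=5)
        V_stripe = with_d.per_cell_final[2:4, 6]
        assert np.all(V_stripe < 0.5 * np.maximum(base.per_cell_final[2:4, 6], 10.0))


@pytest.fixture(scope="module")
def patterned_lattice(table1):
    """One converged baseline 10x10 hex simulation with the VEGF gradient."""
    lat = build_lattice("hex", 10, 10)
    traj, summary = simulate_tissue(lat, table1, model=2,
                                    vegf=VegfFieldSpec(2500.0, 1.0, 0.0), seed=0)
    return lat, traj, summary


class TestPatternedTissue:
    def test_front_row_alternates(self, patterned_lattice):
        _, traj, summary = patterned_lattice
        assert traj.converged
        assert summary.front_alternation_index >= 0.6

    def test_ligands_anticorrelate_across_cells(self, patterned_lattice):
        """Heterodimerization makes DLL4-high cells JAG1-low and vice versa."""
        _, traj, _ = patterned_lattice
        D, J = traj.final_state[:, 0], traj.final_state[:, 1]
        assert np.corrcoef(D, J)[0, 1] < -0.8

    def test_tip_cells_deplete_their_jag1(self, patterned_lattice):
        _, traj, summary = patterned_lattice
        tips = summary.labels == "tip"
        D, J = traj.final_state[:, 0], traj.final_state[:, 1]
        assert tips.any()
        assert np.all(J[tips] < 0.1 * D[tips])

    def test_tip_cells_have_high_dll4_low_notch_activity(self, patterned_lattice):
        _, traj, summary = patterned_lattice
        tips = summary.labels == "tip"
        D, S = traj.final_state[:, 0], traj.final_state[:, 4]
        front = slice(0, 10)
        assert D[front][tips[front]].min() > D[front][~tips[front]].max()
        assert S[front][tips[front]].max() < S[front][~tips[front]].min()
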