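"""Tree model, SWC I/O, eligibility rule, metrics, Sholl, dendrogram."""

from io import StringIO

import numpy as np
import pytest

from striaquant.morphometry import (
    ReconstructedNeuron,
    SWCParseError,
    dendrogram,
    read_swc,
    reconstruction_eligible,
    sholl,
    sholl_brute_force,
    tree_metrics,
    write_swc,
)

from conftest import build_neuron, random_neuron


class TestSWC:
    def test_minimal_two_node_file(self):
        n = read_swc("1 1 0 0 0 1 -1\n2 3 10 0 0 1 1\n")
        assert n.n_nodes == 2
        assert tree_metrics(n).n_primary_dendrites == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_identity(self, seed):
        neuron = random_neuron(np.random.default_rng(seed))
        buf = StringIO()
        write_swc(neuron, buf)
        back = read_swc(StringIO(buf.getvalue()))
        assert np.allclose(back.coords, neuron.coords, atol=1e-6)
        assert np.array_equal(back.parents, neuron.parents)

    def test_reindexes_shuffled_ids(self):
        # children declared before parents, non-consecutive ids
        text = "7 3 20 0 0 1 3\n3 3 10 0 0 1 5\n5 1 0 0 0 1 -1\n"
        n = read_swc(text)
        assert n.n_nodes == 3
        assert n.parents.tolist() == [-1, 0, 1]

    def test_missing_parent_names_line(self):
        with pytest.raises(SWCParseError, match="line 2"):
            read_swc("1 1 0 0 0 1 -1\n2 3 1 0 0 1 99\n")

    def test_multiple_roots_rejected(self):
        with pytest.raises(SWCParseError, match="multiple roots"):
            read_swc("1 1 0 0 0 1 -1\n2 1 5 0 0 1 -1\n")

    def test_cycle_rejected(self):
        text = "1 1 0 0 0 1 -1\n2 3 1 0 0 1 3\n3 3 2 0 0 1 2\n"
        with pytest.raises(SWCParseError, match="line"):
            read_swc(text)

    def test_wrong_column_count(self):
        with pytest.raises(SWCParseError, match="line 1"):
            read_swc("1 1 0 0 0 -1\n")


class TestEligibility:
    def make(self, endpoint_zs, thickness=50.0):
        edges = [(0, (10 * (i + 1), 0, z)) for i, z in enumerate(endpoint_zs)]
        return build_neuron(edges, soma=(0, 0, 25.0))

    def test_half_inside_is_eligible(self):
        n = self.make([10.0, 40.0, -5.0, 60.0])  # exactly 2 of 4 inside
        assert reconstruction_eligible(n, 50.0)

    def test_all_inside(self):
        assert reconstruction_eligible(self.make([5.0, 25.0, 45.0]), 50.0)

    def test_one_third_inside_not_eligible(self):
        assert not reconstruction_eligible(self.make([10.0, -5.0, 60.0]), 50.0)

    def test_no_endpoints_rejected(self):
        soma_only = ReconstructedNeuron(np.zeros((1, 3)), np.array([-1]))
        with pytest.raises(ValueError):
            reconstruction_eligible(soma_only, 50.0)


class TestTreeMetrics:
    def test_straight_dendrite(self, straight_neuron):
        m = tree_metrics(straight_neuron)
        assert m.total_length_um == pytest.approx(30.0)
        assert m.n_primary_dendrites == 1
        assert m.n_endpoints == 1
        assert m.path_distances_um.tolist() == pytest.approx([30.0])
        assert m.terminal_length_pct == pytest.approx(100.0)

    def test_y_tree(self, y_neuron):
        m = tree_metrics(y_neuron)
        assert m.total_length_um == pytest.approx(30.0)
        assert m.terminal_length_pct == pytest.approx(100 * 20 / 30)
        assert m.per_dendrite[0].n_endpoints == 2
        assert sorted(m.path_distances_um) == pytest.approx([20.0, 20.0])

    def test_three_primaries_additivity(self):
        n = build_neuron([(0, (5, 0, 0)), (0, (0, 5, 0)), (0, (-5, 0, 0))])
        m = tree_metrics(n)
        assert m.n_primary_dendrites == 3
        assert m.total_length_um == pytest.approx(15.0)
        assert m.terminal_length_pct == pytest.approx(100.0)
        assert [d.length_um for d in m.per_dendrite] == pytest.approx([5.0] * 3)

    def test_complete_flag_per_dendrite(self):
        # dendrite 1 ends inside the 50 μm section, dendrite 2 ends outside
        n = build_neuron(
            [(0, (10, 0, 25)), (0, (0, 10, 80))], soma=(0, 0, 25)
        )
        m = tree_metrics(n, section_thickness_um=50.0)
        assert [d.complete for d in m.per_dendrite] == [True, False]

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = random_neuron(rng)
        theta = rng.uniform(0, 2 * np.pi)
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = ReconstructedNeuron(n.coords @ R.T + rng.normal(0, 50, 3), n.parents)
        m0, m1 = tree_metrics(n), tree_metrics(moved)
        assert m1.total_length_um == pytest.approx(m0.total_length_um)
        assert m1.terminal_length_pct == pytest.approx(m0.terminal_length_pct)
        assert np.allclose(
            np.sort(m1.path_distances_um), np.sort(m0.path_distances_um)
        )
        assert sholl(moved).intersections == sholl(n).intersections

    @pytest.mark.parametrize("seed", range(5))
    def test_uniform_scaling(self, seed):
        rng = np.random.default_rng(seed)
        n = random_neuron(rng)
        c = 2.5
        scaled = ReconstructedNeuron(n.coords * c, n.parents)
        m0, m1 = tree_metrics(n), tree_metrics(scaled)
        assert m1.total_length_um == pytest.approx(c * m0.total_length_um)
        assert m1.n_primary_dendrites == m0.n_primary_dendrites
        assert m1.terminal_length_pct == pytest.approx(m0.terminal_length_pct)
        radii = (4.0, 11.0, 23.0)
        assert (
            sholl(scaled, tuple(c * r for r in radii)).intersections
            == sholl(n, radii).intersections
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_path_distance_dominates_euclidean(self, seed):
        n = random_neuron(np.random.default_rng(seed))
        m = tree_metrics(n)
        eps = n.endpoints()
        euclid = np.linalg.norm(n.coords[eps] - n.coords[0], axis=1)
        assert np.all(m.path_distances_um >= euclid - 1e-9)


class TestSholl:
    def test_single_radial_dendrite(self):
        n = build_neuron([(0, (35, 0, 0))])
        assert sholl(n).intersections == (1, 1, 1)

    def test_bifurcating_radial_tree(self):
        # trunk to 15 μm, then two branches reaching 35 μm radial distance
        n = build_neuron(
            [(0, (15, 0, 0)), (1, (35, 8, 0)), (1, (35, -8, 0))]
        )
        assert sholl(n).intersections == (1, 2, 2)
        assert sholl_brute_force(n).intersections == (1, 2, 2)

    def test_short_dendrite_no_crossings(self):
        n = build_neuron([(0, (5, 0, 0))])
        assert sholl(n).intersections == (0, 0, 0)

    def test_segment_crossing_circle_twice(self):
        # chord passing near the soma: enters and exits the r=10 circle
        n = build_neuron([(0, (15, 0, 0)), (1, (-15, 1, 0))])
        counts = sholl(n, (10.0,)).intersections
        assert counts == (3,)  # trunk exits once, chord crosses twice
        assert sholl_brute_force(n, (10.0,)).intersections == counts

    def test_projection_ignores_z(self):
        flat = build_neuron([(0, (35, 0, 0))])
        tilted = build_neuron([(0, (35, 0, 40))])
        assert sholl(tilted).intersections == sholl(flat).intersections

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = random_neuron(rng, n_nodes=20)
        radii = (5.0, 12.0, 21.0, 33.0)
        assert (
            sholl(n, radii).intersections
            == sholl_brute_force(n, radii).intersections
        )

    def test_invalid_radii(self):
        n = build_neuron([(0, (35, 0, 0))])
        with pytest.raises(ValueError):
            sholl(n, (10.0, 10.0))
        with pytest.raises(ValueError):
            sholl(n, (-1.0, 5.0))


class TestDendrogram:
    def test_unbranched_single_bar(self, straight_neuron):
        d = dendrogram(straight_neuron)
        assert len(d.children) == 1
        assert d.children[0].length_um == pytest.approx(30.0)
        assert d.children[0].children == []

    def test_y_tree_topology(self, y_neuron):
        d = dendrogram(y_neuron)
        trunk = d.children[0]
        assert trunk.length_um == pytest.approx(10.0)
        assert sorted(c.length_um for c in trunk.children) == pytest.approx(
            [10.0, 10.0]
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_length_conservation(self, seed):
        n = random_neuron(np.random.default_rng(seed))
        assert dendrogram(n).total_length() == pytest.approx(
            tree_metrics(n).total_length_um
        )
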