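"""Proximity factors, strengths and interconnectivity networks."""

import numpy as np
import pytest

import lidtraj as lt
from lidtraj.core import AtomRecord, Frame, Topology, Trajectory
from lidtraj.proximity import ProximityMatrix, geometric_mean, resolve_window


def _pair_system(distances):
    """Two single-atom residues whose separation follows `distances` in time."""
    topo = Topology(
        [
            AtomRecord(1, "CA", "C", 1, "ALA", "A"),
            AtomRecord(2, "CA", "C", 10, "ALA", "A"),
        ]
    )
    frames = [
        Frame(np.array([[0.0, 0, 0], [d, 0, 0]]), time=float(t))
        for t, d in enumerate(distances)
    ]
    traj = Trajectory(topo, frames)
    r1, r2 = topo.residues()
    return traj, r1, r2


class TestProximityFactor:
    def test_constant_distance_returns_it(self):
        traj, r1, r2 = _pair_system([2.5] * 6)
        assert lt.proximity_factor(traj, r1, r2) == pytest.approx(2.5)

    def test_one_and_four_give_two(self):
        # geometric mean of 1 A and 4 A is sqrt(4) = 2 A
        traj, r1, r2 = _pair_system([1.0, 4.0])
        assert lt.proximity_factor(traj, r1, r2) == pytest.approx(2.0)

    def test_single_frame_window_degenerates_to_min_distance(self):
        traj, r1, r2 = _pair_system([3.7])
        p = lt.proximity_factor(traj, r1, r2, window=np.array([0]))
        assert p == pytest.approx(3.7)

    def test_am_gm_bound_on_random_windows(self, rng):
        # P_ij <= arithmetic mean, equality only for constant distance
        for _ in range(20):
            d = rng.uniform(0.5, 12.0, size=rng.integers(2, 30))
            traj, r1, r2 = _pair_system(d)
            p = lt.proximity_factor(traj, r1, r2)
            assert p <= d.mean() + 1e-12
            if np.ptp(d) > 1e-9:
                assert p < d.mean()

    def test_matches_direct_product_oracle(self, rng):
        # log-space evaluation equals the naive product-then-root on
        # windows short enough not to overflow
        d = rng.uniform(0.5, 9.0, size=12)
        traj, r1, r2 = _pair_system(d)
        naive = float(np.prod(d) ** (1.0 / len(d)))
        assert lt.proximity_factor(traj, r1, r2) == pytest.approx(naive, rel=1e-12)

    def test_zero_distance_is_clamped_not_crashed(self):
        traj, r1, r2 = _pair_system([0.0, 4.0])
        p = lt.proximity_factor(traj, r1, r2)
        assert p > 0


class TestWindows:
    def test_first_and_last_fraction(self, toy_complex):
        topo, frame, regions = toy_complex
        spec = lt.preset_spec("rigid", regions, seed=1, n_frames=50)
        traj, _ = lt.generate_trajectory(spec, (topo, frame))
        first = resolve_window(traj, "first:0.2")
        last = resolve_window(traj, "last:0.2")
        np.testing.assert_array_equal(first, np.arange(10))
        np.testing.assert_array_equal(last, np.arange(40, 50))

    def test_time_pair_window(self, toy_complex):
        topo, frame, regions = toy_complex
        spec = lt.preset_spec("rigid", regions, seed=1, n_frames=20)
        traj, _ = lt.generate_trajectory(spec, (topo, frame))
        idx = resolve_window(traj, (50.0, 90.0))
        np.testing.assert_array_equal(idx, np.arange(5, 10))

    def test_bad_specs_rejected(self, toy_complex):
        topo, frame, regions = toy_complex
        spec = lt.preset_spec("rigid", regions, seed=1, n_frames=5)
        traj, _ = lt.generate_trajectory(spec, (topo, frame))
        with pytest.raises(ValueError):
            resolve_window(traj, "middle:0.5")
        with pytest.raises(ValueError):
            resolve_window(traj, (1e6, 2e6))


class TestStrengths:
    @pytest.mark.parametrize("p,s", [(1.0, 1.0), (2.0, 0.5), (0.25, 4.0)])
    def test_inverse(self, p, s):
        assert lt.interaction_strength(p) == pytest.approx(s)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            lt.interaction_strength(0.0)

    def test_strength_times_proximity_is_one(self, rng):
        for p in rng.uniform(0.1, 20, size=20):
            assert lt.interaction_strength(p) * p == pytest.approx(1.0, rel=1e-15)

    def test_composition_with_geometric_mean(self):
        traj, r1, r2 = _pair_system([1.0, 4.0])
        p = lt.proximity_factor(traj, r1, r2)
        assert lt.interaction_strength(p) == pytest.approx(0.5)

    def test_normalized_strengths(self):
        s = {("S595", "N1"): 4.0, ("A592", "N1"): 2.0, ("Q596", "N1"): 4.0}
        out = lt.normalized_strengths(s, ("S595", "N1"))
        assert out[("S595", "N1")] == 1.0
        assert out[("A592", "N1")] == pytest.approx(0.5)  # P twice the ref's
        assert out[("Q596", "N1")] == pytest.approx(1.0)

    def test_all_equal_strengths_normalize_to_one(self):
        s = {k: 3.3 for k in ["a", "b", "c"]}
        assert all(v == pytest.approx(1.0) for v in
                   lt.normalized_strengths(s, "b").values())

    def test_missing_reference_pair(self):
        with pytest.raises(KeyError):
            lt.normalized_strengths({"a": 1.0}, "zz")


class TestNetworks:
    def test_all_pairs_above_cutoff_give_empty_network(self):
        m = ProximityMatrix((0, 1, 2), {(1, 10): 5.0, (2, 20): 6.0})
        net = lt.build_network(m, cutoff=4.0)
        assert net.edges == []

    def test_direct_filter_example(self):
        m = ProximityMatrix((0, 1, 2), {(1, 10): 3.0, (2, 20): 4.5})
        net = lt.build_network(m, cutoff=4.0, min_sequence_separation=4)
        assert net.edges == [(1, 10, 3.0)]

    def test_sequence_separation_filter(self):
        m = ProximityMatrix((0, 1, 2), {(1, 3): 2.0, (1, 10): 2.0})
        net = lt.build_network(m, cutoff=4.0, min_sequence_separation=4)
        assert net.edge_pairs() == {(1, 10)}

    def test_enlarging_cutoff_never_removes_edges(self, rng):
        pairs = {
            (int(i), int(i) + int(j)): float(p)
            for i, j, p in zip(
                rng.integers(1, 50, 30),
                rng.integers(4, 30, 30),
                rng.uniform(1, 8, 30),
            )
        }
        m = ProximityMatrix((0, 1, 2), pairs)
        prev: set = set()
        for cutoff in (2.0, 3.0, 4.5, 6.0, 8.0):
            edges = lt.build_network(m, cutoff=cutoff).edge_pairs()
            assert prev <= edges
            prev = edges

    def test_matrix_and_network_match_brute_force_on_toy(self, toy_complex):
        # <=10-residue instance: every pair recomputed independently with
        # the naive product-then-root evaluation
        topo, frame, regions = toy_complex
        spec = lt.preset_spec("approach", regions, seed=23, n_frames=30)
        traj, _ = lt.generate_trajectory(spec, (topo, frame))
        residues = regions.residues_in("lid", topo)
        assert len(residues) == 10
        m = lt.proximity_matrix(traj, residues, window="last:0.5")
        frames = range(15, 30)
        for (i, j), p in m.pairs.items():
            ri = next(r for r in residues if r.number == i)
            rj = next(r for r in residues if r.number == j)
            per_frame = []
            for k in frames:
                c = traj.frames[k].coordinates
                per_frame.append(
                    min(
                        np.linalg.norm(c[a] - c[b])
                        for a in ri.atom_indices
                        for b in rj.atom_indices
                    )
                )
            naive = float(np.prod(per_frame) ** (1 / len(per_frame)))
            assert p == pytest.approx(naive, rel=1e-9)
        net = lt.build_network(m, cutoff=10.0, min_sequence_separation=2)
        expected = {
            (i, j) for (i, j), p in m.pairs.items()
            if p <= 10.0 and j - i >= 2
        }
        assert net.edge_pairs() == expected

    def test_symmetric_storage_and_no_self_edges(self):
        m = ProximityMatrix((0, 1, 2), {(2, 5): 1.5})
        assert m.get(5, 2) == m.get(2, 5)
        with pytest.raises(ValueError):
            lt.InteractionNetwork(nodes=[1], edges=[(1, 1, 1.0)], cutoff=4.0)


class TestCommonContacts:
    def _nets(self, *edge_sets):
        out = []
        for k, es in enumerate(edge_sets):
            edges = sorted((i, j, 1.0) for i, j in es)
            nodes = sorted({i for i, _ in es} | {j for _, j in es})
            out.append(
                lt.InteractionNetwork(nodes=nodes, edges=edges, cutoff=4.0,
                                      label=str(k))
            )
        return out

    def test_identical_networks_share_everything(self):
        es = {(1, 10), (2, 20)}
        nets = self._nets(es, es, es)
        assert lt.common_contacts(nets, k=3) == es

    def test_disjoint_networks_share_nothing(self):
        nets = self._nets({(1, 10)}, {(2, 20)})
        assert lt.common_contacts(nets, k=2) == set()

    def test_default_k_is_all_but_one(self):
        nets = self._nets({(1, 10), (2, 20)}, {(1, 10)}, {(1, 10), (3, 30)})
        assert lt.common_contacts(nets) == {(1, 10)}

    def test_reference_sets_strict_intersection(self):
        # the five published condition blocks share exactly one pair
        refs = lt.load_reference_contact_sets()
        assert set(refs) == {"crystal", "WT", "N1R", "R2A", "K577E"}
        strict = lt.common_contacts(list(refs.values()), k=5)
        assert strict == {(547, 573)}

    def test_reference_sets_majority_contacts(self):
        refs = lt.load_reference_contact_sets()
        most = lt.common_contacts(list(refs.values()), k=4)
        assert most == {
            (531, 581), (536, 576), (536, 579),
            (538, 588), (546, 569), (547, 573),
        }

    def test_reference_crystal_block_values(self):
        refs = lt.load_reference_contact_sets()
        crystal = dict(
            ((i, j), p) for i, j, p in refs["crystal"].edges
        )
        assert crystal[(531, 581)] == pytest.approx(2.23)
        assert crystal[(536, 576)] == pytest.approx(2.68)
        assert crystal[(547, 573)] == pytest.approx(2.22)
        assert (536, 576) in refs["crystal"].edge_pairs()
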