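"""Superposition and distance primitives against hand and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import lidtraj as lt
from lidtraj.core import AtomRecord, Frame, Topology, Trajectory
from lidtraj.errors import DegenerateFitError, SelectionError
from lidtraj.geometry import min_distance


def _point_topology(n, element="C", chain="A"):
    return Topology(
        [
            AtomRecord(serial=i + 1, name="CA", element=element,
                       residue_number=i + 1, residue_name="ALA", chain_id=chain)
            for i in range(n)
        ]
    )


def _svd_kabsch(X, Y):
    """Independent textbook Kabsch: rotation mapping centred X onto centred Y."""
    xc, yc = X.mean(0), Y.mean(0)
    H = (X - xc).T @ (Y - yc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1, 1, d]) @ U.T
    return R, yc - R @ xc


class TestKabsch:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.coords = rng.normal(size=(12, 3)) * 4.0
        self.sel = np.arange(12)

    def test_identity(self):
        f = Frame(self.coords)
        tf, fitted = lt.kabsch_fit(f, Frame(self.coords.copy()), self.sel)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-9)
        np.testing.assert_allclose(fitted.coordinates, self.coords, atol=1e-9)

    def test_pure_translation_recovered(self):
        mobile = Frame(self.coords + np.array([5.0, 0.0, 0.0]))
        tf, fitted = lt.kabsch_fit(mobile, Frame(self.coords), self.sel)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tf.translation, [-5.0, 0.0, 0.0], atol=1e-9)
        np.testing.assert_allclose(fitted.coordinates, self.coords, atol=1e-9)

    def test_known_rotation_inverted(self):
        R = Rotation.from_euler("xyz", [0.4, -1.1, 2.0]).as_matrix()
        mobile = Frame(self.coords @ R.T)
        tf, fitted = lt.kabsch_fit(mobile, Frame(self.coords), self.sel)
        np.testing.assert_allclose(tf.rotation, R.T, atol=1e-6)
        np.testing.assert_allclose(fitted.coordinates, self.coords, atol=1e-6)

    def test_matches_textbook_svd_oracle(self, rng):
        X = rng.normal(size=(20, 3)) * 3
        Y = X @ Rotation.random(random_state=3).as_matrix().T + rng.normal(
            size=(20, 3), scale=0.3
        )
        tf, _ = lt.kabsch_fit(Frame(X), Frame(Y), np.arange(20))
        R, t = _svd_kabsch(X, Y)
        np.testing.assert_allclose(tf.rotation, R, atol=1e-8)
        np.testing.assert_allclose(tf.translation, t, atol=1e-8)

    def test_deviation_never_increases_and_rigid_invariance(self, rng):
        # two properties over random clouds: fitting cannot worsen the
        # deviation, and any rigid pre-transform of the mobile frame leaves
        # the post-fit deviation unchanged
        for _ in range(10):
            X = rng.normal(size=(15, 3)) * 2
            Y = X + rng.normal(size=(15, 3), scale=0.5)
            sel = np.arange(15)
            _, fitted = lt.kabsch_fit(Frame(Y), Frame(X), sel)
            pre = ((Y - X) ** 2).sum()
            post = ((fitted.coordinates - X) ** 2).sum()
            assert post <= pre + 1e-10

            R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            t = rng.normal(size=3) * 10
            _, fitted2 = lt.kabsch_fit(Frame(Y @ R.T + t), Frame(X), sel)
            post2 = ((fitted2.coordinates - X) ** 2).sum()
            assert post2 == pytest.approx(post, abs=1e-8)

    def test_mass_weighted_fit_prefers_heavy_atoms(self):
        # two-mass system: with one dominant mass the fit centres on it
        X = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        Y = X.copy()
        Y[0] += [0.5, 0, 0]
        masses = np.array([1000.0, 1.0, 1.0, 1.0])
        tf_w, _ = lt.kabsch_fit(
            Frame(Y), Frame(X), np.arange(4), masses=masses, mass_weighted=True
        )
        tf_u, _ = lt.kabsch_fit(Frame(Y), Frame(X), np.arange(4))
        # the weighted fit follows the dominant mass much more closely
        # than the unweighted fit (which splits the shift over 4 atoms)
        assert tf_w.translation[0] < -0.4
        assert -0.2 < tf_u.translation[0] <= 0.0

    @pytest.mark.parametrize(
        "coords",
        [
            np.array([[0.0, 0, 0], [1, 0, 0]]),                      # <3 atoms
            np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]),  # collinear
        ],
    )
    def test_degenerate_selections_rejected(self, coords):
        with pytest.raises(DegenerateFitError):
            lt.kabsch_fit(Frame(coords), Frame(coords.copy()),
                          np.arange(len(coords)))

    def test_reflection_is_never_returned(self, rng):
        X = rng.normal(size=(10, 3))
        Y = X.copy()
        Y[:, 0] *= -1  # mirrored cloud
        tf, _ = lt.kabsch_fit(Frame(Y), Frame(X), np.arange(10))
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)


class TestMinResidueDistance:
    def test_coincident_atoms_give_zero(self):
        topo = _point_topology(2)
        f = Frame(np.array([[1.0, 1, 1], [1.0, 1, 1]]))
        assert lt.min_residue_distance(f, topo, np.array([0]), np.array([1])) == 0.0

    def test_four_pair_example(self):
        topo = _point_topology(4)
        f = Frame(np.array([[0.0, 0, 0], [1, 0, 0], [4, 0, 0], [9, 0, 0]]))
        d = lt.min_residue_distance(
            f, topo, np.array([0, 1]), np.array([2, 3])
        )
        assert d == pytest.approx(3.0)

    def test_brute_force_oracle_equivalence(self, rng):
        topo = _point_topology(60)
        for _ in range(5):
            coords = rng.normal(size=(60, 3)) * 8
            f = Frame(coords)
            a = rng.choice(60, size=25, replace=False)
            b = np.setdiff1d(np.arange(60), a)
            expected = min(
                np.linalg.norm(coords[i] - coords[j]) for i in a for j in b
            )
            assert min_distance(f, a, b) == pytest.approx(expected, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        topo = _point_topology(20)
        coords = rng.normal(size=(20, 3)) * 5
        a, b = np.arange(10), np.arange(10, 20)
        d0 = min_distance(Frame(coords), a, b)
        R = Rotation.random(random_state=11).as_matrix()
        moved = coords @ R.T + np.array([3.0, -7.0, 1.0])
        assert min_distance(Frame(moved), a, b) == pytest.approx(d0, abs=1e-9)

    def test_hydrogens_excluded_by_default(self):
        topo = Topology(
            [
                AtomRecord(1, "CA", "C", 1, "ALA", "A"),
                AtomRecord(2, "HA", "H", 1, "ALA", "A"),
                AtomRecord(3, "CA", "C", 2, "ALA", "A"),
            ]
        )
        f = Frame(np.array([[0.0, 0, 0], [4.0, 0, 0], [5.0, 0, 0]]))
        heavy = lt.min_residue_distance(
            f, topo, np.array([0, 1]), np.array([2]), atom_subset="heavy"
        )
        everything = lt.min_residue_distance(
            f, topo, np.array([0, 1]), np.array([2]), atom_subset="all"
        )
        assert heavy == pytest.approx(5.0)
        assert everything == pytest.approx(1.0)

    def test_empty_after_filter_is_an_error(self):
        topo = Topology([AtomRecord(1, "HA", "H", 1, "ALA", "A"),
                         AtomRecord(2, "CA", "C", 2, "ALA", "A")])
        f = Frame(np.zeros((2, 3)))
        with pytest.raises(SelectionError):
            lt.min_residue_distance(f, topo, np.array([0]), np.array([1]),
                                    atom_subset="heavy")


class TestRmsf:
    def test_static_trajectory_is_zero(self, toy_complex):
        topo, frame, _ = toy_complex
        frames = [Frame(frame.coordinates.copy(), time=float(t)) for t in range(4)]
        traj = Trajectory(topo, frames)
        per_atom, mean = lt.rmsf(traj, np.arange(topo.n_atoms))
        np.testing.assert_allclose(per_atom, 0.0, atol=1e-12)
        assert mean == 0.0

    def test_alternating_displacement_gives_unit_rmsf(self):
        topo = _point_topology(4)
        base = np.zeros((4, 3))
        frames = []
        for t in range(6):
            c = base.copy()
            c[0, 0] = 1.0 if t % 2 == 0 else -1.0
            frames.append(Frame(c, time=float(t)))
        per_atom, _ = lt.rmsf(Trajectory(topo, frames), np.arange(4))
        assert per_atom[0] == pytest.approx(1.0)
        np.testing.assert_allclose(per_atom[1:], 0.0, atol=1e-12)

    def test_fit_removes_rigid_body_translation(self, rng):
        topo = _point_topology(10)
        base = rng.normal(size=(10, 3)) * 3
        frames = [
            Frame(base + np.array([2.0 * t, -t, 0.5 * t]), time=float(t))
            for t in range(5)
        ]
        traj = Trajectory(topo, frames)
        ref = Frame(base)
        per_atom, mean = lt.rmsf(traj, np.arange(10), fit=(ref, np.arange(10)))
        assert mean < 1e-9

    def test_single_frame_is_an_error(self, toy_complex):
        topo, frame, _ = toy_complex
        traj = Trajectory(topo, [frame])
        with pytest.raises(ValueError, match="single-frame"):
            lt.rmsf(traj, np.arange(topo.n_atoms))


class TestComDistance:
    def test_identical_groups_give_zero(self, toy_complex):
        topo, frame, _ = toy_complex
        traj = Trajectory(topo, [frame])
        idx = np.arange(10)
        series, mean, sd = lt.com_distance(traj, idx, idx)
        np.testing.assert_allclose(series, 0.0, atol=1e-12)

    def test_two_point_groups_five_apart(self):
        topo = _point_topology(2, element="H")
        f = Frame(np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        series, mean, sd = lt.com_distance(
            Trajectory(topo, [f]), np.array([0]), np.array([1])
        )
        assert mean == pytest.approx(5.0)
        assert sd == 0.0

    def test_whole_system_translation_invariance(self, toy_complex, rng):
        topo, frame, regions = toy_complex
        a = regions.resolve("core", topo)
        b = regions.resolve("peptide", topo)
        d0 = lt.com_distance(Trajectory(topo, [frame]), a, b)[1]
        shifted = Frame(frame.coordinates + rng.normal(size=3) * 20)
        d1 = lt.com_distance(Trajectory(topo, [shifted]), a, b)[1]
        assert d1 == pytest.approx(d0, abs=1e-9)
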