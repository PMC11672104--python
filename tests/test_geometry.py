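"""Helix axes, interhelix/hinge angles, distances, salt-bridge occupancy."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tncoupling.geometry import (
    GeometryError,
    hinge_angle,
    helix_axis,
    interdomain_distance,
    interhelix_angle,
    pair_bond_occupancy,
)
from tncoupling.io import RegionSpec, Topology, Trajectory, Atom

from conftest import make_topology, random_rotation


def line_points(direction, n=10, origin=(0.0, 0.0, 0.0), rise=1.5):
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    return np.asarray(origin) + rise * np.arange(n)[:, None] * direction


class TestHelixAxis:
    def test_straight_line_along_z(self):
        axis = helix_axis(line_points([0, 0, 1]))
        np.testing.assert_allclose(axis, [0, 0, 1], atol=1e-9)

    def test_rotated_line_gives_rotated_axis(self, rng):
        r = random_rotation(rng)
        pts = line_points([0, 0, 1]) @ r.T
        np.testing.assert_allclose(helix_axis(pts), r @ np.array([0, 0, 1]), atol=1e-6)

    def test_reversed_order_flips_sign(self):
        pts = line_points([0, 0, 1])
        np.testing.assert_allclose(helix_axis(pts[::-1]), -helix_axis(pts), atol=1e-9)

    def test_too_few_atoms_and_degenerate(self):
        with pytest.raises(GeometryError, match=">= 4"):
            helix_axis(line_points([0, 0, 1], n=3))
        with pytest.raises(GeometryError, match="degenerate"):
            helix_axis(np.ones((5, 3)))


class TestInterhelixAngle:
    def test_parallel_is_zero(self):
        a = line_points([0, 0, 1])
        b = line_points([0, 0, 1], origin=(5, 0, 0))
        assert interhelix_angle(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_is_ninety(self):
        assert interhelix_angle(line_points([0, 0, 1]), line_points([1, 0, 0])) == pytest.approx(90.0)

    def test_planted_wild_type_mean_angle(self):
        """Helix B rotated 101.81 deg from helix A about their common normal."""
        theta = np.radians(101.81)
        b_dir = [0.0, -np.sin(theta), np.cos(theta)]
        angle = interhelix_angle(line_points([0, 0, 1]), line_points(b_dir, origin=(8, 0, 0)))
        assert angle == pytest.approx(101.81, abs=0.1)

    def test_symmetry(self, rng):
        a = line_points(rng.normal(size=3))
        b = line_points(rng.normal(size=3), origin=(4, 4, 0))
        assert interhelix_angle(a, b) == pytest.approx(interhelix_angle(b, a), abs=1e-9)


class TestHingeAngle:
    def test_collinear_through_pivot(self):
        assert hinge_angle([0, 0, 0], [[-5, 0, 0]], [[5, 0, 0]]) == pytest.approx(180.0)

    def test_right_angle_corner(self):
        assert hinge_angle([0, 0, 0], [[0, 7, 0]], [[3, 0, 0]]) == pytest.approx(90.0)

    def test_planted_wild_type_hinge(self):
        th = np.radians(121.61)
        d1 = 20.0 * np.array([np.cos(th), np.sin(th), 0.0])
        assert hinge_angle([0, 0, 0], [d1], [[15.0, 0, 0]]) == pytest.approx(121.61, abs=0.1)

    def test_pivot_on_centroid_errors(self):
        with pytest.raises(GeometryError, match="zero-length"):
            hinge_angle([1, 1, 1], [[1, 1, 1]], [[5, 0, 0]])


class TestInterdomainDistance:
    def test_two_single_atoms(self):
        assert interdomain_distance([[0, 0, 0]], [[30.18, 0, 0]]) == pytest.approx(30.18)

    def test_translation_shifts_distance(self):
        d0 = interdomain_distance([[0, 0, 0]], [[10, 0, 0]])
        d1 = interdomain_distance([[0, 0, 0]], [[13, 0, 0]])
        assert d1 - d0 == pytest.approx(3.0)

    def test_rotation_invariance(self, rng):
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(4, 3)) + 20
        r = random_rotation(rng)
        assert interdomain_distance(a @ r.T, b @ r.T) == pytest.approx(
            interdomain_distance(a, b), abs=1e-9
        )


def _pair_topology(with_acceptor: bool) -> Topology:
    atoms = [Atom(0, "CA", "C", 1, "ARG", "C"), Atom(1, "NH1", "N", 1, "ARG", "C")]
    if with_acceptor:
        atoms.append(Atom(2, "OD1", "O", 2, "ASP", "C"))
    else:
        atoms.append(Atom(2, "CA", "C", 2, "GLY", "C"))
    return Topology(atoms)


class TestPairBondOccupancy:
    def test_fraction_below_cutoff(self):
        topo = _pair_topology(True)
        coords = np.zeros((3, 3, 3))
        for f, d in enumerate([3.2, 4.5, 3.8]):
            coords[f, 2] = [d, 0, 0]
        traj = Trajectory(coords)
        nh = RegionSpec.chain_range("nh", "C", 1, 1, atom_names=("NH1",))
        od = RegionSpec.chain_range("od", "C", 2, 2, atom_names=("OD1",))
        occ, series = pair_bond_occupancy(traj, topo, od, nh, cutoff=4.0)
        assert occ == pytest.approx(2 / 3)
        assert list(series.bound) == [True, False, True]

    def test_wild_type_glycine_has_zero_occupancy(self):
        """No carboxylate atoms to select: ionic-bond probability is 0 by definition."""
        topo = _pair_topology(False)
        traj = Trajectory(np.zeros((4, 3, 3)))
        nh = RegionSpec.chain_range("nh", "C", 1, 1, atom_names=("NH1",))
        od = RegionSpec.chain_range("od", "C", 2, 2, atom_names=("OD1", "OD2"))
        occ, series = pair_bond_occupancy(traj, topo, od, nh, cutoff=4.0)
        assert occ == 0.0
        assert not series.bound.any()

    def test_invalid_cutoff(self):
        topo = _pair_topology(True)
        traj = Trajectory(np.zeros((1, 3, 3)))
        nh = RegionSpec.chain_range("nh", "C", 1, 1, atom_names=("NH1",))
        od = RegionSpec.chain_range("od", "C", 2, 2, atom_names=("OD1",))
        with pytest.raises(GeometryError, match="cutoff"):
            pair_bond_occupancy(traj, topo, od, nh, cutoff=0.0)

    @given(st.integers(0, 2**31 - 1))
    def test_occupancy_monotone_in_cutoff(self, seed):
        """Occupancy at a wider cutoff is never smaller than at a narrower one."""
        topo = _pair_topology(True)
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 6, size=(10, 3, 3))
        traj = Trajectory(coords)
        nh = RegionSpec.chain_range("nh", "C", 1, 1, atom_names=("NH1",))
        od = RegionSpec.chain_range("od", "C", 2, 2, atom_names=("OD1",))
        occ_wide, _ = pair_bond_occupancy(traj, topo, od, nh, cutoff=4.5)
        occ_narrow, _ = pair_bond_occupancy(traj, topo, od, nh, cutoff=4.0)
        assert occ_wide >= occ_narrow


class TestRigidTransformInvariance:
    def test_all_metrics_invariant_under_global_rigid_transform(self, wt_bundle, rng):
        """Rotating+translating a frame leaves angle and distance metrics unchanged."""
        from tncoupling.io import resolve
        from tncoupling.geometry import (
            interhelix_angle as ih, hinge_angle as ha, interdomain_distance as dd,
        )

        topo, regions = wt_bundle.topology, wt_bundle.regions
        frame = wt_bundle.runs[0].coordinates[0]
        r = random_rotation(rng)
        t = rng.normal(size=3) * 30
        moved = frame @ r.T + t

        ia = resolve(regions["helix_a"], topo)
        ib = resolve(regions["helix_b"], topo)
        i1 = resolve(regions["nc_lobe"], topo)
        i2 = resolve(regions["itc_domain"], topo)
        ip = resolve(regions["pivot"], topo)
        assert ih(moved[ia], moved[ib]) == pytest.approx(ih(frame[ia], frame[ib]), abs=1e-6)
        assert ha(moved[ip], moved[i1], moved[i2]) == pytest.approx(
            ha(frame[ip], frame[i1], frame[i2]), abs=1e-6
        )
        assert dd(moved[i1], moved[i2]) == pytest.approx(dd(frame[i1], frame[i2]), abs=1e-6)
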