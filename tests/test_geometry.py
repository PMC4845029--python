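"""Agonist-site geometry: centroids, pocket volume, axes, torsions, H-bonds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sitecraft.errors import DegenerateGeometryError, UsageError
from sitecraft.geometry import (
    HBondSpec,
    RingSpec,
    classify_ring_pair,
    detect_hbond,
    dihedral,
    hairpin_tilt,
    hairpin_twist,
    hbond_occupancy,
    pocket_volume,
    ring_centroid,
    ring_orientation,
    strand_axis,
    tau2_basin_fractions,
    tetrahedron_volume,
)
from sitecraft.io import AtomRecord, Selection, Snapshot
from sitecraft.synthetic import make_hbond_series, make_pocket_snapshot

from conftest import random_rigid_motion


def _ring_snapshot(coords):
    atoms = [
        AtomRecord(serial=i + 1, name=f"C{i}", residue_name="PHE", chain="R",
                   residue_number=1, element="C")
        for i in range(len(coords))
    ]
    return Snapshot(atoms=atoms, coords=np.asarray(coords, float))


def _ring_spec(n, label="r"):
    return RingSpec(label=label, atom_names=[f"C{i}" for i in range(n)],
                    selection=Selection(expression=label, resolved=list(range(n))))


class TestRingCentroid:
    def test_hexagon_centre_and_translation(self, hexagon):
        snap = _ring_snapshot(hexagon)
        np.testing.assert_allclose(ring_centroid(snap, _ring_spec(6)), 0.0, atol=1e-12)
        snap2 = _ring_snapshot(hexagon + np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(
            ring_centroid(snap2, _ring_spec(6)), [1.0, 2.0, 3.0], atol=1e-12
        )

    def test_five_atom_ring_is_plain_average(self, hexagon):
        snap = _ring_snapshot(hexagon[:5])
        np.testing.assert_allclose(
            ring_centroid(snap, _ring_spec(5)), hexagon[:5].mean(axis=0), atol=1e-12
        )


class TestPocketVolume:
    # unit regular tetrahedron ABCD and E = mirror of D through the ABC plane
    A = np.array([0.0, 0.0, 0.0])
    B = np.array([1.0, 0.0, 0.0])
    C = np.array([0.5, math.sqrt(3) / 2, 0.0])
    D = np.array([0.5, math.sqrt(3) / 6, math.sqrt(2.0 / 3.0)])
    E = D * np.array([1.0, 1.0, -1.0])
    DECOMP = (("A", "B", "C", "D"), ("A", "B", "C", "E"))

    def cents(self):
        return dict(zip("ABCDE", (self.A, self.B, self.C, self.D, self.E)))

    def test_double_unit_tetrahedron(self):
        vol = pocket_volume(self.cents(), self.DECOMP)
        assert vol == pytest.approx(2 * math.sqrt(2) / 12, abs=1e-12)

    def test_coplanar_is_zero(self):
        cents = self.cents()
        cents["D"] = np.array([0.3, 0.1, 0.0])
        cents["E"] = np.array([0.9, 0.4, 0.0])
        assert pocket_volume(cents, self.DECOMP) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        rot, trans = random_rigid_motion(rng)
        cents = self.cents()
        moved = {k: rot @ v + trans for k, v in cents.items()}
        assert pocket_volume(moved, self.DECOMP) == pytest.approx(
            pocket_volume(cents, self.DECOMP), abs=1e-9
        )

    @pytest.mark.parametrize(
        "decomp",
        [
            (("A", "B", "C", "D"), ("A", "B", "C", "D")),   # covers 4 labels
            (("A", "B", "C", "D"), ("A", "E", "C", "B")),   # fine cover, used below
        ][:1],
    )
    def test_bad_cover_rejected(self, decomp):
        with pytest.raises(UsageError):
            pocket_volume(self.cents(), decomp)

    def test_shared_face_must_be_three(self):
        with pytest.raises(UsageError, match="share exactly 3"):
            pocket_volume(
                {**self.cents(), "F": np.ones(3)},
                (("A", "B", "C", "D"), ("A", "B", "E", "F")),
            )

    def test_matches_independent_simplex_sums(self, rng):
        """Brute-force triple-product oracle over 1,000 random 5-point sets."""
        for _ in range(1000):
            pts = rng.uniform(-10, 10, size=(5, 3))
            cents = dict(zip("ABCDE", pts))
            expected = 0.0
            for tet in self.DECOMP:
                a, b, c, d = (cents[k] for k in tet)
                expected += abs(np.dot(np.cross(b - a, c - a), d - a)) / 6.0
            assert pocket_volume(cents, self.DECOMP) == pytest.approx(
                expected, rel=1e-12
            )


class TestStrandAxis:
    def test_exact_line_and_sign_convention(self):
        pts = np.column_stack([np.zeros(6), np.zeros(6), np.arange(6.0)])
        np.testing.assert_allclose(strand_axis(pts), [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(strand_axis(pts[::-1]), [0, 0, -1], atol=1e-12)

    def test_jittered_line_within_two_degrees(self, rng):
        z = np.arange(0.0, 15.0, 1.5)
        pts = np.column_stack([
            0.1 * np.cos(z), 0.1 * np.sin(z), z
        ])
        axis = strand_axis(pts)
        angle = math.degrees(math.acos(min(1.0, abs(axis[2]))))
        assert angle < 2.0

    def test_identical_points_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            strand_axis(np.ones((4, 3)))


class TestHairpinAngles:
    @pytest.mark.parametrize("deg", [0.0, 9.0, 45.0, 90.0])
    def test_constructed_twist(self, deg):
        t = math.radians(deg)
        v1 = np.array([0.0, 0.0, 1.0])
        v2 = np.array([0.0, math.sin(t), math.cos(t)])
        assert hairpin_twist(v1, v2) == pytest.approx(deg, abs=1e-6)

    def test_antiparallel_folding(self):
        # antiparallel strands: the reported angle is the folded magnitude
        t = math.radians(9.0)
        v2 = -np.array([0.0, math.sin(t), math.cos(t)])
        assert hairpin_twist([0, 0, 1], v2) == pytest.approx(9.0, abs=1e-6)

    @pytest.mark.parametrize("deg,expected", [(0.0, 0.0), (8.0, 8.0), (180.0, 180.0)])
    def test_tilt_against_reference(self, deg, expected):
        t = math.radians(deg)
        v = np.array([0.0, math.sin(t), math.cos(t)])
        assert hairpin_tilt(v, [0, 0, 1]) == pytest.approx(expected, abs=1e-6)

    def test_zero_vector_rejected(self):
        with pytest.raises(UsageError):
            hairpin_twist([0, 0, 0], [0, 0, 1])


class TestDihedral:
    @staticmethod
    def build(tau_deg):
        polar = math.radians(70.5)
        t = math.radians(tau_deg)
        return (
            np.array([1.41, 0.0, -0.51]),
            np.zeros(3),
            np.array([0.0, 0.0, 1.5]),
            np.array([0.0, 0.0, 1.5]) + 1.5 * np.array(
                [math.sin(polar) * math.cos(t),
                 math.sin(polar) * math.sin(t),
                 math.cos(polar)]
            ),
        )

    @pytest.mark.parametrize("tau", [0.0, 60.0, -60.0, 120.0, 180.0, -175.0])
    def test_constructed_torsions(self, tau):
        assert dihedral(*self.build(tau)) == pytest.approx(tau, abs=1e-6)

    def test_mirror_antisymmetry_and_order_reversal(self):
        pts = self.build(60.0)
        mirrored = [p * np.array([1.0, 1.0, -1.0]) for p in pts]
        assert dihedral(*mirrored) == pytest.approx(-60.0, abs=1e-6)
        assert dihedral(*pts[::-1]) == pytest.approx(dihedral(*pts), abs=1e-6)

    def test_rigid_motion_invariance(self, rng):
        pts = self.build(-60.0)
        rot, trans = random_rigid_motion(rng)
        moved = [rot @ p + trans for p in pts]
        assert dihedral(*moved) == pytest.approx(-60.0, abs=1e-6)

    def test_degenerate_points(self):
        p = np.zeros(3)
        with pytest.raises(DegenerateGeometryError):
            dihedral(p, p, [0, 0, 1], [1, 0, 1])


class TestTau2Basins:
    def test_counting_and_exclusion(self):
        assert tau2_basin_fractions([60.0] * 4) == (0.0, 1.0)
        angles = [60.0] * 5 + [-60.0]
        f_minus, f_plus = tau2_basin_fractions(angles)
        assert (f_minus, f_plus) == (pytest.approx(1 / 6), pytest.approx(5 / 6))
        assert tau2_basin_fractions([175.0, -175.0]) == (0.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(UsageError):
            tau2_basin_fractions([])


class TestHBond:
    @pytest.mark.parametrize(
        "dist,angle,expected",
        [(3.4, 20.0, True), (3.6, 0.0, False), (3.0, 31.0, False), (3.0, 30.0, True)],
    )
    def test_printed_criteria(self, dist, angle, expected):
        donor = np.zeros(3)
        acceptor = np.array([dist, 0.0, 0.0])
        t = math.radians(angle)
        hydrogen = np.array([math.cos(t), math.sin(t), 0.0])
        assert detect_hbond(donor, hydrogen, acceptor) is expected

    def test_occupancy_counts_snapshots(self):
        ens, truth = make_hbond_series(0.5, 10, seed=4)
        spec = HBondSpec(donor=truth["donor"], hydrogen=truth["hydrogen"],
                         acceptor=truth["acceptor"])
        assert hbond_occupancy(ens, spec) == truth["exact_occupancy"]

    def test_never_formed(self):
        ens, truth = make_hbond_series(0.0, 20, seed=0)
        spec = HBondSpec(donor=0, hydrogen=1, acceptor=2)
        assert hbond_occupancy(ens, spec) == 0.0


class TestRingOrientation:
    def _two_rings(self, angle_deg, offset=3.5, hexagon=None):
        angles = np.radians(np.arange(6) * 60.0)
        ring1 = np.column_stack(
            [1.39 * np.cos(angles), 1.39 * np.sin(angles), np.zeros(6)]
        )
        t = math.radians(angle_deg)
        rot = np.array([[1, 0, 0],
                        [0, math.cos(t), -math.sin(t)],
                        [0, math.sin(t), math.cos(t)]])
        ring2 = (rot @ ring1.T).T + np.array([0.0, 0.0, offset])
        coords = np.vstack([ring1, ring2])
        atoms = [
            AtomRecord(serial=i + 1, name=f"C{i}", residue_name="PHE", chain="R",
                       residue_number=1 + (i // 6), element="C")
            for i in range(12)
        ]
        snap = Snapshot(atoms=atoms, coords=coords)
        r1 = RingSpec("r1", [f"C{i}" for i in range(6)],
                      Selection("r1", list(range(6))))
        r2 = RingSpec("r2", [f"C{i}" for i in range(6, 12)],
                      Selection("r2", list(range(6, 12))))
        return snap, r1, r2

    @pytest.mark.parametrize("angle", [0.0, 35.0, 90.0])
    def test_constructed_normal_angles(self, angle):
        snap, r1, r2 = self._two_rings(angle)
        dist, measured = ring_orientation(r1, r2, snap)
        assert measured == pytest.approx(angle, abs=1e-6)

    def test_face_on_stack_distance(self):
        snap, r1, r2 = self._two_rings(0.0, offset=3.5)
        dist, angle = ring_orientation(r1, r2, snap)
        assert dist == pytest.approx(3.5, abs=1e-9)
        assert angle == pytest.approx(0.0, abs=1e-9)

    def test_classification_labels(self):
        assert classify_ring_pair(10.0) == "face-on"
        assert classify_ring_pair(75.0) == "orthogonal"
        assert classify_ring_pair(45.0) == "intermediate"


class TestRigidMotionInvariance:
    """Every site metric is invariant under one common rigid motion."""

    def test_pocket_snapshot_metrics(self, rng):
        snap, truth = make_pocket_snapshot(tau2_deg=60.0)
        rot, trans = random_rigid_motion(rng)
        moved = Snapshot(atoms=snap.atoms, coords=(rot @ snap.coords.T).T + trans)
        name_idx = {(a.chain, a.name): i for i, a in enumerate(snap.atoms)}
        lig = [name_idx[("L", n)] for n in truth["ligand_dihedral_atoms"]]
        for s in (snap, moved):
            assert dihedral(*(s.coords[i] for i in lig)) == pytest.approx(60.0, abs=1e-6)
        ring_sels = {}
        for resnum, label in enumerate(truth["rings"], start=1):
            idx = [
                i for i, a in enumerate(snap.atoms)
                if a.chain == "R" and a.residue_number == resnum
            ]
            ring_sels[label] = RingSpec(label, [], Selection(label, idx))
        cents0 = {lbl: ring_centroid(snap, spec) for lbl, spec in ring_sels.items()}
        cents1 = {lbl: ring_centroid(moved, spec) for lbl, spec in ring_sels.items()}
        from sitecraft.geometry import DEFAULT_POCKET_DECOMPOSITION

        assert pocket_volume(cents1, DEFAULT_POCKET_DECOMPOSITION) == pytest.approx(
            pocket_volume(cents0, DEFAULT_POCKET_DECOMPOSITION), abs=1e-6
        )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    tau=st.floats(min_value=-179.0, max_value=179.0),
    seed=st.integers(min_value=0, max_value=2**20),
)
def test_dihedral_mirror_antisymmetry_property(tau, seed):
    """dihedral is antisymmetric under reflection for arbitrary torsions."""
    pts = TestDihedral.build(tau)
    rng = np.random.default_rng(seed)
    rot, trans = random_rigid_motion(rng)
    moved = [rot @ p + trans for p in pts]
    val = dihedral(*moved)
    mirrored = [p * np.array([1.0, 1.0, -1.0]) for p in pts]
    assert val == pytest.approx(tau, abs=1e-6)
    assert dihedral(*mirrored) == pytest.approx(-tau, abs=1e-6)
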