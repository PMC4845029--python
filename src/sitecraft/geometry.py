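"""Per-snapshot and per-ensemble structural metrics of the agonist site.

The metrics quantify the architecture of the aromatic core (ring centroids,
the two-tetrahedron pocket volume, ring-plane orientations), the geometry
of the complementary beta5'-beta6 hairpin (SVD strand axes, twist, tilt),
ligand torsions (the bimodal tau2 of bound ACh) and hydrogen bonds
(<3.5 A donor-acceptor distance and <=30 deg H-donor-acceptor angle).
All metrics are invariant under rigid motion of the whole snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sitecraft.errors import DegenerateGeometryError, StructuralError, UsageError
from sitecraft.io import Ensemble, Selection, Snapshot

__all__ = [
    "RingSpec",
    "HBondSpec",
    "SiteMetrics",
    "ring_centroid",
    "pocket_volume",
    "tetrahedron_volume",
    "strand_axis",
    "hairpin_twist",
    "hairpin_tilt",
    "dihedral",
    "tau2_basin_fractions",
    "detect_hbond",
    "hbond_occupancy",
    "ring_orientation",
    "classify_ring_pair",
    "DEFAULT_POCKET_DECOMPOSITION",
]

# Default 5-centroid -> two-tetrahedron decomposition (an explicit package
# convention; the two 4-tuples share exactly three labels).
DEFAULT_POCKET_DECOMPOSITION = (
    ("aW149", "aY198", "aY190", "aY93"),
    ("aW149", "aY93", "W55", "aY198"),
)

HBOND_DISTANCE_A = 3.5
HBOND_ANGLE_DEG = 30.0


@dataclass
class RingSpec:
    """An aromatic ring: label (e.g. ``aW149``), ring-atom names, selection."""

    label: str
    atom_names: list[str]
    selection: Selection

    def __post_init__(self) -> None:
        if len(self.selection.resolved) < 5:
            raise UsageError(
                f"ring {self.label!r} needs >=5 ring atoms, "
                f"got {len(self.selection.resolved)}"
            )


@dataclass
class HBondSpec:
    """Donor / hydrogen / acceptor atom indices and a human-readable label."""

    donor: int
    hydrogen: int
    acceptor: int
    label: str = ""

    def __post_init__(self) -> None:
        if len({self.donor, self.hydrogen, self.acceptor}) != 3:
            raise UsageError("donor, hydrogen and acceptor must be distinct atoms")


@dataclass
class SiteMetrics:
    """Aggregated agonist-site metrics for one construct/ensemble."""

    pocket_volume: float = np.nan
    twist_deg: float = np.nan
    tilt_deg: float = np.nan
    tau2_deg: float = np.nan
    hbond_occupancy: dict = field(default_factory=dict)
    ring_geometry: dict = field(default_factory=dict)


def ring_centroid(snapshot: Snapshot, ring: RingSpec) -> np.ndarray:
    """Unweighted geometric centre of the ring atoms."""
    idx = np.asarray(ring.selection.resolved, dtype=int)
    if idx.size and idx.max() >= snapshot.n_atoms:
        raise StructuralError(f"ring {ring.label!r}: atom index out of range")
    return snapshot.coords[idx].mean(axis=0)


def tetrahedron_volume(a, b, c, d) -> float:
    """|det(b-a, c-a, d-a)| / 6 — the three-simplex determinant volume."""
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    return abs(np.linalg.det(np.stack([b - a, c - a, d - a]))) / 6.0


def pocket_volume(
    centroids: dict[str, np.ndarray],
    decomposition: tuple[tuple[str, ...], tuple[str, ...]] = DEFAULT_POCKET_DECOMPOSITION,
) -> float:
    """Binding-pocket volume from five labelled centroids.

    The five points are joined into two adjoining tetrahedra (the two
    4-tuples of ``decomposition`` must cover all five labels and share
    exactly three); the volume is the sum of the two simplex volumes.
    """
    t1, t2 = decomposition
    if len(set(t1)) != 4 or len(set(t2)) != 4:
        raise UsageError("each tetrahedron needs exactly 4 distinct labels")
    if len(set(t1) & set(t2)) != 3:
        raise UsageError("the two tetrahedra must share exactly 3 labels")
    cover = set(t1) | set(t2)
    if len(cover) != 5:
        raise UsageError(
            f"decomposition must cover exactly 5 labels, covers {len(cover)}"
        )
    missing = cover - set(centroids)
    if missing:
        raise UsageError(f"centroids missing for labels {sorted(missing)}")
    return sum(
        tetrahedron_volume(*(centroids[lbl] for lbl in tet)) for tet in (t1, t2)
    )


def strand_axis(backbone_coords: np.ndarray) -> np.ndarray:
    """Least-squares central axis of a strand via SVD of centred coordinates.

    Returns the dominant right-singular direction, sign-fixed to point from
    the first toward the last residue.
    """
    coords = np.asarray(backbone_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
        raise UsageError("strand_axis needs an (n>=2, 3) coordinate array")
    centred = coords - coords.mean(axis=0)
    if np.allclose(centred, 0.0):
        raise DegenerateGeometryError("all strand points identical")
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0 or not np.isfinite(n):
        raise UsageError(f"{name} must be a nonzero vector")
    return v / n


def hairpin_twist(axis_beta5p: np.ndarray, axis_beta6: np.ndarray) -> float:
    """Angle between the two strand axes, folded to [0, 90] degrees.

    The strands are antiparallel, so the unsigned |cos| convention reports
    the small positive inter-strand angle.
    """
    u = _check_unit(axis_beta5p, "axis_beta5p")
    v = _check_unit(axis_beta6, "axis_beta6")
    return float(np.degrees(np.arccos(np.clip(abs(np.dot(u, v)), 0.0, 1.0))))


def hairpin_tilt(hairpin_axis: np.ndarray, reference: np.ndarray) -> float:
    """Angle in [0, 180] degrees between the hairpin mean axis and a
    caller-supplied reference direction (no default biological frame is
    assumed)."""
    u = _check_unit(hairpin_axis, "hairpin_axis")
    v = _check_unit(reference, "reference")
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC torsion angle in (-180, 180] degrees (cis = 0)."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.allclose(a, b):
            raise DegenerateGeometryError("consecutive dihedral points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.allclose(n1, 0.0) or np.allclose(n2, 0.0):
        raise DegenerateGeometryError("collinear points: dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = -np.dot(m1, n2)
    angle = np.degrees(np.arctan2(y, x))
    # IUPAC: cis (eclipsed) = 0, clockwise far-bond rotation positive;
    # fold -180 to +180 for uniqueness
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def tau2_basin_fractions(
    angles_deg, basin_half_width_deg: float = 60.0
) -> tuple[float, float]:
    """Fractions of torsions in the -60 and +60 degree basins.

    An angle belongs to a basin when its magnitude is within
    ``basin_half_width_deg`` of zero-crossing sign convention: negative
    angles with |angle| <= half-width count toward the -60 basin, positive
    toward +60.  Out-of-basin angles are excluded, so the fractions sum
    to at most 1.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise UsageError("tau2_basin_fractions needs at least one angle")
    in_basin = np.abs(angles) <= basin_half_width_deg
    n = angles.size
    f_minus = float(np.count_nonzero(in_basin & (angles < 0)) / n)
    f_plus = float(np.count_nonzero(in_basin & (angles > 0)) / n)
    return f_minus, f_plus


def detect_hbond(
    donor,
    hydrogen,
    acceptor,
    max_distance_A: float = HBOND_DISTANCE_A,
    max_angle_deg: float = HBOND_ANGLE_DEG,
) -> bool:
    """Hydrogen-bond criterion: donor-acceptor distance < 3.5 A and the
    angle at the donor between donor->hydrogen and donor->acceptor <= 30 deg."""
    donor, hydrogen, acceptor = (
        np.asarray(p, dtype=float) for p in (donor, hydrogen, acceptor)
    )
    da = acceptor - donor
    dh = hydrogen - donor
    d = np.linalg.norm(da)
    if d >= max_distance_A:
        return False
    ndh = np.linalg.norm(dh)
    if d == 0 or ndh == 0:
        raise DegenerateGeometryError("coincident H-bond atoms")
    cosang = np.clip(np.dot(da, dh) / (d * ndh), -1.0, 1.0)
    return bool(np.degrees(np.arccos(cosang)) <= max_angle_deg)


def hbond_occupancy(ensemble: Ensemble, spec: HBondSpec) -> float:
    """Fraction of snapshots in which the H-bond criterion is satisfied."""
    n_atoms = ensemble.snapshots[0].n_atoms
    for idx in (spec.donor, spec.hydrogen, spec.acceptor):
        if not 0 <= idx < n_atoms:
            raise StructuralError(f"H-bond atom index {idx} out of range")
    hits = sum(
        detect_hbond(
            snap.coords[spec.donor],
            snap.coords[spec.hydrogen],
            snap.coords[spec.acceptor],
        )
        for snap in ensemble.snapshots
    )
    return hits / ensemble.n_snapshots


def _ring_plane_normal(coords: np.ndarray) -> np.ndarray:
    centred = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-9:  # atoms collinear: no plane
        raise DegenerateGeometryError("degenerate ring: atoms are collinear")
    return vt[2]


def ring_orientation(
    ring1: RingSpec, ring2: RingSpec, snapshot: Snapshot
) -> tuple[float, float]:
    """Centroid distance (A) and best-fit plane-normal angle folded to
    [0, 90] degrees for a pair of rings."""
    c1 = ring_centroid(snapshot, ring1)
    c2 = ring_centroid(snapshot, ring2)
    n1 = _ring_plane_normal(snapshot.coords[np.asarray(ring1.selection.resolved)])
    n2 = _ring_plane_normal(snapshot.coords[np.asarray(ring2.selection.resolved)])
    cosang = abs(np.clip(np.dot(n1, n2), -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    return float(np.linalg.norm(c2 - c1)), angle


def classify_ring_pair(
    normal_angle_deg: float,
    face_on_max_deg: float = 30.0,
    orthogonal_min_deg: float = 60.0,
) -> str:
    """Qualitative label for a ring pair: face-on, orthogonal or intermediate.

    Thresholds are reporting conventions; the raw angle is always kept
    alongside the label.
    """
    if normal_angle_deg <= face_on_max_deg:
        return "face-on"
    if normal_angle_deg >= orthogonal_min_deg:
        return "orthogonal"
    return "intermediate"
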