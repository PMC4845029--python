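"""Synthetic generators for every pipeline stage.

MD trajectories and patch-clamp records for the receptor are not
distributable, so these generators produce inputs with the statistical
structure each analysis stage assumes: idealized beta-hairpin ensembles
with controllable twist and per-residue fluctuation amplitudes, aromatic
pocket snapshots with prescribed ring geometry and ligand torsion,
H-bond ensembles with exact target occupancy, energy-component
calibration sets built from known (alpha*, beta*), and dwell-time
sequences from a known gating scheme, including a two-mode switching
variant.

Every generator is seed-deterministic and returns a *truth* record (a
plain dict, JSON-serializable) holding the exact generating values, so
recovery tests read the truth from the generator's bookkeeping rather
than from constants of their own.

The electrostatic component of the calibration surrogate uses a screened
Coulomb form.  This is an explicitly non-Poisson-Boltzmann stand-in that
only makes the component magnitudes physically plausible; real energy
tables are consumed, never computed, by the scoring stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from sitecraft.errors import UsageError
from sitecraft.io import AtomRecord, Ensemble, Snapshot
from sitecraft.kinetics import DwellDataset, GatingScheme, simulate_dwells
from sitecraft.scoring import CalibrationPoint

__all__ = [
    "HairpinSpec",
    "CalibrationTruth",
    "make_hairpin_ensemble",
    "make_pocket_snapshot",
    "make_hbond_series",
    "make_calibration_set",
    "make_energy_series",
    "make_dwell_data",
    "make_bimodal_dwells",
    "screened_coulomb",
]


@dataclass
class HairpinSpec:
    """Parameters of an idealized two-strand antiparallel hairpin ensemble.

    Strand axes are straight with fixed ``rise_A`` per residue and an exact
    separation angle of ``twist_deg``; snapshots add independent Gaussian
    displacements with the per-residue amplitudes in ``fluctuation_A``
    (cycled over both strands).  ``tilt_deg`` tilts the mean hairpin axis
    away from +z for tilt-metric fixtures.
    """

    n_residues: int = 4
    twist_deg: float = 9.0
    tilt_deg: float = 0.0
    rise_A: float = 3.4
    fluctuation_A: list = field(default_factory=lambda: [0.0])
    n_snapshots: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2 or self.n_snapshots < 1:
            raise UsageError("counts must be positive (>=2 residues)")
        if any(a < 0 for a in self.fluctuation_A):
            raise UsageError("fluctuation amplitudes must be >= 0")


@dataclass
class CalibrationTruth:
    """Known generating values for a synthetic calibration set."""

    alpha_true: float = 0.22
    beta_true: float = 1.24
    n_points: int = 13
    component_range: tuple = (-12.0, -5.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise UsageError("n_points must be >= 2")
        if self.noise_sd < 0:
            raise UsageError("noise_sd must be >= 0")


def _rotation_about_x(deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


_BACKBONE = ("N", "CA", "C")


def make_hairpin_ensemble(spec: HairpinSpec) -> tuple[Ensemble, dict]:
    """Idealized beta5'-beta6 hairpin ensemble with exact generating twist.

    Strand 1 (chain G, residues 107-(107+n-1)) runs along an axis tilted
    by ``+twist/2`` about x from the mean axis; strand 2 (residues
    115-...) is antiparallel along ``-twist/2``, offset 5 A in y.  The
    mean axis itself is tilted ``tilt_deg`` from +z.  Returns the ensemble
    and a truth dict with the generating parameters.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    mean_axis = _rotation_about_x(spec.tilt_deg) @ np.array([0.0, 0.0, 1.0])
    axis1 = _rotation_about_x(spec.tilt_deg + spec.twist_deg / 2.0) @ np.array(
        [0.0, 0.0, 1.0]
    )
    axis2 = _rotation_about_x(spec.tilt_deg - spec.twist_deg / 2.0) @ np.array(
        [0.0, 0.0, 1.0]
    )
    # N/CA/C offsets lie along the strand direction so the SVD axis of the
    # backbone cloud equals the generating axis exactly
    offset_scale = {"N": -0.6, "CA": 0.0, "C": 0.6}
    atoms: list[AtomRecord] = []
    base: list[np.ndarray] = []
    amp_per_atom: list[float] = []
    serial = 1
    amps = spec.fluctuation_A

    def add_strand(axis: np.ndarray, origin: np.ndarray, first_res: int,
                   antiparallel: bool) -> None:
        nonlocal serial
        direction = -axis if antiparallel else axis
        for i in range(n):
            res = first_res + i
            centre = origin + direction * spec.rise_A * i
            amp = amps[(res - 107) % len(amps)]
            for name in _BACKBONE:
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=name,
                        residue_name="GLY",
                        chain="G",
                        residue_number=res,
                        element=name[0],
                    )
                )
                base.append(centre + direction * offset_scale[name])
                amp_per_atom.append(amp)
                serial += 1

    # antiparallel pair: strand 1 ascends, strand 2 descends from the top
    add_strand(axis1, np.zeros(3), 107, antiparallel=False)
    add_strand(axis2, np.array([0.0, 5.0, 0.0]) + axis2 * spec.rise_A * (n - 1),
               115, antiparallel=True)
    base_arr = np.array(base)
    amp_arr = np.array(amp_per_atom)
    snaps = []
    for m in range(spec.n_snapshots):
        noise = rng.standard_normal(base_arr.shape) * amp_arr[:, None]
        snaps.append(
            Snapshot(atoms=atoms, coords=base_arr + noise, time_ps=float(m))
        )
    ens = Ensemble(snapshots=snaps, stride_ps=1.0, label="synthetic-hairpin")
    truth = {
        "twist_deg": spec.twist_deg,
        "tilt_deg": spec.tilt_deg,
        "mean_axis": mean_axis.tolist(),
        "axis_beta5p": axis1.tolist(),
        "axis_beta6": axis2.tolist(),
        "strand1_residues": list(range(107, 107 + n)),
        "strand2_residues": list(range(115, 115 + n)),
        "fluctuation_A": {
            107 + i: amps[i % len(amps)] for i in range(n)
        } | {115 + i: amps[(115 + i - 107) % len(amps)] for i in range(n)},
        "seed": spec.seed,
    }
    return ens, truth


def _hexagon(centroid: np.ndarray, normal: np.ndarray, radius: float = 1.39
             ) -> np.ndarray:
    normal = normal / np.linalg.norm(normal)
    # two in-plane unit vectors
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, normal)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    angles = np.radians(np.arange(6) * 60.0)
    return centroid + radius * (
        np.outer(np.cos(angles), u) + np.outer(np.sin(angles), v)
    )


DEFAULT_RING_LAYOUT = {
    # centroid (A), plane normal — a compact aromatic cage
    "aW149": (np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])),
    "aY198": (np.array([4.5, 0.0, 1.0]), np.array([0.0, 1.0, 0.0])),
    "aY190": (np.array([2.0, 4.0, 2.0]), np.array([1.0, 0.0, 0.0])),
    "aY93": (np.array([-3.5, 2.5, 1.5]), np.array([0.0, 0.7071, 0.7071])),
    "W55": (np.array([0.5, -4.0, 3.0]), np.array([0.7071, 0.0, 0.7071])),
}


def make_pocket_snapshot(
    ring_layout: dict | None = None,
    tau2_deg: float = 60.0,
) -> tuple[Snapshot, dict]:
    """Aromatic-pocket snapshot with prescribed ring geometry and ligand
    torsion.

    ``ring_layout`` maps ring label -> (centroid, plane normal); each ring
    is realized as a regular hexagon of aromatic C-C radius.  A four-atom
    ligand fragment (quaternary N, two carbons, ester O) is placed so its
    N-C-C-O torsion equals ``tau2_deg`` exactly, plus a structural-water
    oxygen/hydrogen pair near the ligand.  The truth dict records
    centroids, normals and the requested torsion.
    """
    layout = DEFAULT_RING_LAYOUT if ring_layout is None else ring_layout
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = 1
    resnum = 1
    ring_atom_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    for label, (centroid, normal) in layout.items():
        centroid = np.asarray(centroid, dtype=float)
        normal = np.asarray(normal, dtype=float)
        if np.linalg.norm(normal) == 0:
            raise UsageError(f"zero normal for ring {label!r}")
        ring = _hexagon(centroid, normal)
        for name, xyz in zip(ring_atom_names, ring):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    residue_name=label[:3].upper(),
                    chain="R",
                    residue_number=resnum,
                    element="C",
                )
            )
            coords.append(xyz)
            serial += 1
        resnum += 1
    # ligand fragment with exact N-C-C-O dihedral: with the C7-C6 bond on
    # +z and the N projection on +x, a terminal direction at azimuth tau
    # gives torsion tau exactly (tetrahedral-ish 109.5 deg bond angles)
    t = math.radians(tau2_deg)
    polar = math.radians(180.0 - 109.5)
    p1 = np.array([1.41, 0.0, -0.51])  # xy-projection along +x
    p2 = np.zeros(3)
    p3 = np.array([0.0, 0.0, 1.5])
    p4 = p3 + 1.5 * np.array(
        [math.sin(polar) * math.cos(t),
         math.sin(polar) * math.sin(t),
         math.cos(polar)]
    )
    lig_origin = np.array([0.5, 0.5, 2.5])
    for name, elem, xyz in (
        ("N", "N", p1), ("C7", "C", p2), ("C6", "C", p3), ("O1", "O", p4)
    ):
        atoms.append(
            AtomRecord(serial=serial, name=name, residue_name="ACH",
                       chain="L", residue_number=resnum, element=elem)
        )
        coords.append(lig_origin + xyz)
        serial += 1
    resnum += 1
    for name, elem, xyz in (
        ("OW", "O", np.array([2.0, 2.0, 4.5])),
        ("HW1", "H", np.array([2.6, 2.4, 5.1])),
    ):
        atoms.append(
            AtomRecord(serial=serial, name=name, residue_name="HOH",
                       chain="W", residue_number=resnum, element=elem)
        )
        coords.append(xyz)
        serial += 1
    snapshot = Snapshot(atoms=atoms, coords=np.array(coords), time_ps=0.0)
    truth = {
        "rings": {
            label: {"centroid": np.asarray(c, dtype=float).tolist(),
                    "normal": (np.asarray(nrm, dtype=float)
                               / np.linalg.norm(nrm)).tolist()}
            for label, (c, nrm) in layout.items()
        },
        "tau2_deg": tau2_deg,
        "ligand_dihedral_atoms": ["N", "C7", "C6", "O1"],
    }
    return snapshot, truth


def make_hbond_series(
    target_occupancy: float, n_snapshots: int, seed: int = 0
) -> tuple[Ensemble, dict]:
    """Donor/hydrogen/acceptor triplet ensemble with exact occupancy.

    Exactly ``floor(target * n)`` snapshots satisfy the 3.5 A / 30 deg
    criterion (bond formed: d = 2.9 A, in-line hydrogen); in the rest the
    acceptor is moved to 5.0 A.  Which snapshots are bonded is a seeded
    permutation, so occupancy is exact by construction.
    """
    if not 0.0 <= target_occupancy <= 1.0:
        raise UsageError("target occupancy must be in [0, 1]")
    if n_snapshots < 1:
        raise UsageError("n_snapshots must be >= 1")
    rng = np.random.default_rng(seed)
    n_bonded = int(math.floor(target_occupancy * n_snapshots))
    bonded = np.zeros(n_snapshots, dtype=bool)
    bonded[rng.permutation(n_snapshots)[:n_bonded]] = True
    atoms = [
        AtomRecord(serial=1, name="N", residue_name="GLY", chain="G",
                   residue_number=111, element="N"),
        AtomRecord(serial=2, name="H", residue_name="GLY", chain="G",
                   residue_number=111, element="H"),
        AtomRecord(serial=3, name="O", residue_name="GLY", chain="G",
                   residue_number=115, element="O"),
    ]
    snaps = []
    for m in range(n_snapshots):
        d = 2.9 if bonded[m] else 5.0
        coords = np.array([
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],   # hydrogen in line with the acceptor
            [d, 0.0, 0.0],
        ])
        snaps.append(Snapshot(atoms=atoms, coords=coords, time_ps=float(m)))
    ens = Ensemble(snapshots=snaps, stride_ps=1.0, label="synthetic-hbond")
    truth = {
        "target_occupancy": target_occupancy,
        "exact_occupancy": n_bonded / n_snapshots,
        "n_bonded": n_bonded,
        "donor": 0, "hydrogen": 1, "acceptor": 2,
        "seed": seed,
    }
    return ens, truth


def screened_coulomb(
    q1: float, q2: float, r_A: float, kappa_per_A: float = 0.12,
    dielectric: float = 4.0,
) -> float:
    """Screened-Coulomb interaction energy in kcal/mol.

    332.06 * q1*q2 * exp(-kappa*r) / (eps*r) — a deliberately simple
    surrogate used only to draw plausible electrostatic component
    magnitudes for fixtures; it is not a Poisson-Boltzmann energy.
    """
    if r_A <= 0:
        raise UsageError("distance must be positive")
    return 332.06 * q1 * q2 * math.exp(-kappa_per_A * r_A) / (dielectric * r_A)


def make_calibration_set(
    truth: CalibrationTruth,
) -> tuple[list[CalibrationPoint], dict]:
    """Calibration points from known (alpha*, beta*) plus additive noise.

    vdW means are drawn uniformly over ``component_range``; electrostatic
    means come from the screened-Coulomb surrogate evaluated at jittered
    charge-charge distances (3.5-6.5 A, unit charges), which lands the
    rescaled totals in the -4 to -7 kcal/mol window of real agonist-site
    estimates.  experimental = alpha*vdw + beta*elec + N(0, noise_sd).
    """
    rng = np.random.default_rng(truth.seed)
    lo, hi = truth.component_range
    points = []
    records = []
    for i in range(truth.n_points):
        vdw = float(rng.uniform(lo, hi))
        r = float(rng.uniform(3.5, 6.5))
        # effective charges +-0.53 land elec in ~[-4.4, -1.6] so rescaled
        # totals span the -4..-7 kcal/mol window of real site estimates
        elec = screened_coulomb(0.53, -0.53, r)
        noise = float(rng.normal(0.0, truth.noise_sd)) if truth.noise_sd else 0.0
        exp_energy = truth.alpha_true * vdw + truth.beta_true * elec + noise
        points.append(
            CalibrationPoint(
                construct=f"syn{i:02d}",
                mean_e_vdw=vdw,
                mean_e_elec=elec,
                experimental_energy=exp_energy,
            )
        )
        records.append({"construct": f"syn{i:02d}", "mean_e_vdw": vdw,
                        "mean_e_elec": elec, "noise": noise,
                        "experimental_energy": exp_energy})
    truth_dict = {
        "alpha_true": truth.alpha_true,
        "beta_true": truth.beta_true,
        "noise_sd": truth.noise_sd,
        "n_points": truth.n_points,
        "seed": truth.seed,
        "points": records,
    }
    return points, truth_dict


def make_energy_series(
    mean_vdw: float,
    mean_elec: float,
    sd: float = 1.0,
    n_snapshots: int = 2000,
    seed: int = 0,
    construct: str = "syn",
    ligand: str = "ACh",
):
    """Per-snapshot component series with given means and Gaussian spread."""
    from sitecraft.scoring import EnergyComponentSeries

    rng = np.random.default_rng(seed)
    e_vdw = mean_vdw + rng.standard_normal(n_snapshots) * sd
    e_elec = mean_elec + rng.standard_normal(n_snapshots) * sd
    truth = {"mean_vdw": mean_vdw, "mean_elec": mean_elec, "sd": sd,
             "n_snapshots": n_snapshots, "seed": seed}
    return (
        EnergyComponentSeries(construct=construct, ligand=ligand,
                              e_vdw=e_vdw, e_elec=e_elec),
        truth,
    )


def make_dwell_data(
    scheme: GatingScheme,
    concs_M: list[float],
    n_events: int,
    seed: int = 0,
    events_per_cluster: int | None = None,
) -> tuple[list[DwellDataset], dict]:
    """Dwell datasets at several concentrations from one known scheme."""
    datasets = []
    for i, conc in enumerate(concs_M):
        datasets.append(
            simulate_dwells(
                scheme, conc, n_events, seed=seed + i,
                events_per_cluster=events_per_cluster,
            )
        )
    truth = {
        "k_on": scheme.k_on, "k_off": scheme.k_off,
        "f_open": scheme.f_open, "b_close": scheme.b_close,
        "kd_M": scheme.kd_M, "concs_M": list(concs_M),
        "n_events": n_events, "seed": seed,
    }
    return datasets, truth


def make_bimodal_dwells(
    scheme_ha: GatingScheme,
    scheme_la: GatingScheme,
    switch_tau_s: float,
    n_clusters: int,
    events_per_cluster: int = 20,
    conc_M: float = 1e-4,
    seed: int = 0,
) -> tuple[DwellDataset, dict]:
    """Cluster sequence alternating between two gating modes.

    A hidden two-state mode process with exponential holding time
    ``switch_tau_s`` (both modes) runs in continuous time; each cluster is
    simulated from the scheme of the mode active when it starts.  The
    truth dict carries the per-cluster mode labels, the generating
    schemes and the switching constant.
    """
    if n_clusters < 1 or events_per_cluster < 1:
        raise UsageError("counts must be positive")
    if switch_tau_s <= 0:
        raise UsageError("switch_tau_s must be positive")
    rng = np.random.default_rng(seed)
    mode = int(rng.integers(0, 2))
    clusters: list = []
    labels: list = []
    # alternate exponential mode holds; every hold hosts >=1 cluster and a
    # new cluster starts only while the hold is still running, so labelled
    # run durations estimate switch_tau up to one trailing cluster
    while len(clusters) < n_clusters:
        hold = rng.exponential(switch_tau_s)
        elapsed = 0.0
        first = True
        while (first or elapsed < hold) and len(clusters) < n_clusters:
            scheme = (scheme_la, scheme_ha)[mode]
            ds = simulate_dwells(scheme, conc_M, events_per_cluster, seed=rng)
            clusters.append(ds.clusters[0])
            labels.append(mode)
            elapsed += sum(d for _, d in ds.clusters[0])
            first = False
        mode = 1 - mode
    dataset = DwellDataset(
        clusters=clusters, conc_M=conc_M, voltage_mV=-100.0,
        construct="bimodal-sim",
    )
    truth = {
        "switch_tau_s": switch_tau_s,
        "mode_labels": labels,
        "conc_M": conc_M,
        "ha": {"k_on": scheme_ha.k_on, "k_off": scheme_ha.k_off,
               "f_open": scheme_ha.f_open, "b_close": scheme_ha.b_close},
        "la": {"k_on": scheme_la.k_on, "k_off": scheme_la.k_off,
               "f_open": scheme_la.f_open, "b_close": scheme_la.b_close},
        "seed": seed,
    }
    return dataset, truth
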