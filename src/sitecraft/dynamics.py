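"""Trajectory stability and flexibility analytics.

RMSD against a reference structure (optionally after an optimal Kabsch
superposition, optionally excluding a flexible region such as loop F),
rolling-average drift slopes as a stationarity diagnostic, and per-residue
RMSF about the ensemble-average structure, including difference profiles
between high- and low-affinity constructs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from sitecraft.errors import StructuralError, UsageError
from sitecraft.io import Ensemble, Selection, Snapshot

__all__ = [
    "RmsdSeries",
    "RmsfProfile",
    "rmsd",
    "rmsd_series",
    "rolling_drift",
    "rmsf",
    "rmsf_difference",
]


@dataclass
class RmsdSeries:
    """Per-snapshot RMSD (A) against a fixed reference."""

    time_ps: np.ndarray
    rmsd_A: np.ndarray
    excluded: Selection | None = None
    superposed: bool = False

    def __post_init__(self) -> None:
        self.time_ps = np.asarray(self.time_ps, dtype=float)
        self.rmsd_A = np.asarray(self.rmsd_A, dtype=float)
        if self.time_ps.shape != self.rmsd_A.shape:
            raise UsageError("time and rmsd arrays must have equal length")
        if np.any(self.rmsd_A < 0):
            raise UsageError("rmsd values must be non-negative")


@dataclass
class RmsfProfile:
    """Per-residue RMSF (A)."""

    residue_number: np.ndarray
    rmsf_A: np.ndarray

    def __post_init__(self) -> None:
        self.residue_number = np.asarray(self.residue_number, dtype=int)
        self.rmsf_A = np.asarray(self.rmsf_A, dtype=float)
        if self.residue_number.shape != self.rmsf_A.shape:
            raise UsageError("residue and rmsf arrays must have equal length")


def _kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal least-squares rigid fit of ``mobile`` onto ``target``."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    p = mobile - mc
    q = target - tc
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (rot @ p.T).T + tc


def rmsd(
    snapshot: Snapshot,
    reference: Snapshot,
    selection: Selection | None = None,
    superpose: bool = False,
) -> float:
    """Root-mean-square deviation over the selected atoms.

    With ``superpose=True`` an optimal least-squares rigid fit (Kabsch) of
    the snapshot onto the reference is applied first.
    """
    if selection is None:
        idx = np.arange(snapshot.n_atoms)
    else:
        idx = np.asarray(selection.resolved, dtype=int)
    if idx.size == 0:
        raise UsageError("empty selection for rmsd")
    if snapshot.n_atoms != reference.n_atoms:
        raise StructuralError(
            f"snapshot has {snapshot.n_atoms} atoms, reference "
            f"{reference.n_atoms}"
        )
    mob = snapshot.coords[idx]
    ref = reference.coords[idx]
    if superpose:
        mob = _kabsch_superpose(mob, ref)
    return float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))


def rmsd_series(
    ensemble: Ensemble,
    reference: Snapshot | None = None,
    selection: Selection | None = None,
    exclude: Selection | None = None,
    superpose: bool = False,
) -> RmsdSeries:
    """Per-snapshot RMSD over ``selection`` minus ``exclude``.

    The exclusion mirrors removing a disordered region (loop F) from the
    stability measure; indices in ``exclude`` that are not part of the
    selection are warned about and ignored.
    """
    if reference is None:
        reference = ensemble.snapshots[0]
    if selection is None:
        idx = np.arange(ensemble.snapshots[0].n_atoms)
        expr = "all"
    else:
        idx = np.asarray(selection.resolved, dtype=int)
        expr = selection.expression
    if exclude is not None and len(exclude.resolved) > 0:
        exc = np.asarray(exclude.resolved, dtype=int)
        stray = np.setdiff1d(exc, idx)
        if stray.size:
            warnings.warn(
                f"{stray.size} excluded atoms are not in the selection; ignored",
                stacklevel=2,
            )
        idx = np.setdiff1d(idx, exc)
        if idx.size == 0:
            raise UsageError("exclusion removed every selected atom")
    eff = Selection(expression=f"({expr}) minus exclusion", resolved=list(idx))
    values = [
        rmsd(snap, reference, selection=eff, superpose=superpose)
        for snap in ensemble.snapshots
    ]
    times = np.array([s.time_ps for s in ensemble.snapshots], dtype=float)
    return RmsdSeries(
        time_ps=times, rmsd_A=np.array(values), excluded=exclude, superposed=superpose
    )


def rolling_drift(
    series: RmsdSeries,
    window_ps: float = 5000.0,
    fit_span_ps: float = 10000.0,
) -> tuple[np.ndarray, float, float]:
    """Centred rolling mean of an RMSD series and its terminal drift slope.

    Returns ``(rolling_mean, slope_A_per_ns, slope_stderr_A_per_ns)`` where
    the slope is the ordinary least-squares fit to the last ``fit_span_ps``
    of the rolling mean.  A near-zero slope indicates a stationary
    (converged) trajectory.
    """
    t = series.time_ps
    y = series.rmsd_A
    if t.size < 2:
        raise UsageError("rolling_drift needs at least two samples")
    duration = t[-1] - t[0]
    if window_ps > duration:
        raise UsageError(
            f"rolling window {window_ps} ps exceeds series duration {duration} ps"
        )
    if fit_span_ps > duration:
        raise UsageError(
            f"fit span {fit_span_ps} ps exceeds series duration {duration} ps"
        )
    # centred window, shrunk symmetrically near the ends so the smoother
    # is unbiased for linear trends over the whole series
    half = window_ps / 2.0
    rolling = np.empty_like(y)
    for i, ti in enumerate(t):
        h = min(half, ti - t[0], t[-1] - ti)
        mask = (t >= ti - h) & (t <= ti + h)
        rolling[i] = y[mask].mean()
    tail = t >= t[-1] - fit_span_ps
    tt = t[tail] / 1000.0  # ns
    yy = rolling[tail]
    (slope, _), cov = np.polyfit(tt, yy, 1, cov=True)
    stderr = float(np.sqrt(cov[0, 0]))
    return rolling, float(slope), stderr


def rmsf(
    ensemble: Ensemble,
    selection: Selection | None = None,
    group_by_residue: bool = True,
) -> RmsfProfile:
    """Root-mean-square fluctuation about the ensemble-average structure.

    Per-atom fluctuations are averaged per residue when
    ``group_by_residue`` is set (one value per residue over its selected
    backbone atoms).
    """
    if ensemble.n_snapshots < 2:
        raise UsageError("rmsf needs at least two snapshots")
    if selection is None:
        idx = np.arange(ensemble.snapshots[0].n_atoms)
    else:
        idx = np.asarray(selection.resolved, dtype=int)
    if idx.size == 0:
        raise UsageError("empty selection for rmsf")
    coords = ensemble.coords_array()[:, idx, :]
    mean_struct = coords.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((coords - mean_struct) ** 2, axis=2), axis=0))
    atoms = [ensemble.atoms[i] for i in idx]
    if not group_by_residue:
        residues = np.array([a.residue_number for a in atoms])
        return RmsfProfile(residue_number=residues, rmsf_A=per_atom)
    order: list[int] = []
    buckets: dict[int, list[float]] = {}
    for atom, val in zip(atoms, per_atom):
        if atom.residue_number not in buckets:
            order.append(atom.residue_number)
            buckets[atom.residue_number] = []
        buckets[atom.residue_number].append(val)
    residues = np.array(order)
    values = np.array([np.mean(buckets[r]) for r in order])
    return RmsfProfile(residue_number=residues, rmsf_A=values)


def rmsf_difference(
    profile_ha: RmsfProfile, profile_la: RmsfProfile
) -> RmsfProfile:
    """Elementwise HA minus LA RMSF over the shared residues.

    Residues present in only one profile are dropped (and warned about);
    an empty intersection is an error.
    """
    shared = np.intersect1d(profile_ha.residue_number, profile_la.residue_number)
    if shared.size == 0:
        raise UsageError("profiles share no residues")
    n_drop = (
        profile_ha.residue_number.size
        + profile_la.residue_number.size
        - 2 * shared.size
    )
    if n_drop:
        warnings.warn(f"{n_drop} unmatched residues dropped", stacklevel=2)
    ha = dict(zip(profile_ha.residue_number, profile_ha.rmsf_A))
    la = dict(zip(profile_la.residue_number, profile_la.rmsf_A))
    diff = np.array([ha[r] - la[r] for r in shared])
    return RmsfProfile(residue_number=shared, rmsf_A=diff)
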