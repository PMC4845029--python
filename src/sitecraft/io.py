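"""Coordinate-ensemble and table I/O plus atom selection.

An :class:`Ensemble` is an ordered list of snapshots sharing one atom table
— the universal substrate of the geometry and dynamics analytics.  The
canonical on-disk form is a multi-model PDB (MODEL/ENDMDL delimited, parsed
and written through :mod:`biotite`); a plain multi-frame XYZ dialect is
accepted for synthetic fixtures.  Units are angstrom for coordinates,
picoseconds for time, kcal/mol for energies and seconds for dwell
durations; conversion happens only at I/O boundaries.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sitecraft.errors import FormatError, StructuralError, UsageError

__all__ = [
    "AtomRecord",
    "Snapshot",
    "Ensemble",
    "Selection",
    "read_ensemble",
    "write_ensemble",
    "select_atoms",
    "read_energy_table",
    "write_energy_table",
    "read_dwell_table",
    "write_dwell_table",
    "ENERGY_COLUMNS",
    "DWELL_COLUMNS",
]

ENERGY_COLUMNS = ["snapshot_index", "time_ps", "e_vdw_kcal", "e_elec_kcal"]
DWELL_COLUMNS = ["cluster_id", "state", "duration_s", "conc_M", "voltage_mV", "construct"]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared atom table.

    Residue numbers are stored as-is in the numbering convention of the
    source structure (gamma-subunit numbers in the default configuration);
    cross-subunit equivalences live in run configuration, never here.
    """

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_number: int
    element: str = ""


@dataclass
class Snapshot:
    """A single coordinate frame: the atom table plus an (n, 3) array in A."""

    atoms: list[AtomRecord]
    coords: np.ndarray
    time_ps: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise StructuralError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructuralError("non-finite coordinates in snapshot")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class Ensemble:
    """Ordered snapshots sharing an identical atom table."""

    snapshots: list[Snapshot]
    stride_ps: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.snapshots:
            raise StructuralError("ensemble must contain at least one snapshot")
        ref = self.snapshots[0].atoms
        for i, snap in enumerate(self.snapshots):
            if len(snap.atoms) != len(ref):
                raise StructuralError(
                    f"frame {i} has {len(snap.atoms)} atoms, expected {len(ref)}"
                )

    @property
    def atoms(self) -> list[AtomRecord]:
        return self.snapshots[0].atoms

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)

    def coords_array(self) -> np.ndarray:
        """All coordinates as an (n_snapshots, n_atoms, 3) array."""
        return np.stack([s.coords for s in self.snapshots])

    def restricted(self, selection: "Selection") -> "Ensemble":
        """A new ensemble containing only the selected atoms."""
        idx = np.asarray(selection.resolved, dtype=int)
        atoms = [self.atoms[i] for i in idx]
        snaps = [
            Snapshot(atoms=atoms, coords=s.coords[idx], time_ps=s.time_ps)
            for s in self.snapshots
        ]
        return Ensemble(snapshots=snaps, stride_ps=self.stride_ps, label=self.label)


@dataclass
class Selection:
    """A resolved atom selection: the expression and strictly increasing indices."""

    expression: str
    resolved: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        res = list(self.resolved)
        if any(res[i] >= res[i + 1] for i in range(len(res) - 1)):
            raise UsageError("selection indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.resolved)


# --------------------------------------------------------------------------
# Selection mini-grammar:  clause ("and" clause)*
#   clause := "chain" ID+ | "resid" RANGE+ | "name" ID+
#   RANGE  := INT | INT-INT
# --------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


def _parse_expression(expression: str) -> list[tuple[str, list]]:
    clauses = []
    for raw in re.split(r"\s+and\s+", expression.strip()):
        tokens = raw.split()
        if not tokens:
            raise UsageError(f"empty clause in selection {expression!r}")
        key, args = tokens[0].lower(), tokens[1:]
        if key in ("chain", "name"):
            if not args:
                raise UsageError(f"{key!r} clause needs at least one value")
            clauses.append((key, args))
        elif key == "resid":
            if not args:
                raise UsageError("'resid' clause needs at least one range")
            ranges = []
            for a in args:
                m = _RANGE_RE.match(a)
                if not m:
                    raise UsageError(f"bad resid range {a!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                ranges.append((min(lo, hi), max(lo, hi)))
            clauses.append((key, ranges))
        else:
            raise UsageError(f"unknown selection keyword {key!r}")
    return clauses


def select_atoms(ensemble: Ensemble, expression: str) -> Selection:
    """Resolve a selection expression against an ensemble's atom table.

    The grammar is a conjunction of ``chain``, ``resid`` (inclusive ranges)
    and ``name`` clauses, e.g. ``"chain G and resid 166-183 and name CA"``.
    An empty match is legal but warned about.
    """
    clauses = _parse_expression(expression)
    resolved = []
    for i, atom in enumerate(ensemble.atoms):
        ok = True
        for key, args in clauses:
            if key == "chain":
                ok = atom.chain in args
            elif key == "name":
                ok = atom.name in args
            else:  # resid
                ok = any(lo <= atom.residue_number <= hi for lo, hi in args)
            if not ok:
                break
        if ok:
            resolved.append(i)
    if not resolved:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return Selection(expression=expression, resolved=resolved)


# --------------------------------------------------------------------------
# Ensemble I/O
# --------------------------------------------------------------------------


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("pdb_multimodel", "xyz"):
            raise UsageError(f"unknown ensemble format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".pdb":
        return "pdb_multimodel"
    if suffix == ".xyz":
        return "xyz"
    raise UsageError(f"cannot infer format from {path!r}; pass format=")


def read_ensemble(
    path: str | Path,
    format: str | None = None,
    stride_ps: float = 0.0,
    label: str = "",
) -> Ensemble:
    """Read a coordinate ensemble (multi-model PDB via biotite, or XYZ).

    The atom table is taken from the first frame; every subsequent frame is
    checked for atom-count equality and a :class:`StructuralError` naming
    the offending frame is raised on mismatch.
    """
    fmt = _infer_format(path, format)
    path = Path(path)
    if not path.exists():
        raise UsageError(f"no such file: {path}")
    if fmt == "pdb_multimodel":
        return _read_pdb(path, stride_ps, label)
    return _read_xyz(path, stride_ps, label)


def _read_pdb(path: Path, stride_ps: float, label: str) -> Ensemble:
    import biotite.structure.io.pdb as pdb

    # biotite refuses ragged models outright; pre-check atom counts per MODEL
    # so the error names the frame, as the contract requires.
    counts = []
    n = 0
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model, n = True, 0
            elif rec == "ENDMDL":
                counts.append(n)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                n += 1
    if in_model:
        counts.append(n)
    if counts and any(c != counts[0] for c in counts):
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise StructuralError(
            f"frame {bad} has {counts[bad]} atoms, expected {counts[0]}"
        )

    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)
    if stack.array_length() == 0:
        raise FormatError(f"no atoms in {path}")
    atoms = [
        AtomRecord(
            serial=i + 1,
            name=str(stack.atom_name[i]),
            residue_name=str(stack.res_name[i]),
            chain=str(stack.chain_id[i]),
            residue_number=int(stack.res_id[i]),
            element=str(stack.element[i]),
        )
        for i in range(stack.array_length())
    ]
    coords = np.asarray(stack.coord, dtype=float)
    snaps = [
        Snapshot(atoms=atoms, coords=coords[m], time_ps=m * stride_ps)
        for m in range(coords.shape[0])
    ]
    return Ensemble(snapshots=snaps, stride_ps=stride_ps, label=label)


def _read_xyz(path: Path, stride_ps: float, label: str) -> Ensemble:
    """Multi-frame XYZ: repeated (natoms / comment / natoms lines) blocks.

    Atom metadata beyond the element symbol is encoded in the comment line
    when written by :func:`write_ensemble`; otherwise chain 'A', sequential
    residue numbers and the symbol as atom name are assumed.
    """
    frames: list[np.ndarray] = []
    symbols: list[str] = []
    meta: list[tuple[str, str, str, int]] | None = None
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not any(ln.strip() for ln in lines):
        raise FormatError(f"no records in {path}")
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"bad atom count at line {i + 1} of {path}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        block = lines[i + 2 : i + 2 + natoms]
        if len(block) < natoms:
            raise StructuralError(
                f"frame {frame_no} truncated: {len(block)} of {natoms} atoms"
            )
        coords = np.empty((natoms, 3))
        syms = []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"bad XYZ atom line {i + 3 + j} of {path}")
            syms.append(parts[0])
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if frames and natoms != frames[0].shape[0]:
            raise StructuralError(
                f"frame {frame_no} has {natoms} atoms, expected {frames[0].shape[0]}"
            )
        if meta is None and comment.startswith("sitecraft-atoms "):
            meta = []
            for entry in comment[len("sitecraft-atoms ") :].split(";"):
                name, resname, chain, resnum = entry.split(",")
                meta.append((name, resname, chain, int(resnum)))
        frames.append(coords)
        symbols = symbols or syms
        frame_no += 1
        i += 2 + natoms
    if not frames:
        raise FormatError(f"no records in {path}")
    atoms = []
    for k, sym in enumerate(symbols):
        if meta is not None and k < len(meta):
            name, resname, chain, resnum = meta[k]
        else:
            name, resname, chain, resnum = sym, "UNK", "A", k + 1
        atoms.append(
            AtomRecord(
                serial=k + 1,
                name=name,
                residue_name=resname,
                chain=chain,
                residue_number=resnum,
                element=sym,
            )
        )
    snaps = [
        Snapshot(atoms=atoms, coords=c, time_ps=m * stride_ps)
        for m, c in enumerate(frames)
    ]
    return Ensemble(snapshots=snaps, stride_ps=stride_ps, label=label)


def write_ensemble(ensemble: Ensemble, path: str | Path, format: str | None = None) -> None:
    """Write an ensemble as multi-model PDB (via biotite) or multi-frame XYZ."""
    fmt = _infer_format(path, format)
    path = Path(path)
    if fmt == "pdb_multimodel":
        _write_pdb(ensemble, path)
    else:
        _write_xyz(ensemble, path)


def _write_pdb(ensemble: Ensemble, path: Path) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = len(ensemble.atoms)
    stack = struc.AtomArrayStack(ensemble.n_snapshots, n)
    stack.coord = ensemble.coords_array()
    stack.chain_id = np.array([a.chain for a in ensemble.atoms])
    stack.res_id = np.array([a.residue_number for a in ensemble.atoms])
    stack.res_name = np.array([a.residue_name for a in ensemble.atoms])
    stack.atom_name = np.array([a.name for a in ensemble.atoms])
    stack.element = np.array([a.element or a.name[:1] for a in ensemble.atoms])
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def _write_xyz(ensemble: Ensemble, path: Path) -> None:
    meta = ";".join(
        f"{a.name},{a.residue_name},{a.chain},{a.residue_number}"
        for a in ensemble.atoms
    )
    with open(path, "w") as fh:
        for snap in ensemble.snapshots:
            fh.write(f"{snap.n_atoms}\n")
            fh.write(f"sitecraft-atoms {meta}\n")
            for atom, xyz in zip(snap.atoms, snap.coords):
                sym = atom.element or atom.name[:1]
                fh.write(f"{sym} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


# --------------------------------------------------------------------------
# Tabular dialects
# --------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_energy_table(path: str | Path):
    """Read a per-snapshot energy-component CSV into an EnergyComponentSeries.

    Columns: ``snapshot_index,time_ps,e_vdw_kcal,e_elec_kcal`` (kcal/mol).
    Row order is preserved.
    """
    from sitecraft.scoring import EnergyComponentSeries

    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: no records") from exc
    if df.empty:
        raise FormatError(f"{path}: no records")
    _require_columns(df, ENERGY_COLUMNS, path)
    for col in ("e_vdw_kcal", "e_elec_kcal", "time_ps"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"{path}: non-numeric {col} at row {row}")
        df[col] = vals
    construct = str(df["construct"].iloc[0]) if "construct" in df.columns else ""
    ligand = str(df["ligand"].iloc[0]) if "ligand" in df.columns else ""
    return EnergyComponentSeries(
        construct=construct,
        ligand=ligand,
        e_vdw=df["e_vdw_kcal"].to_numpy(float),
        e_elec=df["e_elec_kcal"].to_numpy(float),
    )


def write_energy_table(series, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "snapshot_index": np.arange(len(series.e_vdw)),
            "time_ps": np.arange(len(series.e_vdw), dtype=float),
            "e_vdw_kcal": series.e_vdw,
            "e_elec_kcal": series.e_elec,
        }
    )
    df["construct"] = series.construct
    df["ligand"] = series.ligand
    df.to_csv(path, index=False)


def read_dwell_table(path: str | Path):
    """Read a dwell-interval CSV into a DwellDataset.

    Columns: ``cluster_id,state{open|closed},duration_s,conc_M,voltage_mV,
    construct``.  States must strictly alternate within each cluster; a
    violation is a :class:`FormatError` carrying the row number.
    """
    from sitecraft.kinetics import DwellDataset

    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: no records") from exc
    if df.empty:
        raise FormatError(f"{path}: no records")
    _require_columns(df, DWELL_COLUMNS, path)
    states = df["state"].astype(str).str.lower()
    bad_state = ~states.isin(["open", "closed"])
    if bad_state.any():
        row = int(np.flatnonzero(bad_state.to_numpy())[0])
        raise FormatError(f"{path}: state must be open|closed at row {row}")
    durations = pd.to_numeric(df["duration_s"], errors="coerce")
    bad = durations.isna() | (durations <= 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(f"{path}: bad duration_s at row {row}")
    # alternation check per cluster, in file order
    prev: dict = {}
    for row, (cid, state) in enumerate(zip(df["cluster_id"], states)):
        if prev.get(cid) == state:
            raise FormatError(
                f"{path}: consecutive {state!r} states in cluster {cid} at row {row}"
            )
        prev[cid] = state
    clusters = []
    for cid, grp in df.groupby("cluster_id", sort=False):
        clusters.append(
            [
                (s, float(d))
                for s, d in zip(grp["state"].str.lower(), grp["duration_s"])
            ]
        )
    return DwellDataset(
        clusters=clusters,
        conc_M=float(df["conc_M"].iloc[0]),
        voltage_mV=float(df["voltage_mV"].iloc[0]),
        construct=str(df["construct"].iloc[0]),
    )


def write_dwell_table(dataset, path: str | Path) -> None:
    rows = []
    for cid, cluster in enumerate(dataset.clusters):
        for state, dur in cluster:
            rows.append(
                {
                    "cluster_id": cid,
                    "state": state,
                    "duration_s": dur,
                    "conc_M": dataset.conc_M,
                    "voltage_mV": dataset.voltage_mV,
                    "construct": dataset.construct,
                }
            )
    pd.DataFrame(rows, columns=DWELL_COLUMNS).to_csv(path, index=False)
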