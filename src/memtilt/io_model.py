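"""System data model and coordinate I/O.

The in-memory model is deliberately small: an ordered list of
:class:`Atom` records (static), plus :class:`Frame` objects carrying
coordinates and an orthorhombic box (dynamic).  Coordinates are stored in
Å internally; the GRO nm convention is converted at the I/O boundary.

Partial charges are not representable in PDB/GRO, so they arrive through a
plain-text sidecar charge table mapping (residue name, atom name) to
(charge in e, mass in u) — see :func:`load_charge_table`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "ParseError",
    "read_coordinates",
    "write_coordinates",
    "wrap_and_unwrap",
    "load_charge_table",
    "apply_charge_table",
    "standard_groups",
]


class ParseError(ValueError):
    """A coordinate file failed to parse; the message names the line."""


# Fallback masses for elements guessed from atom names (u).
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "F": 18.998,
}

_WATER_RESNAMES = {"SOL", "WAT", "HOH", "TIP3", "T3P", "SPC"}
_CATION_RESNAMES = {"NA", "NA+", "SOD"}
_ANION_RESNAMES = {"CL", "CL-", "CLA"}
_AMINO_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "NME", "ACE", "NHE",
}


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if stripped[:2].upper() in ("NA", "CL", "MG") and len(stripped) <= 3:
        return stripped[:2].upper()
    return stripped[:1].upper() if stripped else "C"


@dataclass
class Atom:
    """One atom: identity plus the per-atom physics inputs.

    ``charge`` is in elementary charges, ``mass`` in unified atomic mass
    units.  ``residue_index`` is 1-based, matching PDB/GRO conventions.
    """

    name: str
    residue_index: int
    residue_name: str
    charge: float = 0.0
    mass: float = 0.0
    element: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.charge):
            raise ValueError(f"atom {self.name}: charge must be finite")
        if self.element is None:
            self.element = _guess_element(self.name)
        if self.mass == 0.0:
            self.mass = _ELEMENT_MASSES.get(self.element, 12.011)
        if self.mass <= 0:
            raise ValueError(f"atom {self.name}: mass must be > 0")


class Topology:
    """Ordered atom list with named index-group selections.

    Groups are plain integer index arrays under names like ``"water"``,
    ``"Na+"``, ``"Cl-"``, ``"peptide"`` and ``"lipid_terminal_methyls"``;
    :func:`standard_groups` builds them from residue/atom names.
    """

    def __init__(self, atoms: Sequence[Atom], groups: dict[str, np.ndarray] | None = None,
                 charges_assigned: bool = False):
        if len(atoms) == 0:
            raise ValueError("empty system")
        self.atoms: list[Atom] = list(atoms)
        self.groups: dict[str, np.ndarray] = {}
        for name, idx in (groups or {}).items():
            self.set_group(name, idx)
        #: True once charges came from a charge table or a generator.
        self.charges_assigned = charges_assigned

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    def set_group(self, name: str, indices: Iterable[int]) -> None:
        idx = np.asarray(sorted(set(int(i) for i in indices)), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= len(self.atoms)):
            raise ValueError(f"group {name!r}: index out of range")
        self.groups[name] = idx

    def select(self, resname: str | None = None, name: str | None = None,
               residue_index: int | None = None) -> np.ndarray:
        """Indices of atoms matching all given residue/atom-name filters."""
        out = []
        for i, a in enumerate(self.atoms):
            if resname is not None and a.residue_name != resname:
                continue
            if name is not None and a.name != name:
                continue
            if residue_index is not None and a.residue_index != residue_index:
                continue
            out.append(i)
        return np.asarray(out, dtype=int)

    def residues(self) -> Iterator[tuple[int, np.ndarray]]:
        """Yield (residue_index, atom indices) in file order."""
        order: dict[int, list[int]] = {}
        for i, a in enumerate(self.atoms):
            order.setdefault(a.residue_index, []).append(i)
        for resid, idx in order.items():
            yield resid, np.asarray(idx, dtype=int)

    def total_charge(self) -> float:
        return float(self.charges.sum())


@dataclass
class Frame:
    """Coordinates (Å) and orthorhombic box lengths (Å) at one time (ns)."""

    time: float
    coordinates: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be > 0")


@dataclass
class Trajectory:
    """A topology plus a time-ordered list of frames."""

    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        for f in self.frames:
            if f.coordinates.shape[0] != self.topology.n_atoms:
                raise ValueError("frame atom count does not match topology")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)


# ---------------------------------------------------------------------------
# standard groups

def standard_groups(topology: Topology) -> Topology:
    """Populate the conventional named groups from residue/atom names.

    Terminal-methyl lipid markers are atoms named ``CM``/``CM1``/``CM2``
    or the lipid14-style ``C218``/``C318`` chain termini.
    """
    water, na, cl, pep, methyl = [], [], [], [], []
    for i, a in enumerate(topology.atoms):
        rn = a.residue_name.upper()
        if rn in _WATER_RESNAMES:
            water.append(i)
        elif rn in _CATION_RESNAMES:
            na.append(i)
        elif rn in _ANION_RESNAMES:
            cl.append(i)
        elif rn in _AMINO_RESNAMES:
            pep.append(i)
        if a.name.upper() in ("CM", "CM1", "CM2", "C218", "C318"):
            methyl.append(i)
    topology.set_group("water", water)
    topology.set_group("Na+", na)
    topology.set_group("Cl-", cl)
    topology.set_group("peptide", pep)
    topology.set_group("lipid_terminal_methyls", methyl)
    return topology


# ---------------------------------------------------------------------------
# GRO

def _detect_gro_precision(line: str) -> tuple[int, int]:
    """Return (field width, n decimals) of the position columns.

    GRO position fields are ``%(w).(w-5)f``; GROMACS infers the width from
    the decimal-point spacing and so do we.
    """
    tail = line[20:].rstrip("\n")
    dots = [i for i, ch in enumerate(tail) if ch == "."]
    if len(dots) < 2:
        raise ParseError("cannot detect GRO position format")
    width = dots[1] - dots[0]
    return width, width - 5


def _read_gro(path: Path) -> tuple[Topology, Frame]:
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: line 2: truncated GRO file")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as exc:
        raise ParseError(f"{path}: line 2: invalid atom count") from exc
    if n_atoms == 0:
        raise ParseError(f"{path}: line 2: empty system")
    if len(lines) < n_atoms + 3:
        raise ParseError(f"{path}: line {len(lines)}: truncated GRO file")

    width, _ = _detect_gro_precision(lines[2])
    atoms: list[Atom] = []
    coords = np.empty((n_atoms, 3), dtype=float)
    for k in range(n_atoms):
        ln = lines[2 + k]
        lineno = 3 + k
        try:
            resid = int(ln[0:5])
            resname = ln[5:10].strip()
            name = ln[10:15].strip()
            x = float(ln[20 + 0 * width:20 + 1 * width])
            y = float(ln[20 + 1 * width:20 + 2 * width])
            z = float(ln[20 + 2 * width:20 + 3 * width])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: line {lineno}: malformed GRO atom record") from exc
        atoms.append(Atom(name=name, residue_index=resid, residue_name=resname))
        coords[k] = (x, y, z)
    try:
        box_fields = [float(v) for v in lines[2 + n_atoms].split()]
        box = np.array(box_fields[:3], dtype=float)
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: line {3 + n_atoms}: malformed box line") from exc
    if len(box_fields) > 3 and any(abs(v) > 1e-9 for v in box_fields[3:]):
        raise ParseError(f"{path}: line {3 + n_atoms}: triclinic boxes are not supported")
    # nm -> Å
    return (standard_groups(_renumber_contiguous(Topology(atoms))),
            Frame(time=0.0, coordinates=coords * 10.0, box=box * 10.0))


def _write_gro(topology: Topology, frame: Frame, path: Path, ndec: int = 4) -> None:
    width = ndec + 5
    with open(path, "w") as fh:
        fh.write("written by memtilt\n")
        fh.write(f"{topology.n_atoms:5d}\n")
        for i, a in enumerate(topology.atoms):
            x, y, z = frame.coordinates[i] / 10.0  # Å -> nm
            fh.write(
                f"{a.residue_index % 100000:5d}{a.residue_name:<5.5s}"
                f"{a.name:>5.5s}{(i + 1) % 100000:5d}"
                f"{x:{width}.{ndec}f}{y:{width}.{ndec}f}{z:{width}.{ndec}f}\n"
            )
        bx, by, bz = frame.box / 10.0
        fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


# ---------------------------------------------------------------------------
# PDB

def _read_pdb(path: Path) -> tuple[Topology, Frame]:
    atoms: list[Atom] = []
    xyz: list[tuple[float, float, float]] = []
    box = None
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        rec = ln[:6]
        if rec == "CRYST1":
            try:
                box = np.array([float(ln[6:15]), float(ln[15:24]), float(ln[24:33])])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: malformed CRYST1") from exc
            angles = ln[33:54].split()
            if angles and any(abs(float(a) - 90.0) > 1e-3 for a in angles):
                raise ParseError(f"{path}: line {lineno}: non-orthorhombic box")
        elif rec in ("ATOM  ", "HETATM"):
            try:
                name = ln[12:16].strip()
                resname = ln[17:21].strip()
                resid = int(ln[22:26])
                x, y, z = float(ln[30:38]), float(ln[38:46]), float(ln[46:54])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: line {lineno}: malformed ATOM record") from exc
            atoms.append(Atom(name=name, residue_index=resid, residue_name=resname))
            xyz.append((x, y, z))
    if not atoms:
        raise ParseError(f"{path}: empty system")
    if box is None:
        raise ParseError(f"{path}: missing CRYST1 record (no box)")
    return (standard_groups(_renumber_contiguous(Topology(atoms))),
            Frame(time=0.0, coordinates=np.array(xyz), box=box))


def _write_pdb(topology: Topology, frame: Frame, path: Path) -> None:
    with open(path, "w") as fh:
        bx, by, bz = frame.box
        fh.write(f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}  90.00  90.00  90.00 P 1           1\n")
        for i, a in enumerate(topology.atoms):
            x, y, z = frame.coordinates[i]
            serial = (i + 1) % 100000
            name = a.name if len(a.name) >= 4 else f" {a.name:<3.3s}"
            fh.write(
                f"ATOM  {serial:5d} {name:<4.4s} {a.residue_name:<4.4s}"
                f"{a.residue_index % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"          {(a.element or ''):>2.2s}\n"
            )
        fh.write("END\n")


def _renumber_contiguous(topology: Topology) -> Topology:
    """Renumber residues 1..n by consecutive runs of the file's residue id.

    Run-based (not value-based) so 5-digit GRO serial wrap-around cannot
    merge distinct residues that share a wrapped number.
    """
    counter = 0
    prev_raw: int | None = None
    for a in topology.atoms:
        if a.residue_index != prev_raw:
            counter += 1
            prev_raw = a.residue_index
        a.residue_index = counter
    return topology


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.upper()
    else:
        fmt = path.suffix.lstrip(".").upper()
    if fmt not in ("PDB", "GRO"):
        raise ValueError(f"unsupported coordinate format: {fmt!r}")
    return fmt


def read_coordinates(path: str | Path, format: str | None = None) -> tuple[Topology, Frame]:
    """Read a PDB or GRO file into (Topology, Frame).

    Charges default to 0 (unassigned) and masses to standard element
    masses; override with :func:`apply_charge_table`.  Residue numbers in
    the file may wrap (GRO 5-digit fields); they are renumbered to be
    unique and contiguous from 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    return _read_gro(path) if fmt == "GRO" else _read_pdb(path)


def write_coordinates(system: tuple[Topology, Frame], path: str | Path,
                      format: str | None = None) -> Path:
    """Write (Topology, Frame) to PDB or GRO; re-readable by
    :func:`read_coordinates` with coordinates preserved to format precision
    (GRO is written with 4 decimals in nm, i.e. 0.001 Å)."""
    topology, frame = system
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "GRO":
        _write_gro(topology, frame, path)
    else:
        _write_pdb(topology, frame, path)
    return path


# ---------------------------------------------------------------------------
# wrapping

def wrap_positions(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the primary box [0, L) per axis."""
    return np.mod(coords, box)


def wrap_and_unwrap(frame: Frame, topology: Topology) -> Frame:
    """Wrap atoms into the box, then make each residue whole.

    After wrapping, every atom of a residue is shifted by whole box vectors
    so it sits within half a box length of the residue's first atom
    (minimum-image unwrap).  Required before any residue center-of-mass.
    """
    box = frame.box
    coords = wrap_positions(frame.coordinates, box)
    for _, idx in topology.residues():
        anchor = coords[idx[0]]
        delta = coords[idx] - anchor
        coords[idx] = anchor + delta - np.round(delta / box) * box
        extent = coords[idx].max(axis=0) - coords[idx].min(axis=0)
        if np.any(extent > box / 2):
            warnings.warn(
                f"residue {topology.atoms[idx[0]].residue_index} spans more "
                "than half the box after unwrapping", stacklevel=2)
    return Frame(time=frame.time, coordinates=coords, box=box.copy())


# ---------------------------------------------------------------------------
# charge tables

def load_charge_table(path: str | Path) -> dict[tuple[str, str], tuple[float, float]]:
    """Parse a whitespace-separated sidecar table.

    Columns: residue_name atom_name charge_e mass_u; ``#`` starts a comment.
    A residue name of ``*`` matches any residue.
    """
    table: dict[tuple[str, str], tuple[float, float]] = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        parts = ln.split()
        if len(parts) != 4:
            raise ParseError(f"{path}: line {lineno}: expected 4 columns")
        resname, name, q, m = parts
        table[(resname, name)] = (float(q), float(m))
    return table


def apply_charge_table(topology: Topology,
                       table: dict[tuple[str, str], tuple[float, float]]) -> Topology:
    """Assign charges/masses from a table; error on the first uncovered atom."""
    for i, a in enumerate(topology.atoms):
        entry = table.get((a.residue_name, a.name)) or table.get(("*", a.name))
        if entry is None:
            raise KeyError(
                f"charge table does not cover atom {i} "
                f"({a.residue_name}/{a.name})")
        a.charge, a.mass = entry
    topology.charges_assigned = True
    return topology
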