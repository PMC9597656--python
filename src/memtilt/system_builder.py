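"""Double-bilayer compartment construction with salt gradients.

A double-bilayer box — a single-bilayer system duplicated and translated
along z — encloses two separated aqueous compartments, so an excess of
NaCl placed in the central compartment (the intracellular mimic) sets up
a sustained transmembrane potential under periodic boundaries.  The
builder performs the construction steps with exact bookkeeping: duplicate
and translate, substitute compartment waters by ions, set a net ionic
charge imbalance between compartments, and delete selections (peptide and
counterions), each returning a :class:`BuildReport` whose arithmetic is
verifiable against the output coordinates.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .io_model import Atom, Frame, Topology, standard_groups
from .units import L_PER_A3, N_AVOGADRO

__all__ = ["BuildReport", "CompartmentGeometry", "duplicate_translate",
           "add_salt", "set_ion_imbalance", "delete_selection",
           "WATER_VOLUME_A3", "MIN_ION_SEPARATION_A"]

#: Effective volume per water molecule used for molarity → count
#: conversion (Å³); printed in every report that uses it.
WATER_VOLUME_A3 = 30.0
#: Minimum allowed distance between placed ions (Å).
MIN_ION_SEPARATION_A = 3.5

_ION_PARAMS = {"NA": ("NA", +1.0, 22.990), "CL": ("CL", -1.0, 35.45)}


@dataclass
class CompartmentGeometry:
    """Central compartment z range; the external one is its periodic
    complement.  ``detection`` labels how the ranges were obtained."""

    central: tuple[float, float]
    detection: str = "user-supplied"

    def contains_central(self, z: float | np.ndarray, lz: float) -> np.ndarray:
        lo, hi = self.central
        z = np.mod(np.asarray(z, dtype=float), lz)
        if lo <= hi:
            return (z >= lo) & (z < hi)
        return (z >= lo) | (z < hi)


@dataclass
class BuildReport:
    operation: str
    atoms_before: int
    atoms_after: int
    ions_added: dict[str, dict[str, int]] = field(default_factory=dict)
    waters_removed: int = 0
    net_charge_before: float = 0.0
    net_charge_after: float = 0.0
    compartment_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int | None = None
    notes: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        lines = [f"build report: {self.operation}",
                 f"  atoms: {self.atoms_before} -> {self.atoms_after}",
                 f"  net charge (e): {self.net_charge_before:+.3f} -> "
                 f"{self.net_charge_after:+.3f}"]
        for sp, comps in self.ions_added.items():
            for comp, n in comps.items():
                lines.append(f"  ions added: {sp} x{n} in {comp}")
        if self.waters_removed:
            lines.append(f"  waters removed: {self.waters_removed}")
        for name, rng in self.compartment_ranges.items():
            lines.append(f"  compartment {name}: z in [{rng[0]:.2f}, {rng[1]:.2f}] Å")
        if self.seed is not None:
            lines.append(f"  seed: {self.seed}")
        lines.extend(f"  note: {n}" for n in self.notes)
        return "\n".join(lines)


def _rebuild(atoms: list[Atom], coords: np.ndarray, box: np.ndarray,
             charges_assigned: bool, time: float = 0.0) -> tuple[Topology, Frame]:
    top = Topology(atoms, charges_assigned=charges_assigned)
    standard_groups(top)
    return top, Frame(time=time, coordinates=coords, box=box)


def _renumber(atoms: list[Atom]) -> None:
    mapping: dict[int, int] = {}
    for a in atoms:
        if a.residue_index not in mapping:
            mapping[a.residue_index] = len(mapping) + 1
        a.residue_index = mapping[a.residue_index]


def duplicate_translate(system: tuple[Topology, Frame]
                        ) -> tuple[tuple[Topology, Frame], BuildReport]:
    """Duplicate the system and translate the copy by +Lz; box z doubles.

    Residue numbering of the copy continues after the original so every
    residue stays unique.
    """
    top, frame = system
    if frame.box.shape != (3,):
        raise ValueError("orthorhombic box required")
    max_resid = max(a.residue_index for a in top.atoms)
    atoms = [copy.copy(a) for a in top.atoms]
    for a in top.atoms:
        b = copy.copy(a)
        b.residue_index = a.residue_index + max_resid
        atoms.append(b)
    coords = np.vstack([frame.coordinates,
                        frame.coordinates + np.array([0.0, 0.0, frame.box[2]])])
    box = frame.box * np.array([1.0, 1.0, 2.0])
    out = _rebuild(atoms, coords, box, top.charges_assigned, frame.time)
    report = BuildReport(operation="duplicate_translate",
                         atoms_before=top.n_atoms, atoms_after=2 * top.n_atoms,
                         net_charge_before=top.total_charge(),
                         net_charge_after=out[0].total_charge())
    return out, report


def _water_residues(top: Topology) -> dict[int, np.ndarray]:
    """residue_index -> atom indices for every water molecule."""
    widx = set(top.groups.get("water", np.array([], dtype=int)).tolist())
    out: dict[int, list[int]] = {}
    for i in widx:
        out.setdefault(top.atoms[i].residue_index, []).append(i)
    return {r: np.asarray(sorted(v), dtype=int) for r, v in out.items()}


def _oxygen_of(top: Topology, idx: np.ndarray) -> int:
    for i in idx:
        if (top.atoms[i].element or "").upper() == "O":
            return int(i)
    return int(idx[0])


def _min_image_dist(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    d = a - b
    d -= np.round(d / box) * box
    return float(np.linalg.norm(d))


def add_salt(system: tuple[Topology, Frame], compartment: CompartmentGeometry,
             n_na: int | None = None, n_cl: int | None = None,
             concentration: float | None = None, seed: int = 0,
             max_redraws: int = 500
             ) -> tuple[tuple[Topology, Frame], BuildReport]:
    """Substitute compartment waters by Na⁺/Cl⁻ ions.

    Either explicit counts or a molar concentration may be given; with a
    concentration, counts = round(c·N_A·V) where V is (compartment water
    count)·30 Å³ per water.  Ions take the water-oxygen position (the two
    hydrogens are deleted); a minimum pairwise ion separation of 3.5 Å is
    enforced by seeded re-draws.
    """
    top, frame = system
    lz = float(frame.box[2])
    waters = _water_residues(top)
    in_comp = {r: idx for r, idx in waters.items()
               if compartment.contains_central(
                   frame.coordinates[_oxygen_of(top, idx), 2], lz)}
    notes: list[str] = []
    if concentration is not None:
        v_l = len(in_comp) * WATER_VOLUME_A3 * L_PER_A3
        n_pairs = int(round(concentration * N_AVOGADRO * v_l))
        if n_na is None:
            n_na = n_pairs
        if n_cl is None:
            n_cl = n_pairs
        notes.append(f"{concentration} mol/L over {len(in_comp)} waters x "
                     f"{WATER_VOLUME_A3} Å³ -> {n_pairs} ion pairs")
    n_na = int(n_na or 0)
    n_cl = int(n_cl or 0)
    if n_na < 0 or n_cl < 0:
        raise ValueError("ion counts must be >= 0")
    n_total = n_na + n_cl
    report = BuildReport(operation="add_salt", atoms_before=top.n_atoms,
                         atoms_after=top.n_atoms,
                         net_charge_before=top.total_charge(),
                         net_charge_after=top.total_charge(),
                         compartment_ranges={"central": compartment.central},
                         seed=seed, notes=notes)
    if n_total == 0:
        return (top, frame), report
    if len(in_comp) < n_total:
        raise ValueError(
            f"insufficient waters in compartment: need {n_total}, "
            f"have {len(in_comp)}")

    rng = np.random.default_rng(seed)
    candidates = list(in_comp.keys())
    rng.shuffle(candidates)
    chosen: list[int] = []
    # respect the separation against pre-existing ions as well
    existing = np.concatenate([top.groups.get("Na+", np.array([], dtype=int)),
                               top.groups.get("Cl-", np.array([], dtype=int))])
    positions: list[np.ndarray] = [frame.coordinates[i] for i in existing]
    draws = 0
    for resid in candidates:
        if len(chosen) == n_total:
            break
        pos = frame.coordinates[_oxygen_of(top, in_comp[resid])]
        if all(_min_image_dist(pos, p, frame.box) >= MIN_ION_SEPARATION_A
               for p in positions):
            chosen.append(resid)
            positions.append(pos)
        else:
            draws += 1
            if draws > max_redraws:
                raise ValueError(
                    f"could not satisfy {MIN_ION_SEPARATION_A} Å separation; "
                    f"achieved {len(chosen)}/{n_total} ions")
    if len(chosen) < n_total:
        raise ValueError(
            f"could not place all ions; achieved {len(chosen)}/{n_total}")

    species = ["NA"] * n_na + ["CL"] * n_cl
    replace = dict(zip(chosen, species))
    atoms: list[Atom] = []
    keep_coords: list[np.ndarray] = []
    for i, a in enumerate(top.atoms):
        resid = a.residue_index
        if resid in replace:
            oi = _oxygen_of(top, in_comp[resid])
            if i == oi:
                name, q, m = _ION_PARAMS[replace[resid]]
                atoms.append(Atom(name=name, residue_index=resid,
                                  residue_name=name, charge=q, mass=m,
                                  element=name))
                keep_coords.append(frame.coordinates[i])
            # hydrogens dropped
        else:
            atoms.append(copy.copy(a))
            keep_coords.append(frame.coordinates[i])
    _renumber(atoms)
    out = _rebuild(atoms, np.asarray(keep_coords), frame.box,
                   top.charges_assigned, frame.time)
    report.atoms_after = out[0].n_atoms
    report.waters_removed = n_total
    report.ions_added = {"Na+": {"central": n_na}, "Cl-": {"central": n_cl}}
    report.net_charge_after = out[0].total_charge()
    return out, report


def _compartment_ion_charge(top: Topology, frame: Frame,
                            compartment: CompartmentGeometry
                            ) -> tuple[float, float]:
    lz = float(frame.box[2])
    q_cent = q_ext = 0.0
    ions = np.concatenate([top.groups.get("Na+", np.array([], dtype=int)),
                           top.groups.get("Cl-", np.array([], dtype=int))])
    for i in ions:
        q = top.atoms[i].charge
        if compartment.contains_central(frame.coordinates[i, 2], lz):
            q_cent += q
        else:
            q_ext += q
    return q_cent, q_ext


def set_ion_imbalance(system: tuple[Topology, Frame],
                      net_charge: int, compartment: CompartmentGeometry,
                      seed: int = 0
                      ) -> tuple[tuple[Topology, Frame], BuildReport]:
    """Move ions between compartments until (external − central) ionic
    charge equals ``net_charge`` (e).

    Each move swaps an ion with a randomly chosen water molecule in the
    destination compartment (the water is translated to the ion's old
    site), so atom counts and total charge are exactly conserved; one
    cation move changes the imbalance by 2 e.
    """
    top, frame = system
    top = Topology([copy.copy(a) for a in top.atoms],
                   charges_assigned=top.charges_assigned)
    standard_groups(top)
    coords = frame.coordinates.copy()
    lz = float(frame.box[2])
    rng = np.random.default_rng(seed)

    def imbalance() -> float:
        fr = Frame(frame.time, coords, frame.box)
        q_cent, q_ext = _compartment_ion_charge(top, fr, compartment)
        return q_ext - q_cent

    start = imbalance()
    delta = net_charge - start
    if abs(delta) % 2 != 0:
        raise ValueError(
            f"requested imbalance {net_charge:+d} unreachable from "
            f"{start:+.0f} by moving ions (parity)")
    moves = int(abs(delta) // 2)
    waters = _water_residues(top)
    for _ in range(moves):
        # choose an ion whose move shifts the imbalance the right way
        want_increase = delta > 0
        candidates = []
        for grp, q in (("Na+", +1), ("Cl-", -1)):
            for i in top.groups.get(grp, np.array([], dtype=int)):
                in_cent = bool(compartment.contains_central(coords[i, 2], lz))
                # moving out of central adds +2q*? to (ext - cent)
                change = 2 * q if in_cent else -2 * q
                if (change > 0) == want_increase:
                    candidates.append((i, in_cent))
        if not candidates:
            raise ValueError("not enough movable ions to reach the "
                             "requested imbalance")
        ion_i, ion_in_cent = candidates[rng.integers(len(candidates))]
        # destination waters are in the opposite compartment
        dest = [r for r, idx in waters.items()
                if compartment.contains_central(
                    coords[_oxygen_of(top, idx), 2], lz) != ion_in_cent]
        if not dest:
            raise ValueError("no destination water for ion move")
        w_res = dest[rng.integers(len(dest))]
        w_idx = waters[w_res]
        oi = _oxygen_of(top, w_idx)
        ion_pos = coords[ion_i].copy()
        shift = ion_pos - coords[oi]
        coords[ion_i] = coords[oi].copy()
        coords[w_idx] += shift  # rigid water translation to the old ion site
    fr = Frame(frame.time, coords, frame.box)
    q_cent, q_ext = _compartment_ion_charge(top, fr, compartment)
    report = BuildReport(
        operation="set_ion_imbalance", atoms_before=top.n_atoms,
        atoms_after=top.n_atoms, net_charge_before=top.total_charge(),
        net_charge_after=top.total_charge(),
        compartment_ranges={"central": compartment.central}, seed=seed,
        notes=[f"ionic charge central {q_cent:+.0f} e, external {q_ext:+.0f} e,"
               f" imbalance {q_ext - q_cent:+.0f} e"])
    return (top, fr), report


def delete_selection(system: tuple[Topology, Frame], selection: np.ndarray
                     ) -> tuple[tuple[Topology, Frame], BuildReport]:
    """Remove the selected atoms; residues are renumbered contiguously."""
    top, frame = system
    selection = set(int(i) for i in np.asarray(selection, dtype=int))
    removed_q = sum(top.atoms[i].charge for i in selection)
    atoms = [copy.copy(a) for i, a in enumerate(top.atoms)
             if i not in selection]
    if not atoms:
        raise ValueError("empty system")
    coords = np.array([frame.coordinates[i] for i in range(top.n_atoms)
                       if i not in selection])
    _renumber(atoms)
    out = _rebuild(atoms, coords, frame.box, top.charges_assigned, frame.time)
    report = BuildReport(operation="delete_selection",
                         atoms_before=top.n_atoms, atoms_after=out[0].n_atoms,
                         net_charge_before=top.total_charge(),
                         net_charge_after=out[0].total_charge(),
                         notes=[f"removed charge {removed_q:+.3f} e"])
    return out, report
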