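"""Normalized z number-density profiles referenced to the membrane center.

The membrane center is defined as the average z position of the lipids'
terminal methyl groups; profiles of peptide residues, ions or the whole
system are binned in membrane-centered coordinates so the center sits at
0 Å.  System-wide profiles of double-bilayer boxes can instead be
box-referenced (``reference="box"``) since no single membrane center is
meaningful there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_model import Frame, Topology, Trajectory

__all__ = ["DensityProfile", "MembraneFrame", "membrane_center", "density"]


@dataclass
class MembraneFrame:
    """Membrane center and leaflet assignment for one frame."""

    center_z: float
    leaflets: dict[str, np.ndarray]  # residue indices of "upper"/"lower"


@dataclass
class DensityProfile:
    """Number density vs membrane-centered z, normalized to max 1."""

    z_centers: np.ndarray        # Å, 0 at the reference center
    rho: np.ndarray              # Å^-3
    rho_norm: np.ndarray
    selection_label: str = ""

    def write(self, path) -> None:
        np.savetxt(path, np.column_stack([self.z_centers, self.rho_norm]),
                   header=f"z_center_A rho_norm  # selection: {self.selection_label}")


def membrane_center(frame: Frame, topology: Topology,
                    bilayer: np.ndarray | None = None) -> MembraneFrame:
    """Membrane center = mean wrapped z of the terminal methyl markers.

    ``bilayer`` restricts the marker atoms considered (for double-bilayer
    systems pass the marker indices of one bilayer); defaults to the
    topology's ``lipid_terminal_methyls`` group.
    """
    if bilayer is None:
        bilayer = topology.groups.get("lipid_terminal_methyls",
                                      np.array([], dtype=int))
    bilayer = np.asarray(bilayer, dtype=int)
    if bilayer.size == 0:
        raise ValueError("empty terminal-methyl selection")
    lz = frame.box[2]
    z = np.mod(frame.coordinates[bilayer, 2], lz)
    center = float(z.mean())
    resids = topology.residue_indices[bilayer]
    upper = np.unique(resids[z > center])
    lower = np.unique(resids[z < center])
    if upper.size == 0 or lower.size == 0:
        warnings.warn("one leaflet is empty (all markers at one z)",
                      stacklevel=2)
    return MembraneFrame(center_z=center,
                         leaflets={"upper": upper, "lower": lower})


def density(trajectory: Trajectory, selection: np.ndarray, n_slices: int,
            reference: str = "membrane",
            bilayer: np.ndarray | None = None,
            label: str = "") -> DensityProfile:
    """z number-density profile of an atom selection, averaged over frames.

    ``reference="membrane"`` recenters each frame on that frame's membrane
    center (per-frame, so membrane drift does not blur the profile);
    ``reference="box"`` keeps box coordinates with z measured from the box
    center.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    top = trajectory.topology
    box = trajectory.frames[0].box
    lz = float(box[2])
    area = float(box[0] * box[1])
    edges = np.linspace(-lz / 2, lz / 2, n_slices + 1)
    dz = edges[1] - edges[0]
    acc = np.zeros(n_slices)
    for fr in trajectory.frames:
        if reference == "membrane":
            c = membrane_center(fr, top, bilayer).center_z
        elif reference == "box":
            c = lz / 2.0
        else:
            raise ValueError("reference must be 'membrane' or 'box'")
        z = np.mod(fr.coordinates[selection, 2] - c + lz / 2, lz) - lz / 2
        idx = np.minimum(((z + lz / 2) / dz).astype(int), n_slices - 1)
        acc += np.bincount(idx, minlength=n_slices)
    rho = acc / trajectory.n_frames / (area * dz)
    peak = rho.max()
    rho_norm = rho / peak if peak > 0 else rho.copy()
    return DensityProfile(z_centers=0.5 * (edges[:-1] + edges[1:]),
                          rho=rho, rho_norm=rho_norm, selection_label=label)
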