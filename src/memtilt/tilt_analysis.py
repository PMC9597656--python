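"""Helix tilt angle τ and its distribution.

τ is the angle between the vector joining the mass-weighted centers of
mass of two anchor residues (defaults 3 and 20, skipping the flexible
termini) and the +z unit vector, reported raw in [0, 180]°: a
surface-parallel helix gives τ ≈ 90°, C-terminus-down insertion gives
τ > 90°.  No folding about 90° and no per-leaflet sign convention is
applied — the caller owns leaflet context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import Frame, Topology, Trajectory, wrap_and_unwrap

__all__ = ["TiltSeries", "TiltHistogram", "tilt_angle", "tilt_series",
           "tilt_histogram"]


class DegenerateAxisError(ValueError):
    pass


@dataclass
class TiltSeries:
    times: np.ndarray  # ns
    tau: np.ndarray    # degrees, [0, 180]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if np.any((self.tau < 0) | (self.tau > 180)):
            raise ValueError("tau out of [0, 180] degrees")

    def write(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.tau]),
                   header="time_ns tau_deg")


@dataclass
class TiltHistogram:
    bin_edges: np.ndarray            # degrees
    counts: np.ndarray
    fraction_above: dict[float, float]


def _residue_com(frame: Frame, topology: Topology, residue_index: int) -> np.ndarray:
    idx = np.array([i for i, a in enumerate(topology.atoms)
                    if a.residue_index == residue_index], dtype=int)
    if idx.size == 0:
        raise ValueError(f"residue {residue_index} not found")
    m = topology.masses[idx]
    total = m.sum()
    if total <= 0:
        raise ValueError(f"residue {residue_index} has non-positive mass")
    return (frame.coordinates[idx] * m[:, None]).sum(axis=0) / total


def tilt_angle(frame: Frame, topology: Topology, res_a: int = 3,
               res_b: int = 20, unwrap: bool = True) -> float:
    """τ (degrees) between COM(res_b) − COM(res_a) and +z.

    Residues are made whole (minimum-image unwrap) before the COM so the
    axis vector is meaningful under periodic boundaries; pass
    ``unwrap=False`` if the coordinates are already whole.
    """
    if unwrap:
        frame = wrap_and_unwrap(frame, topology)
    v = _residue_com(frame, topology, res_b) - _residue_com(frame, topology, res_a)
    norm = float(np.linalg.norm(v))
    if norm < 0.1:
        raise DegenerateAxisError(
            f"degenerate axis: |COM({res_b}) - COM({res_a})| = {norm:.3g} Å")
    cos = np.clip(v[2] / norm, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def tilt_series(trajectory: Trajectory, res_a: int = 3, res_b: int = 20,
                unwrap: bool = True) -> TiltSeries:
    """τ for every frame, in input order."""
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    taus = []
    for i, fr in enumerate(trajectory.frames):
        try:
            taus.append(tilt_angle(fr, trajectory.topology, res_a, res_b,
                                   unwrap=unwrap))
        except ValueError as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
    return TiltSeries(times=trajectory.times, tau=np.asarray(taus))


def tilt_histogram(series: TiltSeries, bin_width: float = 1.0,
                   thresholds: list[float] | None = None) -> TiltHistogram:
    """Histogram of τ over [0, 180]° plus exceedance fractions.

    ``fraction_above[θ]`` is the fraction of frames with τ > θ (the
    tilted-state occupancy when θ separates the S and T states).
    """
    if thresholds is None:
        thresholds = [120.0]
    if series.tau.size == 0:
        raise ValueError("empty series")
    n_bins = 180.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin width must divide 180 degrees")
    edges = np.linspace(0.0, 180.0, int(round(n_bins)) + 1)
    counts, _ = np.histogram(series.tau, bins=edges)
    n = series.tau.size
    frac = {float(th): float(np.sum(series.tau > th)) / n for th in thresholds}
    return TiltHistogram(bin_edges=edges, counts=counts, fraction_above=frac)
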