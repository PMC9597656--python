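"""Synthetic fixtures with known ground truth.

Every analysis stage in the package is exercised against systems whose
answer is known analytically or by construction:

* a parallel-plate capacitor of discrete point charges, whose plateau
  potential difference is σ·d/ε₀ exactly — the oracle for the Poisson
  double integration;
* a geometrically valid mock bilayer (rod-like pseudo-lipids with
  terminal-methyl markers, a water slab, neutralizing cations at the
  surfaces) for membrane-center, density and builder tests;
* a rigid pseudo-helix hopping between a surface-parallel and a tilted
  state via a two-state Markov chain, with a surrogate transmembrane
  potential linearly coupled to the windowed tilt angle plus noise — the
  end-to-end fixture for the tilt/window/clustering/regression pipeline;
* seeded samplers from arbitrary Boltzmann distributions for the
  free-energy inversion.

Each generator returns a machine-readable truth record; recovery tests
read expected values only from it.  All generators are bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .io_model import Atom, Frame, Topology, Trajectory, standard_groups
from .potential_profile import TMPSeries
from .units import E_OVER_EPS0_MV_ANG, kbt_kcal_mol

__all__ = [
    "CapacitorSpec", "TwoStateSpec", "TwoStateTruth",
    "gen_capacitor", "gen_mock_bilayer", "gen_two_state_helix",
    "gen_boltzmann_samples", "SYNTHETIC_CHARGE_TABLE",
]

#: Sidecar charge table covering every residue/atom the generators emit
#: (whitespace columns: resname atomname charge_e mass_u).
SYNTHETIC_CHARGE_TABLE = """\
# synthetic-system charge table (resname atomname charge_e mass_u)
LIP   HD    0.30   80.0
LIP   CT   -0.30  160.0
LIP   CM    0.00   15.0
LIPA  HD   -0.70   80.0
LIPA  CT   -0.30  160.0
LIPA  CM    0.00   15.0
SOL   OW   -0.834  15.999
SOL   HW1   0.417   1.008
SOL   HW2   0.417   1.008
NA    NA    1.00   22.990
CL    CL   -1.00   35.45
ALA   CA    0.00   71.0
CAP   QP    0.00    1.0
CAP   QN    0.00    1.0
"""


# ---------------------------------------------------------------------------
# capacitor

@dataclass
class CapacitorSpec:
    """Two oppositely charged sheets of point charges inside a box."""

    box: tuple[float, float, float] = (40.0, 40.0, 80.0)
    z1: float = 30.0   # +σ plate, Å
    z2: float = 50.0   # −σ plate, Å
    sigma: float = 0.01           # e/Å²
    charges_per_plate: int = 64   # laid out on a √n × √n grid

    def __post_init__(self) -> None:
        if not (0 < self.z1 < self.z2 < self.box[2]):
            raise ValueError("plates must satisfy 0 < z1 < z2 < Lz")

    @property
    def analytic_tmp_mv(self) -> float:
        """Plateau potential drop across the plates, σ·d/ε₀ (mV).

        The plateau beyond the −σ plate sits this far *below* the plateau
        before the +σ plate.
        """
        return self.sigma * (self.z2 - self.z1) * E_OVER_EPS0_MV_ANG


def gen_capacitor(spec: CapacitorSpec, n_frames: int = 1,
                  dt_ns: float = 1.0) -> tuple[Trajectory, dict]:
    """Static trajectory of ±σ point-charge sheets plus analytic truth."""
    lx, ly, lz = spec.box
    g = int(round(np.sqrt(spec.charges_per_plate)))
    if g * g != spec.charges_per_plate:
        raise ValueError("charges_per_plate must be a perfect square")
    q = spec.sigma * lx * ly / spec.charges_per_plate
    xs = (np.arange(g) + 0.5) * lx / g
    ys = (np.arange(g) + 0.5) * ly / g
    xx, yy = np.meshgrid(xs, ys)
    atoms: list[Atom] = []
    coords: list[list[float]] = []
    for resid, (zp, name, qq) in enumerate(
            [(spec.z1, "QP", q), (spec.z2, "QN", -q)], start=1):
        for x, y in zip(xx.ravel(), yy.ravel()):
            atoms.append(Atom(name=name, residue_index=resid,
                              residue_name="CAP", charge=qq, mass=1.0))
            coords.append([x, y, zp])
    top = standard_groups(Topology(atoms, charges_assigned=True))
    base = np.asarray(coords)
    frames = [Frame(time=i * dt_ns, coordinates=base.copy(),
                    box=np.array(spec.box)) for i in range(n_frames)]
    truth = {
        "analytic_tmp_mv": spec.analytic_tmp_mv,
        "sigma_e_per_A2": spec.sigma,
        "separation_A": spec.z2 - spec.z1,
        "plateau_low_side": "above z2",
    }
    return Trajectory(topology=top, frames=frames), truth


# ---------------------------------------------------------------------------
# mock bilayer

def gen_mock_bilayer(n_lipids: int = 100, n_waters: int = 1500,
                     anionic_fraction: float = 0.2,
                     box: tuple[float, float, float] = (40.0, 40.0, 80.0),
                     seed: int = 0) -> tuple[Topology, Frame, str, dict]:
    """Single mock bilayer: two leaflets of 3-bead rod lipids, water
    slabs, and neutralizing Na⁺ at the headgroup surfaces.

    Lipid beads: HD (headgroup, carries the lipid charge dipole or the
    −1 e of an anionic lipid), CT (chain), CM (terminal methyl marker
    near the membrane center).  An ``anionic_fraction`` of lipids carries
    −1 e, neutralized by the same number of Na⁺ counterions placed in the
    electrical-double-layer region next to the headgroups — emulating the
    interfacial cation accumulation of an anionic membrane.

    Returns (topology, frame, charge-table text, truth record).
    """
    if n_lipids < 2 or n_waters < 1:
        raise ValueError("counts must be positive (>= 2 lipids)")
    rng = np.random.default_rng(seed)
    lx, ly, lz = box
    zc = lz / 2.0
    half = 15.0                    # monolayer thickness
    n_anionic = int(round(anionic_fraction * n_lipids))
    per_leaflet = n_lipids // 2

    charge_map = {
        ("LIP", "HD"): 0.30, ("LIP", "CT"): -0.30, ("LIP", "CM"): 0.0,
        ("LIPA", "HD"): -0.70, ("LIPA", "CT"): -0.30, ("LIPA", "CM"): 0.0,
        ("SOL", "OW"): -0.834, ("SOL", "HW1"): 0.417, ("SOL", "HW2"): 0.417,
        ("NA", "NA"): 1.0,
    }
    mass_map = {"HD": 80.0, "CT": 160.0, "CM": 15.0, "OW": 15.999,
                "HW1": 1.008, "HW2": 1.008, "NA": 22.990}

    atoms: list[Atom] = []
    coords: list[list[float]] = []
    resid = 0
    # which lipids are anionic (spread over both leaflets)
    anionic_ids = set(rng.choice(n_lipids, size=n_anionic, replace=False).tolist())

    g = int(np.ceil(np.sqrt(per_leaflet)))
    lipid_no = 0
    for leaflet, sign in (("lower", -1), ("upper", +1)):
        placed = 0
        for i in range(g):
            for j in range(g):
                if placed >= per_leaflet:
                    break
                resid += 1
                resname = "LIPA" if lipid_no in anionic_ids else "LIP"
                x = (i + 0.5) * lx / g
                y = (j + 0.5) * ly / g
                z_hd = zc + sign * half
                z_ct = zc + sign * half * 0.5
                z_cm = zc + sign * 1.0
                for name, z in (("HD", z_hd), ("CT", z_ct), ("CM", z_cm)):
                    atoms.append(Atom(name=name, residue_index=resid,
                                      residue_name=resname,
                                      charge=charge_map[(resname, name)],
                                      mass=mass_map[name]))
                    coords.append([x, y, z])
                placed += 1
                lipid_no += 1

    # water slabs, 3 Å clear of the headgroups
    margin = 3.0
    slabs = [(margin, zc - half - margin), (zc + half + margin, lz - margin)]
    spacing = 3.1
    sites: list[list[float]] = []
    for zlo, zhi in slabs:
        nx = max(int(lx / spacing), 1)
        ny = max(int(ly / spacing), 1)
        nz = max(int((zhi - zlo) / spacing), 1)
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    sites.append([(i + 0.5) * lx / nx, (j + 0.5) * ly / ny,
                                  zlo + (k + 0.5) * (zhi - zlo) / nz])
    if len(sites) < n_waters:
        raise ValueError(
            f"water slab holds only {len(sites)} sites < {n_waters}")
    order = rng.permutation(len(sites))
    water_sites = [sites[i] for i in order[:n_waters]]
    for ws in water_sites:
        resid += 1
        for name, off in (("OW", (0.0, 0.0, 0.0)),
                          ("HW1", (0.76, 0.0, 0.59)),
                          ("HW2", (-0.76, 0.0, 0.59))):
            atoms.append(Atom(name=name, residue_index=resid,
                              residue_name="SOL",
                              charge=charge_map[("SOL", name)],
                              mass=mass_map[name]))
            coords.append([ws[0] + off[0], ws[1] + off[1], ws[2] + off[2]])

    # counter-cations in the double-layer region next to each headgroup plane
    surf_z = [zc - half + 1.5 - margin, zc + half - 1.5 + margin]
    for i in range(n_anionic):
        resid += 1
        z = surf_z[i % 2] + rng.uniform(-1.0, 1.0)
        atoms.append(Atom(name="NA", residue_index=resid, residue_name="NA",
                          charge=1.0, mass=22.990))
        coords.append([rng.uniform(0, lx), rng.uniform(0, ly), z])

    top = standard_groups(Topology(atoms, charges_assigned=True))
    frame = Frame(time=0.0, coordinates=np.asarray(coords), box=np.array(box))
    truth = {
        "membrane_center_z": zc,
        "n_lipids": 2 * per_leaflet,
        "n_anionic": n_anionic,
        "n_counterions": n_anionic,
        "n_waters": n_waters,
        "net_charge": top.total_charge(),
        "water_slabs": slabs,
        "seed": seed,
    }
    return top, frame, SYNTHETIC_CHARGE_TABLE, truth


# ---------------------------------------------------------------------------
# two-state helix

@dataclass
class TwoStateSpec:
    """Two-orientation-state helix with TMP–tilt coupling.

    The helix hops between a surface-parallel state (τ ≈ 90°) and a
    tilted state (τ ≈ 110°) via a two-state Markov chain with stationary
    tilted-state occupancy ``occupancy``.  The surrogate TMP per analysis
    window is ``intercept + slope·⟨τ⟩_window + noise``; if
    ``coupling_noise_sd`` is None the noise is calibrated so the expected
    windowed regression r² equals ``target_r2``.  Slope/intercept defaults
    follow the observed cluster trend of roughly −6 mV per degree with
    ≈ −18 mV at τ = 95°.
    """

    tau_states: tuple[float, float] = (90.0, 110.0)
    state_sds: tuple[float, float] = (2.0, 2.0)
    occupancy: float = 0.5            # stationary fraction in tilted state
    switching_rate_per_ns: float = 0.05
    coupling_slope: float = -6.3      # mV per degree
    coupling_intercept: float = 580.0  # mV
    coupling_noise_sd: float | None = None  # mV; None -> calibrate
    target_r2: float = 0.6
    seed: int = 20221003

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy must be in [0, 1]")
        if any(s <= 0 for s in self.state_sds):
            raise ValueError("state sds must be > 0")


@dataclass
class TwoStateTruth:
    """Latent ground truth emitted alongside the generated trajectory."""

    spec: TwoStateSpec
    states: np.ndarray             # per-frame 0 (parallel) / 1 (tilted)
    tau: np.ndarray                # per-frame τ actually used (deg)
    occupancy_realized: float
    window_times: np.ndarray       # ns (midpoints)
    window_tau_mean: np.ndarray
    window_majority_state: np.ndarray
    noise_sd_mv: float
    tmp_mv: np.ndarray
    anchor_depth_A: float = field(default=13.1)
    membrane_center_z: float = 0.0


_HELIX_RISE_A = 1.5   # Å per residue along the helix axis
_N_RESIDUES = 21


def _helix_coords(tau_deg: float, anchor: np.ndarray) -> np.ndarray:
    """Rigid 21-bead helix: bead i sits (i−2)·rise along the axis from the
    residue-3 bead, axis in the xz-plane at angle τ from +z."""
    t = np.radians(tau_deg)
    d = np.array([np.sin(t), 0.0, np.cos(t)])
    offsets = (np.arange(_N_RESIDUES) - 2)[:, None] * _HELIX_RISE_A * d
    return anchor + offsets


def gen_two_state_helix(spec: TwoStateSpec, n_frames: int = 1500,
                        dt_ns: float = 0.25, window_ns: float = 5.0
                        ) -> tuple[Trajectory, TMPSeries, TwoStateTruth]:
    """Rigid-helix trajectory with prescribed two-state tilt dynamics.

    The residue-3 bead depth is state-independent (anchored 13.1 Å above
    the membrane center) while the residue-20 bead deepens as τ grows —
    the C-terminus inserts.  Four terminal-methyl marker atoms at the
    membrane center allow membrane-referenced density profiles.
    """
    rng = np.random.default_rng(spec.seed)
    r, w = spec.switching_rate_per_ns, spec.occupancy
    p01 = min(2.0 * r * dt_ns * w, 1.0)          # parallel -> tilted
    p10 = min(2.0 * r * dt_ns * (1.0 - w), 1.0)  # tilted -> parallel
    states = np.empty(n_frames, dtype=int)
    states[0] = 1 if rng.random() < w else 0
    u = rng.random(n_frames)
    for i in range(1, n_frames):
        if states[i - 1] == 0:
            states[i] = 1 if u[i] < p01 else 0
        else:
            states[i] = 0 if u[i] < p10 else 1
    tau = np.where(states == 0, spec.tau_states[0], spec.tau_states[1]) \
        + np.where(states == 0,
                   rng.normal(0, spec.state_sds[0], n_frames),
                   rng.normal(0, spec.state_sds[1], n_frames))
    tau = np.clip(tau, 0.0, 180.0)

    box = np.array([40.0, 40.0, 80.0])
    zc = box[2] / 2.0
    anchor = np.array([box[0] / 2, box[1] / 2, zc + 13.1])

    atoms: list[Atom] = []
    for resid in range(1, _N_RESIDUES + 1):
        atoms.append(Atom(name="CA", residue_index=resid, residue_name="ALA",
                          charge=0.0, mass=71.0))
    marker_xy = [(5.0, 5.0), (35.0, 5.0), (5.0, 35.0), (35.0, 35.0)]
    for k in range(4):
        atoms.append(Atom(name="CM", residue_index=_N_RESIDUES + 1 + k,
                          residue_name="LIP", charge=0.0, mass=15.0))
    top = standard_groups(Topology(atoms, charges_assigned=True))

    frames = []
    marker_dz = [-1.0, -1.0, 1.0, 1.0]   # straddle the center plane
    for i in range(n_frames):
        helix = _helix_coords(tau[i], anchor)
        markers = np.array([[x, y, zc + dz]
                            for (x, y), dz in zip(marker_xy, marker_dz)])
        frames.append(Frame(time=i * dt_ns,
                            coordinates=np.vstack([helix, markers]),
                            box=box.copy()))
    traj = Trajectory(topology=top, frames=frames)

    # surrogate TMP on the analysis windows
    frames_per_window = int(round(window_ns / dt_ns))
    n_windows = n_frames // frames_per_window
    tau_w = np.array([tau[k * frames_per_window:(k + 1) * frames_per_window].mean()
                      for k in range(n_windows)])
    maj = np.array([int(states[k * frames_per_window:(k + 1) * frames_per_window]
                        .mean() > 0.5) for k in range(n_windows)])
    if spec.coupling_noise_sd is not None:
        noise_sd = float(spec.coupling_noise_sd)
    else:
        signal_sd = float(np.std(spec.coupling_slope * tau_w))
        noise_sd = signal_sd * np.sqrt(1.0 / spec.target_r2 - 1.0) \
            if signal_sd > 0 else 0.0
    tmp = (spec.coupling_intercept + spec.coupling_slope * tau_w
           + rng.normal(0.0, noise_sd, n_windows))
    mids = (np.arange(n_windows) + 0.5) * window_ns
    tmp_series = TMPSeries(window_times=mids, tmp=tmp, mean=float(tmp.mean()),
                           sd=float(np.std(tmp, ddof=1)) if n_windows > 1 else 0.0)
    truth = TwoStateTruth(
        spec=spec, states=states, tau=tau,
        occupancy_realized=float(states.mean()),
        window_times=mids, window_tau_mean=tau_w,
        window_majority_state=maj, noise_sd_mv=noise_sd, tmp_mv=tmp,
        membrane_center_z=zc)
    return traj, tmp_series, truth


# ---------------------------------------------------------------------------
# Boltzmann sampler

def gen_boltzmann_samples(potential: Callable[[np.ndarray], np.ndarray],
                          temperature: float, n: int, seed: int,
                          support: tuple[float, float] = (-10.0, 10.0),
                          n_grid: int = 4096) -> np.ndarray:
    """Draw z samples distributed ∝ exp(−G(z)/k_B T) by inverse-CDF on a
    fine grid over ``support``."""
    zlo, zhi = support
    grid = np.linspace(zlo, zhi, n_grid)
    g = np.asarray(potential(grid), dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("G must be finite on the support")
    p = np.exp(-(g - g.min()) / kbt_kcal_mol(temperature))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1])
                                           * np.diff(grid))])
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return np.interp(u, cdf, grid)
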