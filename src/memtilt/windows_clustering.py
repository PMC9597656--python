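"""Windowed TMP–tilt coupling: window averages, k-means clustering of the
windowed potential, and linear regression of TMP on τ.

The trajectory is split into consecutive non-overlapping windows (default
5 ns); per-window means of the transmembrane potential and the tilt angle
are the units of the coupling analysis.  Clustering runs on the scalar
per-window TMP by default (joint (TMP, τ) clustering behind a flag), with
clusters relabelled in order of decreasing TMP so labels are stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .density_profile import DensityProfile, density
from .io_model import Trajectory
from .potential_profile import TMPSeries
from .tilt_analysis import TiltSeries

__all__ = ["WindowSummary", "ClusterResult", "RegressionResult",
           "make_windows", "cluster_windows", "regress_tilt_tmp",
           "per_cluster_profiles"]


@dataclass
class WindowSummary:
    window_index: int
    t_start: float  # ns
    t_end: float    # ns
    mean_tau: float  # degrees
    sd_tau: float
    mean_tmp: float  # mV
    sd_tmp: float
    n_tau: int = 0
    n_tmp: int = 0
    cluster: int | None = None


@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray
    cluster_tmp: list[tuple[float, float]]  # per-cluster (mean, sd) mV
    cluster_tau: list[tuple[float, float]]  # per-cluster (mean, sd) deg
    seed: int
    inertia: float


@dataclass
class RegressionResult:
    slope: float      # mV per degree
    intercept: float  # mV
    r_squared: float
    n: int


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def make_windows(tmp_series: TMPSeries, tilt_series: TiltSeries,
                 window: float = 5.0) -> list[WindowSummary]:
    """Per-window mean/sd of TMP and τ over a common time grid.

    Windows start at the beginning of the overlapping span; a trailing
    partial window is dropped.  The TMP series may be per-frame or already
    windowed — samples are pooled by window either way.
    """
    t_tmp, t_tau = tmp_series.window_times, tilt_series.times
    lo = max(t_tmp.min(), t_tau.min())
    hi = min(t_tmp.max(), t_tau.max())
    if hi <= lo:
        raise ValueError("TMP and tilt series do not overlap in time")
    dt_tau = float(np.median(np.diff(t_tau))) if t_tau.size > 1 else window
    start = float(t_tau.min())
    span = t_tau.max() - start + dt_tau
    n_windows = int(np.floor((span + 1e-9) / window))
    out: list[WindowSummary] = []
    for w in range(n_windows):
        wlo, whi = start + w * window, start + (w + 1) * window
        m_tau = (t_tau >= wlo - 1e-9) & (t_tau < whi - 1e-9)
        m_tmp = (t_tmp >= wlo - 1e-9) & (t_tmp < whi - 1e-9)
        if not m_tau.any() or not m_tmp.any():
            continue
        tau_w = tilt_series.tau[m_tau]
        tmp_w = tmp_series.tmp[m_tmp]
        out.append(WindowSummary(
            window_index=w, t_start=wlo, t_end=whi,
            mean_tau=float(tau_w.mean()), sd_tau=_sd(tau_w),
            mean_tmp=float(tmp_w.mean()), sd_tmp=_sd(tmp_w),
            n_tau=int(m_tau.sum()), n_tmp=int(m_tmp.sum())))
    return out


def cluster_windows(windows: list[WindowSummary], k: int, seed: int,
                    features: str = "tmp") -> ClusterResult:
    """k-means (Lloyd, k-means++ init, seeded) on the windowed TMP values.

    ``features="joint"`` clusters standardized (TMP, τ) pairs instead.
    Clusters are relabelled by decreasing mean TMP.
    """
    n = len(windows)
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}]")
    tmp = np.array([w.mean_tmp for w in windows])
    tau = np.array([w.mean_tau for w in windows])
    if features == "tmp":
        X = tmp[:, None]
    elif features == "joint":
        X = np.column_stack([
            (tmp - tmp.mean()) / (tmp.std() or 1.0),
            (tau - tau.mean()) / (tau.std() or 1.0)])
    else:
        raise ValueError("features must be 'tmp' or 'joint'")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                random_state=seed).fit(X)
    raw = km.labels_
    # stable relabelling: cluster 0 has the highest (least negative) TMP
    order = np.argsort([-tmp[raw == c].mean() for c in range(k)])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw]
    c_tmp, c_tau = [], []
    for c in range(k):
        sel = labels == c
        c_tmp.append((float(tmp[sel].mean()), _sd(tmp[sel])))
        c_tau.append((float(tau[sel].mean()), _sd(tau[sel])))
    for w, lab in zip(windows, labels):
        w.cluster = int(lab)
    return ClusterResult(k=k, labels=labels, cluster_tmp=c_tmp,
                         cluster_tau=c_tau, seed=seed,
                         inertia=float(km.inertia_))


def regress_tilt_tmp(windows: list[WindowSummary]) -> RegressionResult:
    """Ordinary least squares of windowed TMP on windowed τ.

    The r² quantifies how much of the TMP variance tracks the tilt angle;
    slope is in mV per degree (TMP on the y axis).
    """
    if len(windows) < 3:
        raise ValueError("need at least 3 windows")
    tau = np.array([w.mean_tau for w in windows])
    tmp = np.array([w.mean_tmp for w in windows])
    if np.std(tau) == 0:
        raise ValueError("zero variance in mean tilt angle")
    res = stats.linregress(tau, tmp)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2), n=len(windows))


def per_cluster_profiles(trajectory: Trajectory, windows: list[WindowSummary],
                         result: ClusterResult, selection: np.ndarray,
                         n_slices: int, reference: str = "box",
                         bilayer: np.ndarray | None = None
                         ) -> list[DensityProfile]:
    """Density profile of a selection for each cluster's pooled frames."""
    times = trajectory.times
    profiles: list[DensityProfile] = []
    for c in range(result.k):
        sel_frames = []
        for w, lab in zip(windows, result.labels):
            if lab != c:
                continue
            m = (times >= w.t_start - 1e-9) & (times < w.t_end - 1e-9)
            sel_frames.extend(np.nonzero(m)[0])
        if not sel_frames:
            warnings.warn(f"cluster {c} has no frames; empty profile",
                          stacklevel=2)
            box = trajectory.frames[0].box
            edges = np.linspace(-box[2] / 2, box[2] / 2, n_slices + 1)
            zc = 0.5 * (edges[:-1] + edges[1:])
            profiles.append(DensityProfile(
                z_centers=zc, rho=np.zeros(n_slices),
                rho_norm=np.zeros(n_slices),
                selection_label=f"cluster {c} (empty)"))
            continue
        sub = Trajectory(topology=trajectory.topology,
                         frames=[trajectory.frames[i] for i in sorted(sel_frames)])
        prof = density(sub, selection, n_slices, reference=reference,
                       bilayer=bilayer, label=f"cluster {c}")
        profiles.append(prof)
    return profiles
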