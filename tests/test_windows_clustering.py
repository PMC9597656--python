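"""Window averaging, k-means clustering of windowed TMP, and the
TMP–tilt regression."""

import numpy as np
import pytest

from memtilt.potential_profile import TMPSeries
from memtilt.synthetic_data import TwoStateSpec, gen_two_state_helix
from memtilt.tilt_analysis import TiltSeries, tilt_series
from memtilt.windows_clustering import (cluster_windows, make_windows,
                                        per_cluster_profiles,
                                        regress_tilt_tmp)


def _series(n_frames=750, dt=0.5, tau=None, tmp=None):
    times = np.arange(n_frames) * dt
    tau = tau if tau is not None else np.full(n_frames, 100.0)
    tilt = TiltSeries(times=times, tau=tau)
    tmp_vals = tmp if tmp is not None else np.full(n_frames, -50.0)
    tmp_series = TMPSeries(window_times=times, tmp=tmp_vals,
                           mean=float(np.mean(tmp_vals)),
                           sd=float(np.std(tmp_vals)))
    return tmp_series, tilt


def test_375ns_at_5ns_gives_75_windows():
    tmp_series, tilt = _series(n_frames=750, dt=0.5)  # covers 375 ns
    windows = make_windows(tmp_series, tilt, window=5.0)
    assert len(windows) == 75


def test_constant_signals_give_constant_windows():
    tmp_series, tilt = _series()
    for w in make_windows(tmp_series, tilt, window=5.0):
        assert w.mean_tau == pytest.approx(100.0)
        assert w.sd_tau == 0.0
        assert w.mean_tmp == pytest.approx(-50.0)
        assert w.sd_tmp == 0.0


def test_piecewise_constant_switch_at_window_boundary():
    tau = np.concatenate([np.full(250, 90.0), np.full(500, 110.0)])
    tmp_series, tilt = _series(tau=tau)
    windows = make_windows(tmp_series, tilt, window=5.0)
    # switch at t = 125 ns = window 25 boundary
    means = np.array([w.mean_tau for w in windows])
    np.testing.assert_allclose(means[:25], 90.0)
    np.testing.assert_allclose(means[25:], 110.0)


def test_trailing_partial_window_dropped():
    tmp_series, tilt = _series(n_frames=754, dt=0.5)  # 377 ns
    assert len(make_windows(tmp_series, tilt, window=5.0)) == 75


def test_disjoint_time_spans_error():
    tmp_series, tilt = _series()
    late = TMPSeries(window_times=tmp_series.window_times + 1e6,
                     tmp=tmp_series.tmp, mean=tmp_series.mean,
                     sd=tmp_series.sd)
    with pytest.raises(ValueError, match="overlap"):
        make_windows(late, tilt, window=5.0)


def test_window_means_reconstruct_global_mean():
    rng = np.random.default_rng(0)
    tau = rng.normal(100, 5, 750)
    tmp_series, tilt = _series(tau=tau)
    windows = make_windows(tmp_series, tilt, window=5.0)
    weights = np.array([w.n_tau for w in windows], dtype=float)
    means = np.array([w.mean_tau for w in windows])
    assert np.average(means, weights=weights) == \
        pytest.approx(tau.mean(), abs=1e-12)


def test_separable_tmp_groups_recovered_exactly():
    tau = np.full(750, 100.0)
    # block boundary at frame 370 = 185 ns = exactly 37 windows
    tmp = np.where(np.arange(750) < 370, -20.0, -150.0) \
        + np.random.default_rng(1).normal(0, 2.0, 750)
    tmp_series, tilt = _series(tau=tau, tmp=tmp)
    windows = make_windows(tmp_series, tilt, window=5.0)
    result = cluster_windows(windows, k=2, seed=0)
    # label 0 = least negative TMP cluster = first 37/38 windows
    expected = (np.arange(75) >= 37).astype(int)
    assert np.array_equal(result.labels, expected)
    assert result.cluster_tmp[0][0] > result.cluster_tmp[1][0]


def test_k_equals_one_recovers_global_mean():
    tmp_series, tilt = _series()
    windows = make_windows(tmp_series, tilt, window=5.0)
    result = cluster_windows(windows, k=1, seed=0)
    assert result.cluster_tmp[0][0] == pytest.approx(-50.0)


def test_k_equals_n_windows_zero_inertia():
    rng = np.random.default_rng(2)
    tmp = rng.normal(-50, 30, 750)
    tmp_series, tilt = _series(tmp=tmp)
    windows = make_windows(tmp_series, tilt, window=5.0)
    result = cluster_windows(windows, k=len(windows), seed=0)
    assert result.inertia == pytest.approx(0.0, abs=1e-9)


def test_inertia_non_increasing_in_k():
    rng = np.random.default_rng(3)
    tmp = rng.normal(-50, 30, 750)
    tmp_series, tilt = _series(tmp=tmp)
    windows = make_windows(tmp_series, tilt, window=5.0)
    inertias = [cluster_windows(windows, k=k, seed=0).inertia
                for k in (1, 2, 3, 4)]
    assert all(a >= b - 1e-9 for a, b in zip(inertias, inertias[1:]))


def test_k_out_of_range_errors():
    tmp_series, tilt = _series()
    windows = make_windows(tmp_series, tilt, window=5.0)
    with pytest.raises(ValueError):
        cluster_windows(windows, k=len(windows) + 1, seed=0)


def test_noiseless_line_regresses_exactly():
    rng = np.random.default_rng(4)
    tau = rng.normal(100, 8, 750)
    tmp = 580.0 - 6.3 * tau
    tmp_series, tilt = _series(tau=tau, tmp=tmp)
    windows = make_windows(tmp_series, tilt, window=5.0)
    reg = regress_tilt_tmp(windows)
    assert reg.r_squared == pytest.approx(1.0, abs=1e-12)
    assert reg.slope == pytest.approx(-6.3, abs=1e-9)
    assert reg.intercept == pytest.approx(580.0, abs=1e-6)


def test_shuffled_pairs_have_near_zero_r2():
    rng = np.random.default_rng(5)
    r2s = []
    for _ in range(10):
        tau = rng.normal(100, 8, 750)
        tmp = 580.0 - 6.3 * rng.permutation(tau) + rng.normal(0, 5, 750)
        tmp_series, tilt = _series(tau=tau, tmp=tmp)
        windows = make_windows(tmp_series, tilt, window=5.0)
        r2s.append(regress_tilt_tmp(windows).r_squared)
    assert np.mean(r2s) < 0.05


def test_r2_invariant_under_affine_rescaling():
    rng = np.random.default_rng(6)
    tau = rng.normal(100, 8, 750)
    tmp = 580.0 - 6.3 * tau + rng.normal(0, 20, 750)
    tmp_series, tilt = _series(tau=tau, tmp=tmp)
    r2_a = regress_tilt_tmp(make_windows(tmp_series, tilt, 5.0)).r_squared
    tmp_series2, tilt2 = _series(tau=0.5 * tau + 20.0, tmp=0.1 * tmp + 7.0)
    r2_b = regress_tilt_tmp(make_windows(tmp_series2, tilt2, 5.0)).r_squared
    assert r2_b == pytest.approx(r2_a, abs=1e-9)


def test_zero_tau_variance_errors():
    tmp_series, tilt = _series()
    windows = make_windows(tmp_series, tilt, window=5.0)
    with pytest.raises(ValueError, match="variance"):
        regress_tilt_tmp(windows)


def test_generator_tuned_r2_recovered(two_state):
    spec, traj, tmp_series, truth = two_state
    series = tilt_series(traj, unwrap=False)
    windows = make_windows(tmp_series, series, window=5.0)
    reg = regress_tilt_tmp(windows)
    assert reg.r_squared == pytest.approx(spec.target_r2, abs=0.15)


def test_per_cluster_profiles_pool_frames_by_state(two_state):
    spec, traj, tmp_series, truth = two_state
    series = tilt_series(traj, unwrap=False)
    windows = make_windows(tmp_series, series, window=5.0)
    result = cluster_windows(windows, k=2, seed=1)
    sel = traj.topology.select(residue_index=20)
    profiles = per_cluster_profiles(traj, windows, result, sel, 160,
                                    reference="membrane")
    # cluster 0 = high TMP = parallel state; its residue-20 marker sits
    # higher above the membrane center than the tilted cluster's
    z_mean = []
    for prof in profiles:
        occ = prof.rho > 0
        z_mean.append(np.average(prof.z_centers[occ],
                                 weights=prof.rho[occ]))
    assert z_mean[0] > z_mean[1] + 4.0


def test_per_cluster_profiles_with_k1_match_global(two_state):
    spec, traj, tmp_series, truth = two_state
    series = tilt_series(traj, unwrap=False)
    windows = make_windows(tmp_series, series, window=5.0)
    result = cluster_windows(windows, k=1, seed=1)
    sel = traj.topology.select(residue_index=20)
    profiles = per_cluster_profiles(traj, windows, result, sel, 80,
                                    reference="membrane")
    from memtilt.density_profile import density
    from memtilt.io_model import Trajectory
    keep = [i for w in windows
            for i in np.nonzero((traj.times >= w.t_start - 1e-9)
                                & (traj.times < w.t_end - 1e-9))[0]]
    sub = Trajectory(topology=traj.topology,
                     frames=[traj.frames[i] for i in sorted(keep)])
    global_prof = density(sub, sel, 80, reference="membrane")
    np.testing.assert_allclose(profiles[0].rho, global_prof.rho, atol=1e-12)
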