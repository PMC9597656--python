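"""Tilt-angle statistics of a two-state helix trajectory.

The synthetic rigid helix hops between a surface-parallel state
(τ ≈ 90°) and a tilted, C-terminus-inserted state (τ ≈ 110°).  The tilt
angle is the angle between the residue-3→residue-20 center-of-mass
vector and +z; the histogram uses 1° bins and reports the fraction of
frames beyond a 120° threshold."""

from memtilt.synthetic_data import TwoStateSpec, gen_two_state_helix
from memtilt.tilt_analysis import tilt_histogram, tilt_series

spec = TwoStateSpec(occupancy=0.5, seed=20221003)
traj, _, truth = gen_two_state_helix(spec, n_frames=1500)

series = tilt_series(traj, res_a=3, res_b=20, unwrap=False)
hist = tilt_histogram(series, bin_width=1.0, thresholds=[100.0, 120.0])

print(f"frames analysed      : {len(series.tau)}")
print(f"mean tilt            : {series.tau.mean():.1f} deg")
print(f"fraction tau > 100°  : {hist.fraction_above[100.0]:.3f} "
      f"(generator occupancy {truth.occupancy_realized:.3f})")
print(f"fraction tau > 120°  : {hist.fraction_above[120.0]:.3f}")
# tau > 100° separates the two states; the exceedance fraction matches
# the generator's realized tilted-state occupancy.
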