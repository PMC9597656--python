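# Methods

## Electrostatic potential and TMP

The potential profile is obtained by summing the partial charges of
*all* atoms (lipids, water, ions, peptide) into *n* uniform slices along
z and integrating the one-dimensional Poisson equation twice,

    d²φ/dz² = −ρ(z)/ε₀ ,

with φ = 0 and dφ/dz = 0 at the lower box edge.  No relative
permittivity enters: every charge, including water's, is explicit, so
ε = ε₀ exactly.  For a slice-binned (piecewise-constant) ρ the field is
piecewise linear and φ piecewise quadratic; the integrator evaluates
that closed form, so the only discretisation error is the binning
itself.  On the capacitor fixture the plateau difference matches
σ·d/ε₀ to machine precision.

If the net charge density is nonzero the mean density is subtracted
before integration (otherwise φ acquires a spurious quadratic ramp and
is not periodic); a warning carrying the subtracted value is attached
to the profile.

The TMP is the difference of plateau-averaged potentials,
central − external, where each declared compartment range is averaged
over its central 50 % (`plateau_fraction`) — robust against the
electrical-double-layer structure at compartment edges.  A more
negative central (intracellular-mimic) compartment gives a negative
TMP.  Compartment ranges may wrap through the periodic boundary.

Defaults: 1050 slices for single-bilayer boxes and 2100 for
double-bilayer boxes (slice width then tracks box height); 5 ns
windows for time series.  Windowed TMP averages the charge density per
window and integrates once (the double integral amplifies per-frame
noise); a `per_frame` flag integrates every frame instead for
fluctuation studies.  Whether the TMP is read off as a plateau average
or a point difference is a genuine convention choice; plateau averaging
was chosen for robustness, and the two agree on every fixture with flat
plateaus.

Unit chain: ρ in e/Å³ integrated twice over Å gives e/Å; the single
conversion constant e/(ε₀·Å) = 1.8095 × 10⁵ mV lives in
`memtilt.units` and derives from `scipy.constants` (CODATA).

## Density profiles and the membrane center

The membrane center is the mean wrapped z of the lipid terminal-methyl
marker atoms; leaflets are assigned by the sign of z − center.
Profiles are recentered **per frame** (not on the trajectory-average
center) so membrane drift does not inflate distribution widths.
System-wide profiles of double-bilayer boxes are box-referenced
instead, since no single membrane center applies.  Profiles are
normalized to a maximum of 1; the unnormalized density integrates to
the mean selection size (conservation, asserted in tests).  Residue
profiles use all atoms by default (heavy-atom-only selection is the
caller's choice via the selection mechanism).

## Gaussian decomposition (S/T two-state analysis)

Residue z distributions are decomposed by maximum-likelihood EM on the
raw samples (scikit-learn `GaussianMixture`, 10 seeded restarts,
default seed 20221003) rather than least squares on a histogram, which
would be bin-width sensitive.  Component populations are mixture
weights (areas), not amplitudes.  Model order k ∈ {1, 2} is selected by
BIC with a conservative ΔBIC > 6 required to accept bimodality.  Peak
shifts between two fits are |center_b| − |center_a| per order-matched
component, so "negative = toward the membrane center at 0" holds on
either side of the membrane.

## Tilt angle

τ is the angle between the vector joining the mass-weighted centers of
mass of residues 3 and 20 (defaults; the flexible termini are excluded
by construction of these anchors) and +ẑ.  All atoms including
hydrogens enter the COM.  Residues are made whole by minimum-image
unwrapping before the COM.  τ is reported raw in [0, 180]° — no folding
about 90° and no per-leaflet sign convention, since values above 90°
(C-terminus inserted) are physically meaningful.  Histograms use 1°
bins; exceedance fractions (default threshold 120°) quantify the
strongly tilted population.

## Windowed coupling analysis

TMP and τ series are averaged over consecutive non-overlapping windows
(default 5 ns; a trailing partial window is dropped, matching an exact
375 = 75 × 5 decomposition).  Clustering runs k-means (Lloyd,
k-means++ init, 10 seeded restarts) on the scalar windowed TMP by
default — joint standardized (TMP, τ) clustering sits behind a flag —
and relabels clusters by decreasing TMP so labels are stable.  k is a
user parameter (default 4, the number of distinct TMP levels the
coupling analysis distinguishes); outputs state "k chosen by user".
The regression is ordinary least squares of TMP on τ (r² is identical
for the transposed orientation; the slope is reported in mV/°).

## Free energy by Boltzmann inversion

G_i = −k_B·T·ln(N_i/N_Max) on 0.05 Å bins at 310 K (both parameters
adjustable).  k_B = R/4184 kcal/(mol·K) from `scipy.constants`.  Empty
bins are NaN, never +∞, so extrema detection is not poisoned by
sampling gaps.  Extrema are located with `scipy.signal.find_peaks`
after an optional moving-average smoothing (detection only; raw G is
always reported).  A `min_prominence` threshold (kcal/mol) suppresses
spurious wiggles from finite sampling: per-bin noise is
≈ k_B·T/√N_i, so a threshold well above that but well below physical
barriers (0.1 kcal/mol in the tests, against a 1.5 kcal/mol
constructed barrier) keeps only real features.  Barrier heights are
G(max) − G(adjacent min) on each side of every interior maximum.

## System builder

`duplicate_translate` duplicates the atom set, translates the copy by
+Lz and doubles the box — two bilayers, two separated aqueous
compartments.  `add_salt` substitutes randomly chosen (seeded)
compartment waters by ions at the water-oxygen position, deleting the
two hydrogens (3-site water assumed), with a minimum pairwise ion
separation of 3.5 Å enforced against both new and pre-existing ions by
bounded re-draws.  Molarity→count conversion uses
counts = round(c·N_A·V) with V = (compartment water count) × 30 Å³ per
water; when explicit counts and a molarity are both available, counts
are authoritative.  `set_ion_imbalance` moves ions between compartments
by swapping each ion with a randomly chosen water in the destination
compartment (atom count and total charge exactly conserved; each
cation move shifts the external−central charge difference by 2 e, so a
parity-infeasible request errors).  Every operation returns a
`BuildReport` whose arithmetic is verified in tests by re-reading the
written coordinate file.

## Coordinate I/O

Coordinates are Å internally, converted at the GRO (nm) boundary.  GRO
is written with 4 decimals in nm (0.001 Å) using the format's
variable-precision convention; round trips are verified both with the
package's own reader and with MDAnalysis as an independent parser.
Residues are renumbered contiguously from 1 by consecutive runs of the
file's residue field, so 5-digit GRO serial wrap-around cannot merge
distinct residues.  Orthorhombic boxes only; z is the membrane normal
everywhere.  Partial charges arrive via a whitespace-separated sidecar
table (residue name, atom name, charge, mass); analyses that need
charges refuse to run until a charge source is applied, naming the
first uncovered atom.

## Synthetic fixtures: what they emulate and what they do not

* **Capacitor** (`gen_capacitor`): discrete ±σ point-charge sheets; the
  analytic plateau difference σ·d/ε₀ is the integration oracle.  It has
  no dielectric response and no thermal noise — it validates the
  integrator, not force-field realism.
* **Mock bilayer** (`gen_mock_bilayer`): two leaflets of 3-bead rod
  lipids (headgroup bead carrying a ±0.3 e dipole pair or the −1 e of
  an anionic lipid, terminal-methyl marker at the center), an 80:20
  neutral:anionic composition by default, 3-site waters on a jittered
  grid, and neutralizing Na⁺ placed in the double-layer region next to
  the headgroups.  Geometrically and electrostatically valid for
  center-finding, density, potential and builder tests; it has no
  realistic lipid conformations, area-per-lipid or water structure.
* **Two-state helix** (`gen_two_state_helix`): a rigid 21-bead helix
  (1.5 Å rise per residue) whose residue-3 bead is anchored 13.1 Å
  above the membrane center while the axis tilts; a two-state Markov
  chain (states 90°/110°, jitter sd 2°, stationary tilted occupancy
  0.5, switching rate 0.05 ns⁻¹ at equal occupancy) drives τ, and the
  surrogate TMP per window is intercept + slope·⟨τ⟩ + noise.  Slope
  −6.3 mV/° and intercept +580 mV follow the observed cluster trend of
  roughly −6 mV per degree with ≈ −18 mV at τ = 95°.  When no explicit
  noise sd is given it is calibrated analytically for a target expected
  r² (default 0.6): noise_sd = |slope|·sd(⟨τ⟩_w)·√(1/r² − 1).  The TMP
  here is *generated from τ*, not computed from charges — the
  charge→potential path is validated separately by the capacitor, so
  each oracle isolates one computation.  Because the helix is rigid and
  the chain is memoryless, passing tests demonstrate correct recovery
  of the imposed statistical structure, not peptide physics.
* **Boltzmann sampler** (`gen_boltzmann_samples`): seeded inverse-CDF
  sampling of exp(−G/k_BT) on a 4096-point grid.

Every generator returns a machine-readable truth record and is
bit-reproducible under its seed; recovery tests read expected values
only from the truth record.

## Problem sizes and statistical tolerances

Recovery statistics use 20 seeded replicates of 1500-frame (375 ns at
0.25 ns/frame) trajectories, 10⁴-sample mixture fits and 4–10 × 10⁵
sample free-energy inversions — sizes at which the checked tolerances
(weight MAE < 0.02, r² within ±0.1 of target, curvature within 5 %)
are comfortably above the residual estimator noise.  The
label-agreement fixture uses a slower chain (0.02 ns⁻¹) and a small
explicit 5 mV noise so that windows are state-pure and TMP clusters
well separated; at much slower switching a 375 ns realization may
never leave one state, which would make two-cluster label recovery
undefined rather than hard.

## Known limitations

* 1-D analysis only: no 2-D/3-D potential maps, no PME-consistent
  reconstruction, no electronic polarizability.
* Orthorhombic boxes; z as the unique normal.
* No trajectory-format backends beyond multi-frame in-memory
  trajectories built from PDB/GRO single frames or generators (the
  `Trajectory` contract is deliberately minimal; an external reader can
  populate it).
* Boltzmann inversion assumes unbiased sampling — no WHAM/MBAR
  reweighting; error bars by block analysis are not built in.
* The k for TMP clustering and the bimodality threshold ΔBIC > 6 are
  conventions, stated in outputs, not inferred from data.
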