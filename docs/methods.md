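# Methods

This note records the models implemented in `sapfilm`, the defaults they
carry, the design choices that were genuinely open, and what the synthetic
data can and cannot establish.

## Conventions

Lengths are in nm, surface tensions in mN/m, pressures in MPa, times in ps,
energies in k_BT at an explicit temperature (default 298 K).  Tension is a
*negative* external pressure throughout (−0.5 … −5.5 MPa); no absolute-value
inputs.  With h in nm and P in MPa, h·P is already a tension in mN/m, which
keeps the estimator formulas free of unit constants.  Lateral coordinates are
wrapped into the periodic square box [0, h_xy) before any grid analysis.

## Pore area by grid occupancy

Head-group marker atoms (galactosyl oxygens for the glycolipid; phosphorus
and nitrogen for the phospholipid) are snapped onto an M × M grid with
M = round(√N), by dividing coordinates by the grid spacing and rounding to
the nearest integer; the pore fraction is the share of grid points left
unoccupied.  No atom–grid distances are ever computed, which is the point of
the method: it scales as O(N) per frame.

Numerical choices:

* **Rounding.** Round-to-nearest with ties to even is the default; a
  truncation mode exists behind a flag because the two readings of
  "convert to an integer" disagree for fractional parts ≥ 0.5 and the
  difference is occasionally wanted for fidelity experiments.
* **Clipping.** Indices are clipped to [0, M−1]; atoms in the final
  half-cell next to the far wall map to the last node.  The algorithm agrees
  *exactly* with a brute-force nearest-node assignment whenever the offset is
  zero (this is a test, not an assumption).
* **Offset.** The grid is inset from the walls by offset_fraction (default
  0.01, i.e. 1 % of the box width); results must be insensitive to this and
  the insensitivity is part of the test suite.
* **Grid policy.** Under expansion the grid is rebuilt per frame by default
  (constant M, rescaled spacing), so the fraction measures coverage relative
  to the instantaneous area; a fixed-first-frame policy is available, under
  which affine expansion itself registers as exposure.  The policy used is
  recorded in output metadata.
* **Rupture detection.** First time the pore fraction holds at or above the
  threshold (default 0.10) for min_consecutive frames (default 3, debouncing
  single-frame spikes).

## Dynamic surface tension

**Pressure tensor.**  γ_PT = (h_z/n)[P_z − ½(P_x + P_y)] per time step, with
n the number of interfaces (2 for the double-sided slab); the cumulative
running mean is the headline estimate.  The prefactor is h_z/n — the only
reading that yields tension units from a pressure × length — and γ_PT is
linear in the components, which the tests exploit.

**Capillary wave.**  γ_CW = k_BT/(2πσ²)·ln(h_z/l).  σ is the erf-fit width
of the slab density profile (the standard deviation of the implied Gaussian,
not its square).  The two interfaces are fitted jointly with a shared σ by
default; an independent-σ mode supports the top/bottom comparison rule.  Fit
initialization: interface positions from half-maximum crossings, σ from the
25–75 % rise distance divided by 1.349.  l is the mean of the water van der
Waals diameter (0.28 nm) and the head-group disc diameter
2·√(h_xy²/(π·n_lipids)), so l tracks the instantaneous box width; within a
chunk the chunk-mean h_xy is used (the collapse rule is otherwise arbitrary,
and chunk-mean is the least surprising).  γ_CW is evaluated in 500 ps chunks
over 300 density slices by default.

**Convergence rule.**  The cumulative γ_PT is compared with the chunked γ_CW;
the report gives the first chunk at which they agree within a stated
tolerance (default 2 mN/m) and checks that the two monolayers' independent CW
estimates never differ by more than one within-chunk standard deviation —
the acceptance rule for treating γ_PT as the mean film behavior.

## Isotherms

Surface pressure Π = γ_water − γ_interface, always formed with the water
tension *measured by the same method*: the simulated-water reference is
40 mN/m (a cutoff-dependent model value), the experimental reference
72 mN/m.  Both are configuration constants, never hard-coded in formulas.

The abscissa is area per lipid A = h_xy²/n_lipids (nm²), which increases
during pulling so that Π falls toward zero as the film ruptures.  The
reciprocal lipid number density is emitted alongside for cross-checks; the
two conventions disagree about monotonicity and only area-per-lipid is
compatible with a decreasing sigmoid at positive b, which is why it is the
fitting variable.

Binning is equal-width in A with per-bin mean, one-standard-deviation bar and
count; samples after the rupture time are excluded first, and ε — the mean
bar size — is computed after that exclusion.  The sigmoid

    Π(A) = Π₀ − (Π_rupture/2)(1 + erf(b(A − c)))

is fitted by bounded nonlinear least squares over (b, c, Π_rupture) with Π₀
*fixed* at γ_water − ε, weights 1/sd when every bar is positive (an
unweighted mode exists since the weighting convention is not dictated by
anything), bounds 0.1 < b < 5, 0.5 < c < 1.2, 2 < Π_rupture < 20.  The
closing-parenthesis placement above is the only reading with the correct
limits (Π → Π₀ for small A, Π → Π₀ − Π_rupture for large A, half-step at
A = c).  A solution pinned at the bounds in more than one parameter is
treated as a failure: it is the signature of data that do not span a sigmoid
transition inside the physical box.

## Nucleation landscape

For a bubble of radius r carrying a fixed number of lipids (default 30,000)
the area per lipid is A(r) = 4πr²/n_lipids and the film tension
γ(r) = γ_water − Π(A(r)).  The formation free energy is

    g(r) = 4πr²·γ(r)/(1 + 2δ/r) + p_eff·(4/3)πr³     (in k_BT),

with Tolman length δ = 0.2 nm by default and p_eff = p_external −
p_internal (internal default 0), so the volume term is negative —
stabilizing — under tension.  The prose convention "internal minus external"
would flip the sign and make growth uphill at negative pressure, which
contradicts the basic mechanics of cavitation; the implemented sign is
therefore external − internal, stated here prominently.

**Which γ_water enters γ(r).**  Two modes exist.  The *corrected* mode
(γ = 72 − Π) is the right scale for Laplace-pressure estimates and is used
for them.  The *model* mode (γ = 40 − Π) is the default for landscapes, for
a structural reason: with Π₀ = γ_water − ε the small-bubble tension in model
mode is exactly ε — a few mN/m, matching the near-zero tension of the
compact, buckled film — whereas in corrected mode it is 32 + ε ≥ 32 mN/m.
A small-r tension of tens of mN/m makes the surface term dominate out to
r = 2γ/|p| (≈130 nm at −0.5 MPa), so no interior minimum can exist inside
the analysis window at mild tension for *any* in-bounds (b, c, Π_rupture);
only the model mode reproduces the two-barrier "kinetic trap" with a
sub-10-nm cavitation barrier.

**Representative film parameters.**  No fitted per-pressure isotherm
parameters are available from real slab data, so the package ships a
representative in-bounds family, found by grid search and clearly labeled
non-experimental (`sapfilm.cnt.REPRESENTATIVE_FAMILY`): b = 4.5, c = 0.6,
with (ε, Π_rupture) = (2, 10), (12, 14), (19, 16.5), (30, 19) at −0.5, −1.5,
−2.5, −3.5 MPa.  Both the noise amplitude ε and the transition step
Π_rupture grow with the pulling rate, consistent with the wilder
fluctuations and the wider transitions of faster-pulled films.  This family
yields four kinetic-trap landscapes with metastable radii 31–37 nm (mean
≈34, against the ≈35 nm headline), embolism-barrier heights that decrease
monotonically with tension, and barriers that are positive at −0.5/−1.5 MPa
but peak below zero at −2.5/−3.5 MPa — the sign pattern that separates
"never embolizes" from "embolism-capable".  At −3.5 MPa the trap exists only
near the upper b and Π_rupture bounds; it is a marginal feature of the
bounds box, and the test suite samples jitters of the family inside the
regime where the trap is structurally present.

**Extrema.**  Landscapes are evaluated on a 0–120 nm grid with 4,801 points;
extrema are located by sign changes of the finite-difference slope and
refined by local parabolic interpolation, and are required (by test) to agree
with a brute-force scan on a 10× finer grid within one coarse step.

**Laplace pressure.**  p = 2γ(r)/r, reported at the metastable radius with
the corrected tension; the worked examples (2.7 and 4.1 MPa inside a 35 nm
bubble at 47 and 72 mN/m) are exact arithmetic checks.

## The synthetic-data generator

The generator is a phenomenological kinetic emulator, **not** an MD
surrogate: only the statistical shape of the estimator inputs is modeled.

* Head groups rattle (Gaussian jitter, default sd 0.08 nm) about
  liquid-condensed lattice anchors; the box expands affinely at
  expansion_rate × |p| (default 2 nm²·ns⁻¹·MPa⁻¹).  A jittered lattice, not
  a random gas, is essential: with M² ≈ N a fully random configuration
  leaves ≈ e⁻¹ ≈ 37 % of grid cells empty, which would swamp the 10 %
  rupture threshold; the lattice gives a ≈4–5 % vacancy floor.
* Pores are disks that nucleate as a Poisson process at rate
  nucleation_rate × |p| (default 0.6 ns⁻¹·MPa⁻¹) and grow at net rate
  growth_rate × |p| − healing_rate (defaults 1.2 nm²·ns⁻¹·MPa⁻¹ and
  1.26 nm²·ns⁻¹).  The constant healing term plays the role of line
  tension resealing small pores; it is what makes −0.5 MPa stable
  indefinitely while −1.5 MPa ruptures in ~10 ns — with purely
  |p|-proportional growth the rupture time would scale as 1/|p| and the
  mild-tension run could not survive a 25 ns window.  Once total coverage
  crosses the threshold, growth becomes exponential (runaway) and the
  trajectory is flagged ruptured.
* The phospholipid mode keeps the box within a fraction of a percent of its
  initial width and holds a fixed set of pores fluctuating about a 23 %
  equilibrium coverage.  The filamentous head-group structure of the real
  film is emulated only through these two observable signatures.  Pore disks
  are inflated by half a grid cell because a snap-to-grid observer
  undercounts a disk by roughly its rim annulus; the inflation makes nominal
  and observed coverage agree.
* Pressure-tensor series are Gaussian around component means whose
  anisotropy encodes the target tension exactly; density profiles are
  double-erf slabs with prescribed width.

All generators take explicit seeds and are bit-reproducible.  None of the
rate constants are measured quantities; they are calibration choices of this
package, set once so that the qualitative pulling phenomenology holds
(stable at −0.5 MPa; rupture times strictly ordered over −1.5/−2.5/−3.5 MPa;
≈10 % rupture coverage; ≈23 % phospholipid coverage; < 2 % phospholipid
lateral growth), and they should never be quoted as results.

**What passing tests do and do not show.**  Green tests establish that the
estimators are unbiased and self-consistent on inputs with the assumed
statistical structure, that the fits recover known parameters at realistic
noise, and that the pipeline is deterministic.  They do not validate the
generator against real MD data — there is no force field, no water, no
curvature, no gas dissolution here — and the landscape conclusions inherit
the representative film parameters rather than fitted experimental ones.

## Pipeline defaults and problem sizes

The default profile encodes the study constants: pressures −0.5 … −3.5 MPa
(phospholipid −5.5 MPa), 276/280 lipids per monolayer, an 18 nm lateral box,
60/45 nm box heights, 25 ns runs at 50 ps/frame, 500 ps chunks, 300 slices,
rupture threshold 0.10, n_lipids = 30,000, δ = 0.2 nm, γ_water 40/72 mN/m,
T = 298 K.  The isotherm stage runs a parameter-recovery experiment (truth
b = 1.5, c = 0.9, Π_rupture = 8/11/14/17 growing with tension, noise
1.5 mN/m, 40 areas × 20 replicates) whose generating plateau is kept
consistent with the data-estimated ε.  Tests and the acceptance script use
shorter tensor series and coarser landscape grids where full length adds
nothing to the property being checked; the problem size actually used is
reported next to every quantity the acceptance script writes.

## Known limitations

* Pore geometry is 2-D disks with union-by-sum area; merging is not resolved
  geometrically (overlaps are rare below the rupture threshold).
* The grid observer is non-periodic at the far wall (indices clip); exact
  translation invariance holds only away from the final half-cell.
* The corrected-mode landscape cannot produce a kinetic trap at mild
  tension (see above); users who want corrected-γ landscapes should read the
  monotonic flag in the stability report rather than assume extrema exist.
* ε in the representative family reaches 30 mN/m at −3.5 MPa, far larger
  than a typical measured bar; it is the price of a kinetic trap at that
  tension inside the printed fit bounds and is flagged as a representative,
  not measured, value.
* The Tolman correction divides the whole surface term; first-order
  expansions of the same correction are out of scope.
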