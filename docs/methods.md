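# Methods

This note documents the physical model, the numerical choices and the
limitations of `spiralsort`. Everything stated here is computed by the
package itself (the test suite and `scripts/acceptance.py` exercise each
claim); no empirical result is asserted beyond what the code produces.

## Scope and model class

The package is a reduced-order design tool, not a CFD solver. The full 3-D
Navier–Stokes problem in the spiral is replaced by:

1. dimensionless similarity numbers (Re, De, CR, AR) on the duct geometry;
2. algebraic force magnitudes (inertial lift, Dean drag);
3. a 1-D lateral force balance for the equilibrium streamline;
4. linear (Hagen–Poiseuille) hydraulics for pressures and outlet splits;
5. a Monte-Carlo assignment model for sorting statistics.

This keeps every computation desk-scale (milliseconds) and exactly
reproducible, at the cost of the fidelity discussed under Limitations.

## Geometry

Lengths are SI meters internally; configs use explicit `_um`/`_mm` suffixes.
The double spiral is a list of loop curvature radii, innermost first. Arc
length is approximated per loop by `2πRᵢ`; the S-bend between the two
sub-spirals adds no length. A drawing's total length may override the sum
(the presets use 334 mm). At millimeter radii the circular-arc approximation
differs from true Archimedean arcs by well under 1%, which is far below the
effect of the unpublished per-loop radii (next paragraph).

**Reconstructed preset radii.** The loop-by-loop radii of the reference
device are not published; only the Dean-number extremes at the design flow
are (De = 30.39 innermost, 6.94 outermost at 860 μl/min). The presets
back-solve those two anchors for the end radii (≈0.40 mm and ≈7.62 mm),
interpolate the 12 loops linearly, and carry a `reconstructed=True` flag.
This honors the printed De range exactly; the nominal 450 μm inter-loop
spacing quoted for the drawing is inconsistent with those anchors for 12
loops and is treated as descriptive only. User-built geometries can instead
use the constant-spacing generator or an explicit radii list.

## Hydraulics

Duct resistance uses the exact Fourier-series solution for laminar flow in a
rectangle, truncated at `n_terms` odd modes (default 50; modes decay as
`n⁻⁵`, so 10 vs 100 terms differ by <0.1% over `h/w ∈ [0.1, 1]`). The
shallow-duct closed form `12μL/(wh³(1−0.63h/w))` agrees within 1% for
`h/w ≤ 0.3` and is provided for cross-checks. The spiral's own resistance
uses the straight-duct formula: curvature corrections to resistance are
second order at De ≤ 31, and the series value already reproduces the ≈4 bar
pressure loss expected at the design flow (computed: 3.80 bar).

PDMS compliance is handled empirically: a `DeformationCurve` tabulates
measured `Q_exp/Q_th` versus pressure (linear interpolation, constant
extrapolation, ratios ≥ 1 enforced), and pressure-driven conditions multiply
the rigid-device flow by that ratio. The 5% band (`ratio ≤ 1.05`) flags a
device as rigid enough. No constitutive elastomer model is attempted.

**Outlet balance.** Outlets sharing a junction equalize pressure drops,
which under Hagen–Poiseuille reduces to `QᵢSᵢ = const`, i.e. `Qᵢ ∝ 1/Sᵢ`.
The split is solved analytically and conserves mass exactly (the last outlet
absorbs the float residual, keeping ΣQᵢ = Q_total to machine precision).
`required_outlet_resistances` additionally solves for the outlet lengths
that realize equal pressure drops at the balanced flows; the common target
drop defaults to the largest baseline drop so corrections only ever lengthen
a channel (always feasible). An explicit lower target raises a
design-infeasible error rather than returning a negative length.

Two working points are quoted for the original device at 2800 mbar —
860 μl/min in the design/validation context and 880 μl/min in the bead-yield
context. Both are honored where each is used (the preset design flow is 860;
the 582 mm/s worked example uses 880 over the measured 300×84 μm section);
the discrepancy is surfaced here rather than resolved.

## Forces and calibration

* `Re = ρU_mD_h/μ`, `De = Re·√(D_h/2R)`, `CR = a/H` (focusing requires
  `CR ≥ 0.07`, i.e. `a ≥ 5.95 μm` at `H = 85 μm`).
* Lift: `F_L = C_L ρ U_m² a⁴ / H²`. The `H²` denominator (rather than
  `D_h²`) matches the geometric structure of the dimensionless coefficient;
  the choice is absorbed by the calibration constant and does not affect the
  size scaling.
* Dean drag: `F_D = 3πμU_D a`, with the empirical secondary-flow correlation
  `U_D = 1.8×10⁻⁴·De^1.63` m/s (prefactor and exponent overridable).
* Sortability index: `R_F = k·F_L/F_D`. Because De varies loop to loop, the
  single-number index is evaluated at the **radial midpoint** of the spiral
  — an auditable convention, with the absolute normalization delegated to
  the calibration constant `k`, solved once so that the 9 μm cut-off
  particle has `R_F = 1.12` at the design flow. `k` is stored on the device,
  echoed in reports, and never defaulted silently (requesting a calibrated
  ratio without `k` raises). Under the geometric `C_L ∝ 1/(a·Re)`,
  `F_L ∝ a³` and `F_D ∝ a`, so `R_F(a₁)/R_F(a₂) = (a₁/a₂)²` independent of
  `k`, flow and radius; the calibrated model then yields 0.50 at 6 μm and
  5.53 at 20 μm. The sortable band check `[0.5, 5.5]` admits a half printed
  ULP (0.05) at each edge, since the band edges are one-decimal quantities.

## Equilibrium streamline closure

The cross-width balance on `x ∈ (0, W)` (distance of the particle **center**
from the inner wall) uses two pluggable profiles:

* lift as a restoring field toward the duct's lateral equilibrium offset
  `x_eq` (default `0.2·W` from the inner wall): shape `(x_eq − x)/W`,
  magnitude `k·F_L`;
* Dean drag as an outward entrainment with the two-vortex shape
  `sin(πx/W)` (zero at both walls, peak mid-width), magnitude `F_D`.

The focused position is the root of the net force nearest the inner wall,
bracketed by a 512-point uniform scan over `(a/2, W − a/2)` (first sign
change wins, ties toward the inner wall) and refined by Brent's method. The
root satisfies `R_F·(x − x_eq)/W = sin(πx/W)` with `x > x_eq`, which is
unique, strictly decreasing in `R_F`, and therefore strictly decreasing in
particle size — larger particles focus nearer the inner wall, the ordering
the separation exploits. In the straight-channel limit (De → 0) the Dean
term vanishes and the root reduces to the lift-only offset `x_eq`. This sign
structure (lift anchoring large particles near the inner-wall equilibrium,
Dean circulation carrying small particles outward) is the minimal 1-D
closure that honors the force magnitudes, reproduces the observed size
ordering, and has a well-defined straight-channel limit; it is a package
design choice, not a field solution. Particles below the critical
confinement ratio never focus: predictions carry an `unfocused` flag with
undefined distance, and the absence of any sign change raises an error
rather than clamping.

Focusing length: `L_f = πμH²/(ρU_m a²C_L)`; requirement #1 passes when
`L_f ≤ L_total`. Validation uses the normalized error
`|d_sim − d_exp|/d_exp`; `model_comparison` calibrates each lift model once
at the design condition and ranks models by mean error across a measurement
table — the single shared calibration is what lets the models' different
Re-dependences differentiate them across a pressure sweep.

## Outlet partition and cut-off tuning

The widened outlet section is partitioned into streamtube bands whose width
fractions equal the balanced flow fractions (plug-flow approximation; a
parabolic-profile partition is provided as an alternative). Streamline
positions computed in the main channel map to the widened section by
conserved width fraction. The cut-off size is the particle whose streamline
sits on the innermost boundary; `tune_cutoff` either

* bisects the flow (Brent-refined, convergence checked against the 0.1 μm
  position tolerance; the calibration constant stays pinned to its original
  reference so tuning is a fixed point), or
* moves the boundary onto the streamline and re-derives outlet widths
  realizing the required split at fixed total outlet width and heights
  (`wᵢ ∝ 1/fᵢ`; for a two-outlet network with an 80/20 split over 515 μm
  this yields exactly the 103/412 μm redesign split).

Both modes report a verification table at cut-off ± 1 μm (the 2 μm
separation range).

## Virtual sorting

Each particle draws a size (point mass or truncated normal), takes its
predicted streamline position in the outlet section, is jittered by a
Gaussian dispersion `σ(a)`, and is assigned to the band containing it;
boundary ties go to the inner side (favoring capture sensitivity over
purity; configurable). Continuous size distributions are interpolated over a
solved 64-point grid; up-to-64 unique sizes are solved exactly. Unfocused
sizes fall back to uniform placement across the width (Dean mixing) with a
warning. The seed is mandatory — there is no silent default — and fixed
seeds reproduce outcomes bit for bit.

Yields follow the bead-experiment definitions (above-cut-off: inner outlet
over total; below: non-inner over total). The published global yields
(81.75% original, 89.34% redesign) are experimental quantities; the
simulator does not claim to predict them without a fitted dispersion model,
and any such fit would be calibration, not prediction. The default fixture
dispersion `σ(a) = max(0.5 μm, 0.03·W_up·(9 μm/a))` is synthetic
bookkeeping for test data generation only.

Enrichment arithmetic: removal `100·(1 − retained/baseline)` (negative
values warned, not clamped; 40,476/ml of 5×10⁹ → 99.9992%, printed 99.99;
158,460/ml of 4×10⁶ → 96.04%, printed 96.03 — the thousands separators in
the source counts are periods), fold difference reported raw and floored
(16,339/1,412 → 11.57 → 11-fold), throughput `time = ⌈diluted volume /
combined flow⌉` in whole minutes (12 × 1150 μl/min = 13.8 ml/min; 1 L in
73 min), and an advisory 1:94 dilution floor.

## Problem sizes and determinism

Default test and acceptance workloads are deliberately small: ≤10⁵
Monte-Carlo particles for binomial checks, 512-point root brackets, 400-point
tuning sweeps. These sizes give 3σ statistical margins on every stochastic
assertion while the entire suite remains a desk-scale computation. All
randomness flows through `numpy.random.default_rng(seed)`; hypothesis
profiles are derandomized.

## Limitations

* The 1-D closure predicts a single equilibrium per size; real devices show
  partial streamline overlap near the cut-off (particle–particle
  interactions) and mid-channel migration of the largest particles, neither
  of which is modeled.
* Lift-only equilibrium offset (0.2·W) and the closure profiles are
  conventions, pluggable but not fitted to field data.
* Whether the lift denominator should be `H²` or `D_h²` cannot be settled
  from the available expressions; the calibration constant absorbs the
  difference, so only size scaling is treated as model-testable.
* Hydraulics neglects curvature corrections, elastohydrodynamic coupling,
  startup transients and non-Newtonian rheology (dilutions ≥ 1:94 are
  water-like by assumption).
* The synthetic fixture generator reproduces the *shape* of bead-calibration
  data (size × pressure grid, Gaussian streamline spread) but none of its
  experimental error structure; passing model-recovery tests therefore
  demonstrates internal consistency, not field accuracy.
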