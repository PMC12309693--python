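# Model and methods

## Scope

`midlinesim` simulates the coordinated posterior elongation of the embryonic
midline tissues as a 2D vertex model of linear cell chains: a notochord
*leader* that elongates by clocked addition of cells at its posterior tip,
and floorplate/hypochord *followers* that elongate through graded collective
migration and stretch-triggered cell division, optionally tethered to the
leader's tip by a shared vertex. It also implements, as pure functions, the
standard manual-measurement formulas for such systems (polarity indices,
kymograph velocities, intensity-profile normalization, ROI statistics), and
synthetic-data generators that produce every input with known ground truth.

## Geometry

A tissue is a chain of quadrilateral cells sharing vertices along their
lateral edges. Cells store four vertex indices in a fixed cyclic order with
the basal pair first and the apical pair last, so the basal and apical edges
are always edges 0 and 2 of the cycle. Each tissue carries an `EcmFrame`: a
horizontal basal reference line `y = basal_y` plus an apical direction sign.
Basoapical distances — the arguments of the adhesion and repulsion
potentials — are measured from that line, which lets mirrored tissues (the
hypochord hangs below the notochord with its basal side facing up) live in
one global coordinate system. For mirrored frames the in-pair
anterior/posterior order is flipped so the stored cyclic order always has
positive signed area; all geometric operations are order-invariant, and the
engine rejects any state in which a cell's signed area becomes non-positive
(see *Degenerate states* below).

## Energy and dynamics

The tissue energy is

U = (a/2) Σ (Vᵢ − V₀)² + (b/2) Σ Lᵢ² + c Σ Σ_{j∈Bᵢ} f(δⱼ) + d Σ Σ_{j∈Aᵢ} g(δⱼ)

with f the piecewise-parabolic adhesion well (minimum −(h_th−h)²/4 at the
ECM distance h, C¹ cutoff at h_th) and g the one-sided harmonic apical wall
beyond ℓ. Forces are the exact analytic gradient (shoelace area gradient,
unit-vector perimeter gradient, branch-wise f′/g′), assembled per cell and
accumulated onto shared vertices; the test suite verifies them against
central finite differences of the energy to 10⁻⁶ relative on randomized
meshes, and verifies C¹ regularity of both potentials at their breakpoints.

Vertices follow overdamped Langevin dynamics τ dr/dt = F + σξ, integrated by
Euler-Maruyama with increments (F/τ)dt + (σ/τ)√dt·N(0,1) per coordinate at
dt = 0.001. The x-coordinates of each tissue's two anterior-most vertices
are immobilized (they receive neither drift nor noise); their y-coordinates
remain free. Migration forces follow η dv/dt = −v + w per cell, advanced by
one classical RK4 step per time step with the activity w frozen within the
step; w is recomputed from cell centroids at the top of every step. The
driftless displacement-variance law (σ/τ)²t and the RK4 closed-form
agreement are asserted by the tests at Monte-Carlo and 10⁻⁶ precision
respectively.

Step ordering: (1) evaluate forces and per-cell measures on the current
geometry; (2) apply both division rules and split due cells (ties in
ascending cell index); (3) update migration forces and apply each follower
cell's force at its posterior basal vertex; (4) update vertices. Identical
seeds and configs give bit-identical traces.

## Division rules

**Stretch-triggered (followers).** A cell's apical+basal edge elastic energy
Uᵢ = b(L²_apical + L²_basal)/2 is compared against the threshold `U_th`.
The first exceedance latches a time stamp Tᵢ; the cell divides at the first
step with t > Tᵢ + S. Under the default `latch-and-recheck` policy a cell
that relaxes below `U_th` before the latency expires clears its latch (the
configurable alternative `latch-and-fire` divides regardless). Division
inserts two vertices at the exact midpoints of the apical and basal edges;
daughters restart with zero migration force, age 0 and a cleared latch, and
no pre-existing vertex moves. Area is conserved exactly at the instant of
division.

**Clocked (leader).** Notochord cells divide on an age clock with period D.
In assemblies the clock is scoped to the posterior-most cell only: the
leader gains one cell per period at its tip, the moving-boundary abstraction
of the progenitor pool that feeds notochord elongation. An every-cell clock
(scope `"all"`, the generic primitive, also provided and tested) doubles the
population every period and is not a sustainable leader model.

## Migration gradient and phenotypes

wᵢ = v_max·sᵢ^α with sᵢ the cell centroid's normalized axis position. The
named presets select the phenotype: `posterior_only` (α = 100; only the tip
cell is appreciably motile), `uniform` (α = 0.01; all cells equally motile),
`graded` (α = 1). When all centroids coincide the activity is v_max by
convention. Because each cell's stretch rate is set by the *difference* of
migration forces across it, the three modes load the tissue differently:
posterior-only loads the tip, uniform dumps the entire differential on the
anterior-most junction (the anterior anchor), graded spreads it evenly —
which is what produces tip-restricted, anterior-rupturing and spatially
unbiased proliferation respectively.

## Assemblies and tethering

The notochord occupies the central band on its ECM line; the floorplate sits
above, adhering to the notochord's apical face; the hypochord mirrors below.
The notochord starts with twice the follower cell count at half the cell
width, so all three tissues share the initial extent. Tethering merges the
posterior basal vertex of the posterior-most follower cell with the matching
posterior notochord vertex (apical side for the floorplate, basal side for
the hypochord) into one vertex placed at their midpoint; the merged vertex
then accumulates both tissues' energy gradients with no extra machinery, and
because midpoint division never replaces a cell's posterior vertices, the
bond stays attached to the posterior-most cells through any number of
divisions. Re-merging is an idempotent no-op.

## Parameters

| name | meaning | default | units |
|------|---------|---------|-------|
| a | area-conservation stiffness | 4.0 | energy/area² |
| b | perimeter-contraction coefficient | 0.05 | energy/length² |
| c, d | basal adhesion / apical repulsion strength | 5.0 | energy/length² |
| V₀ | target cell area | 1.0 | area |
| h, h_th | ECM distance, adhesion cutoff | 0.05, 0.5 | length |
| ℓ | apical confinement distance | 1.2 | length |
| τ, σ | viscosity, noise amplitude | 1.0, 0.01 | — |
| dt | time step | 0.001 | time |
| η, v_max, α | migration relaxation, amplitude, gradient shape | 1.0, 1.5, 1.0 | — |
| U_th, S | division threshold, latency | 0.15, 6.0 | energy, time |
| D | leader clock period | 0.8 / 1.2 (fast/slow presets) | time |
| m | initial follower cell count | 32 (single tissue), 8 (assembly) | — |

Lengths are in units of the initial cell width, time in units of the vertex
relaxation time.

### Calibration rationale

The coefficient set is a calibration, chosen once so the model sits in the
regime the biology describes, and then frozen:

- **Stability.** An isolated square cell has an interior equilibrium only if
  8b < a·V₀ (otherwise perimeter contraction collapses it). a = 4, b = 0.05
  gives a rest side ≈ 0.95 of the target and fast area recovery after
  division.
- **Division threshold.** U_th ≈ b·w*² sets the trigger stretch w*; 0.15
  triggers at ≈ 1.7× the rest width — stretched but far from rupture.
- **Latency.** S is the commitment time between mechanical trigger and
  completed mitosis. It determines whether division relief can keep pace
  with loading: a cell's basal edge peaks near w* + (stretch rate)·S. With
  S = 6 the anterior junction under uniform migration (stretch rate ≈ 0.1–
  0.3 length/time) overshoots the rupture proxy (3× the initial basal
  length) while graded loading (≈ 0.02–0.05 per cell) never does — the
  regime in which "tension cannot be compensated by divisions" at one end
  but can everywhere else. Followers thus cycle much more slowly than the
  leader clock, consistent with the sparse proliferation of these tissues.
- **Migration amplitude.** v_max = 1.5 makes the posterior-only preset
  actually divide (the tip cell must reach w*) while keeping graded runs
  rupture-free with division-position KS ≤ 0.25 across α ∈ [0.85, 1.5].
- **Assembly.** The notochord uses a stiffer parameter set (a = 16, b = 0.2,
  V₀ matched to its half-width cells): the vacuolated notochord is the rigid
  rod of the axis, and the stiffness keeps its elongation tracking the clock
  (≈ 0.49 vs ≈ 0.36 length/time for D = 0.8 vs 1.2) instead of piling
  compressed daughters at the tip. The assembly presets set follower
  v_max = 1.0 (untethered follower rate ≈ 0.42), so the followers lag a fast
  leader and outpace a slow one — the two regimes the tether must buffer.

## Observables

- `tissue_length`: posterior-most minus anterior-most vertex x per tissue.
- `uniformity_statistic`: Kolmogorov-Smirnov distance between division
  relative positions (centroid x normalized by tissue extent at division
  time) and Uniform(0,1); 0 = spatially unbiased. The working bound for
  "unbiased" is 0.25.
- `gap_flag` / `first_gap_time`: cells whose basal edge exceeds 3× the
  initial basal length. A shared-vertex chain cannot literally open a hole,
  so over-stretch is the rupture proxy; `anterior_only` restricts the flag
  to the anterior quarter for the anterior-gap phenotype.
- `length_mismatch_series`: |L_follower − L_leader|/L_leader per frame.
- `export_kymograph`: lateral-boundary occupancy raster (256 bins, linear
  interpolation) whose slanted lines feed the kymograph velocity estimator,
  closing the loop with the quantification module.

## Quantification formulas

All are pure functions over already-extracted measurements (no image I/O):
Golgi position index (a+b)/2L on [0,1]; apical/basal signal ratio summing
the first and last 30% of a membrane profile's arc length (arc length, not
sample count, governs the split when sampling is non-uniform); kymograph
velocity tan(angle)·space/time with the angle measured from the time axis
(0° = stationary) and a centroid-regression angle estimator for rasters;
EdU-positive rate n₊/n; nuclear/cytoplasmic mean ratio; and paired-profile
normalization — running minimum of the reference channel (default window 11
samples) to strip membrane-localized peaks and extract the baseline,
pointwise signal/baseline, 20 equal-width position bins ([left, right), last
bin closed), per-bin mean, and max-rescaling so exactly one bin equals 1.
Binning precedes rescaling. The normalization is invariant to common and to
signal-only positive rescaling.

## Synthetic data

Generators return (data, ground truth) and are bit-reproducible under a
seed: fresh chain meshes; single-front kymographs (Gaussian line profile,
additive Gaussian noise; the raster widens automatically so fast fronts stay
in frame); two-channel axial profiles (power-law gradient × depth-decay
baseline, narrow membrane-like reference peaks whose footprint stays inside
the default filter window, Gaussian noise) with the analytic per-bin truth;
and tidy ROI tables (Gaussian intensity noise, Bernoulli EdU calls). They
emulate the *structure* of real measurements, not microscope physics: no
shot noise, optical blur, segmentation error or depth-dependent gradients
beyond the modeled baseline. Passing closed-loop tests therefore shows the
estimators are correct on their stated measurement model, not that they are
robust to every real-world artifact.

## Numerical choices and degenerate inputs

- Explicit Euler-Maruyama at dt = 0.001 is well inside the stability limit
  of the stiffest term (c, d = 5); the noise-free engine is strict gradient
  descent, and energy descent over 10⁴ steps is asserted by the tests.
- The engine evaluates forces through a fused per-cell kernel (numba when
  available); the pure-numpy implementation in `energy.py` is the reference
  path and both are asserted equal to machine precision.
- Simultaneous division triggers are processed in ascending cell index.
- A cell inversion (non-positive signed area) means the parameter regime
  left model validity: the run aborts with a time-stamped diagnostic
  (`GeometryError`), or, for scenario presets, stops and records the
  diagnostic in `trace.aborted` so the truncated trace remains analyzable.
  Non-finite positions raise `IntegrationError`.
- Degenerate quantification inputs (zero-length cells, zero baselines, empty
  bins, zero totals) raise `MeasurementError` rather than returning NaN; the
  one sentinel is the division-uniformity statistic with no qualifying
  events, which warns and returns NaN.
- Zero-range migration input (single cell or coincident centroids) maps to
  v_max by documented convention.

## Problem sizes

Default study conditions: single-tissue runs use m = 32 cells to t = 100 at
dt = 0.001 (10⁵ steps, ~50–70 cells at the end); assemblies use 8 follower
cells + 16 notochord cells to t = 100 (~200 cells at the end). The
end-to-end test suite runs these conditions across 5 seeds for the phenotype
checks and 3 seeds × 4 exponents for the gradient-shape sweep.

## Known limitations

- Cells are quadrilaterals in a fixed linear chain: no neighbor exchange
  (T1), no extrusion or death, no curved geometries, no 3D.
- The "gap" read-out is an over-stretch proxy; shared-vertex chains cannot
  physically separate.
- FGF signaling, Yap activity and cadherin adhesion appear only as their
  mechanical abstractions (graded activity, stretch threshold, shared
  vertex); the model makes no molecular predictions.
- The biological parameter values are unknown; the defaults are a
  calibration to the qualitative regime (see above), so quantitative outputs
  are in model units and should be read comparatively, not absolutely.
- Uniform-migration runs intentionally leave model validity after anterior
  rupture; their traces are truncated at the inversion time.
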