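# Methods

`oxyvoxel` simulates the tissue inside a single ~1 mm² radiology-image
voxel as an off-lattice collection of vessels, tumor cells and stromal
cells coupled to a continuum oxygen field, and solves two inverse problems
against voxel-average oximetry data: *which tissue morphologies are
consistent with a measured average pO₂*, and *which time-varying vascular
supply or cellular uptake schedule reproduces a measured short-time pO₂
fluctuation*.

## Tissue generation

A composition (vascular, tumor, stromal area fractions in percent) is
realized by `N = round(fraction/100 · |Ω| / (πR²))` disks per element type
(nominal, unclipped disk areas; disks may clip the domain boundary).
Centers are i.i.d. uniform over Ω = [−500, 500]² µm. Overlaps are then
resolved by overdamped relaxation: every cell moves with velocity
`F_net/ν`, where contacting pairs exert a repulsive Hookean force of
magnitude `F·(R_i + R_j − d)` along the center line. Vessels never move
and may overlap one another (irregular vessel cross-sections); cells may
not overlap cells or vessels.

Numerical choices:

- Explicit Euler with `dt_relax = 1 s`. The two-body contraction factor is
  `1 − 2·F·dt_relax/ν = 0.6` per step, comfortably stable.
- Termination when the largest per-step displacement drops below
  `tol_disp = 10⁻³ µm`, at an iteration cap of 10⁴, or when the
  displacement has plateaued (a 150-iteration window improving by < 2%),
  which flags a jammed packing. Jammed layouts are returned with their
  residual-overlap count, not raised as errors: compositions with total
  occupancy above the random disk-packing limit (~85% for this size
  mixture) cannot be realized without residual contact compression, yet
  they are legitimate members of the composition sweep.
- Exactly coincident centers repel along a seeded per-cell random
  direction (force direction is undefined at zero separation).
- Cells leaving Ω are clamped to the boundary.
- Contact tolerance: pair compressions shallower than 0.05 µm (~1% of the
  stromal radius) count as contacts rather than overlaps. The overdamped
  dynamics admits force-balanced wedge equilibria — e.g. a cell squeezed
  symmetrically between two immobile vessels — whose tangential escape is
  asymptotically slow; their residual depth is physically meaningless
  compression, not overlapping tissue. Under this tolerance, layouts with
  total cellular fraction ≤ 50% relax to zero overlaps.
- Neighbor search uses uniform spatial binning (bin ≥ the largest
  interaction distance of the pair class); it is contractually equivalent
  to the all-pairs sum and tested against it.

## Oxygen dynamics

Oxygen `γ(x, t)` (model units ≡ mmHg via the vascular level
`γ_max = 60 mmHg`) obeys a reaction–diffusion equation with three terms:
vascular influx `δ_V(t)·γ_max` at every node within `R_V` of a vessel
center, Fickian diffusion `D_γ Δγ`, and Michaelis–Menten cellular uptake
`−U·γ/(κ_m + γ)` with `U` proportional to the number of covering tumor
cells (rate `δ_T(t)·T_max`) and stromal cells (rate `S_max`). Coupling to
the Lagrangian elements uses the indicator `χ_R` (strict Euclidean
inequality); contributions of multiple covering elements add.

Discretization: forward Euler, 5-point Laplacian, `dx = 5 µm`
(201×201 nodes), `dt = 0.05 s` (`D·dt/dx² = 0.2 ≤ 1/4`; parameter sets
violating the bound are rejected). Boundaries are no-flux (mirror):
the voxel sits inside contiguous tissue, and zero-flux closure makes the
steady-state influx/uptake balance exact under trapezoidal quadrature,
which the tests verify to 10⁻⁶ relative. The field is clipped at zero
after each step (floating-point guard; the saturable uptake cannot drive
the continuum solution negative).

### Vessel ceiling

The influx term alone, taken literally as a constant volumetric source,
admits no bounded steady state whenever the saturated uptake capacity of
the cells falls short of the total influx — in this parameterization that
happens for 84 of the 1530 sweep compositions (sparse cellularity with
rich vasculature), whose averages would run to hundreds of mmHg. Tissue
pO₂ also cannot physically exceed the oxygen content of the supplying
vessels. The solver therefore caps vessel-covered nodes at their
intravascular level `δ_V·γ_max` after each step. With the cap, every
composition has a bounded stationary field, the library average stays
within [0, 60] mmHg, and at `δ_V = 1` vessel nodes sit pinned at 60 mmHg
(the cap is equivalent to a Dirichlet condition inside vessels whenever
the source is strong enough to reach it, which it is in practice). At low
`δ_V` the capped vessels also act as sinks — venous blood clearing tissue
oxygen — which is what lets vascular modulation drive the fast, deep pO₂
drops seen in the data. The literal, uncapped source form remains
available (`ModelParams(vessel_ceiling=False)`) and is used by the
small-grid Newton cross-checks.

### Uptake scaling

The published base uptake rate (0.382, per cell volume in mass units)
does not fix the strength of the nodal sink on a 2-D grid. A single
dimensionless factor `uptake_scale` multiplies `T_max` and `S_max` at
every covered node. It was calibrated once — bisection on the full
pipeline so that tissues of 3.5% vascularity, 55% tumor and 30% stromal
cellularity stabilize at ≈ 29.9 mmHg (replicate mean) from a zero field at
`δ_V = δ_T = 1` — and frozen at `uptake_scale = 4.875`. Per-node tumor and
stromal rates are weighted equally (`stromal_node_weight = 1`), following
the model equation; a volume-proportional weighting was evaluated and
reproduced the published steady-state statistics less well.

With this one factor fixed, the model reproduces the reported stabilized
levels of the calibration composition, of a moderately hypoxic tissue
(1.5/40/45) and of a severely hypoxic one (0.5/20/75) within the reported
replicate spread, but systematically under-oxygenates three reported
replicate-mean compositions (1.5/15/15, 2.5/30/35, 4/75/20) by 3–6 mmHg.
No global scaling removes this residual (it trades those compositions
against the hypoxic ones), so the published values appear to encode a
composition-dependence of the uptake discretization that the printed
equations do not determine. We keep the prescribed single-point
calibration and report the discrepancy rather than fitting per
composition.

### Stabilization

The stationary field is reached by iterating the explicit step from a
uniform initial value (0 mmHg by default) until the normalized error
`ε̄ⁿ = ‖γⁿ − γⁿ⁻¹‖₂ / (N_i·N_j)` falls to 10⁻¹⁰ (evaluated every step;
a literal sum-of-squares variant without the square root is available via
`sqrt_norm=False`). The calibration composition converges in ≈ 2×10⁴
steps, and the stabilized level is independent of the initial value
(0/30/60 mmHg agree within 0.1 mmHg). Divergence (non-finite values)
aborts with an error; in the uncapped variant, layouts whose influx
provably exceeds the saturated uptake capacity are rejected up front.

## Tissue library and matching

The sweep enumerates vascularity 0.5–5% (step 0.5), tumor cellularity
10–95% and stromal cellularity 5–95% (step 5), keeping total occupancy
≤ 100%: exactly 1530 compositions. One morphology per composition is
generated with a per-composition seed spawned from (global seed, index),
so entries are independently reproducible; builds are checkpointed to CSV
and resumable. Stabilized averages are binned into five 12-mmHg classes
over [0, 60]; bins are half-open with a closed top bin (36.0 mmHg → class
3, 60.0 → class 4). Matching returns the entry with the smallest
|average − target| (ties to the lower composition index); representative
sets collect all entries within ±3.5 mmHg of a target.

## Schedule fitting

Measured series give the voxel average at t_k ∈ {4, 7, …, 28} min. Rates
are piecewise constant on (0,4), (4,7), …, (25,28) min, with `δ_V ∈ [0,1]`
and `δ_T ∈ [0,50]`. Starting from the tissue's own stationary field,
segments are fitted sequentially in time order — the system is causal and
the L1 matching objective separable, so the greedy per-segment solution is
the joint optimum. Each segment's rate is found by a one-dimensional
mesh-adaptive pattern search: poll ±mesh around the incumbent (the
previous segment's accepted rate; segment one starts at 1), double the
mesh on an improving poll, halve otherwise, project to the bounds, and
stop when the mesh falls below `range/4096` or the endpoint is within
`fit_tol = 0.01 mmHg` of the target. The dyadic mesh ladder mirrors the
dyadic rate values the underlying direct-search method produces. Failed
simulations inside a poll score +∞. During influx fitting `δ_T ≡ 1`, and
vice versa; the mechanisms are never co-fitted.

Goodness of fit defaults to the relative Euclidean error
`‖γ_E − γ_opt‖₂ / ‖γ_E‖₂` (dimensionless; an all-zero measured series
falls back to the absolute RMS). The literal mean-square form
`(1/N)·Σ(γ_E−γ_opt)²` is available as `gof_form="mean_square"`; reported
thresholds (0.1 accept, 0.2 robustness) behave like relative errors, so
the relative form is the default, and every result records which form it
used.

`FluctuationModel(roi, layout).fit(mode)` wraps the pipeline in a
model/results interface; `FluctuationResults.summary()` prints the
per-segment table.

## Robustness analysis

A fitted schedule is applied verbatim (no re-optimization) to every
representative tissue, each starting from its own stationary field; the
report records composition, stabilized-pO₂ deviation from the anchor, and
GoF per mechanism, plus pass counts below a threshold (default 0.2). Pass
sets are nested in the threshold, and fits degrade with |deviation|.

## Synthetic ROI fixtures

The oximetry experiment behind the four regions of interest published
only per-region anchor values (36.312, 22.89, 13.99, 1.83 mmHg); the full
9-point series exist only as a figure in the cited experimental study and
are not digitized here. The fixture generator produces clearly labelled
synthetic stand-ins anchored at those values: `flat`, `drop_recover` (two
large dips with recoveries, emulating the described >5-fold swings),
`oscillate`, and seeded `random_walk`, all clipped to
[0, anchor + amplitude]. Ground truth for recovery testing comes from
forward-simulating a known schedule and refitting it.

Because the real series are unpublished, the published optimal schedules
and their GoFs cannot be reproduced numerically; the tests substitute
(a) schedule recovery — refitting forward-simulated series returns the
series with GoF < 0.02 — and (b) the mechanism asymmetry on a
large-amplitude drop-recover fixture. Under the calibrated model the
asymmetry is reproduced qualitatively: influx fitting tracks the
fluctuation (GoF ≈ 0.03), while uptake fitting saturates at the 50-fold
bound and cannot reach the dips (simulated floor ≈ 12 vs 6 mmHg target).
It is not reproduced quantitatively (our uptake GoF ≈ 0.07, far from the
near-unity failure reported for the steepest region): with any uptake
scaling consistent with the published steady states, a 50-fold uptake
increase empties the voxel to its perivascular floor within a 3-minute
segment. The quantitative contrast evidently depends on the shape of the
unpublished series.

## What the synthetic data do and do not show

Generated tissues emulate composition (area fractions), randomness of
placement, and non-overlap constraints; they do not emulate spatially
correlated vascular architecture (vessel clustering, cords), variable
element sizes, vessel patency, or 3-D structure. Fixture series emulate
anchor levels and fluctuation magnitude/speed, not measurement noise or
tracer kinetics. Passing tests therefore demonstrate internal consistency
of the solver, the optimizer and the published summary statistics — not
fidelity to any individual animal's tissue.

## Problem sizes used by the test suite

Steady-state comparisons against published values run at the full study
size (1 mm² voxel, 201×201 grid, 25 replicates where the published value
is a replicate mean). The library-structure check runs on a random
150-composition subsample of the 1530-member sweep, comparing the
36–48 mmHg class share (506/1530 ≈ 33%) within sampling tolerance.
Dynamic fitting tests use a reduced 400×400 µm voxel (81×81 grid), where
the fluctuation physics is unchanged; the full-size pipeline is exercised
by the steady-state tests and the CLI smoke test on a 300×300 µm patch.

## Known limitations

- The nodal uptake conversion is calibrated, not derived; steady-state
  averages for three published compositions sit 3–6 mmHg below the
  reported means (see "Uptake scaling").
- Jammed packings (total occupancy ≳ 85%) retain micro-overlaps; their
  indicator masks count nominal coverage.
- The per-segment search certifies a mesh-local optimum only; for
  monotone endpoint responses (verified invariant) this is the global
  per-segment optimum.
- 2-D cross-section only; no intravascular hemodynamics, hemoglobin
  binding, or cell kinetics (the fluctuation window is 30 minutes).
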