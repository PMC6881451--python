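# Methods

## Model overview and assumptions

The simulator is an on-lattice cellular automaton: one cell per cubic voxel
(edge 0.012 mm, matching the mean HCT116 cell diameter), no migration, no
mechanics, and a fixed lattice (typically 100³–200³ voxels). Cells carry an
individual cycle timer (G1/S/G2/M), a treatment-fate label, a hypoxia flag
and per-cell timers for heat-death delay and post-heat arrest. Untreated
normoxic cells have unlimited division potential and never die; the only
untreated death route is chronic hypoxia. Everything the model cannot
resolve about the core microenvironment (nutrient depletion, debris,
pressure) is deliberately folded into the single label "hypoxia".

Division searches the Moore and von Neumann neighbourhoods up to second
order, alternating per cell between the two (a per-cell parity counter is
incremented at every division attempt). Among free voxels the one nearest
the cell-mass centroid is taken, ties broken by the seeded RNG; with no free
voxel the cell enters reversible quiescence (G0) and re-checks for space
every step. After removals the mass is re-compacted: empty voxels are
visited from the centre outwards and each hole repeatedly swaps with its
most radially-outward occupied first-order neighbour until it surfaces.
This conserves cell count and state, preserves radial layering (important
for the encapsulation of dying quiescent cells), and terminates because the
total squared radial moment strictly decreases with every swap. Cell update
order within a step is a fresh random permutation each step, avoiding
lattice-sweep anisotropy.

## Oxygen

Steady state of `dp/dt = D ∇²p − Φ(x)` is found by projected SOR on the
7-point stencil. Every *unoccupied* voxel — not just the lattice boundary —
is a Dirichlet node at p0 = 100 mmHg (well-mixed medium); occupied voxels
are unknowns, necrotic cells occupy space but consume nothing, and values
are clamped to [0, p0], which stops consumption at anoxia (an obstacle
problem). Convergence is declared when the largest per-sweep change is
≤ 0.01% of p0; the absolute reference is used because a criterion relative
to near-zero anoxic values would never be met. The field is recomputed once
per CA step, warm-started from the previous step. Defaults: D_O2 =
3.8e-9 m²/s, Φ = 22.1 mmHg/s, over-relaxation ω = 1.85, iteration cap 2e5
(exceeding it raises with the residual).

The analytical radial model (surface pressure p0, diffusion limit r_l,
anoxic-core radius r_n) serves as the verification oracle. Two conventions
needed fixing where its printed HCT116 parameters (r_l = 233 µm,
r_n = 155 µm) meet spheroids of other sizes:

* spheroids smaller than the diffusion limit get r_n = 0 (no core can
  exist);
* comparisons and the diffusion-coefficient fit are evaluated on the
  model's validity domain r_n ≤ r ≤ r0. Inside r_n the model *defines*
  p = 0 as its inner boundary condition rather than predicting it, and the
  fixed printed (r_l, r_n) pair is only self-consistent near one spheroid
  size; comparing where the model is a genuine prediction is what makes the
  lattice solution and the closed form agree to a few percent of p0, with
  the largest deviations in the outermost cell layers (boundary
  discretisation). The full-plane maximum is also reported alongside.

With this convention a dense 250 µm sphere at the default parameters shows a
maximum central-plane difference of ≈3.9% of p0, and a grid search of D over
[1e-9, 1e-8] m²/s against the model on the two smallest reference sphere
sizes (142 and 250 µm radius, summed squared difference) recovers a
minimizer of ≈3.2e-9 m²/s. A known limitation: pooling the *larger* sphere
sizes pulls the minimizer toward 2.0e-9 m²/s — exactly r_l²Φ/(6 p0), the
value implied by the printed r_l — because no single D reproduces the fixed
(r_l, r_n) pair across all sizes; the printed parameters are internally
consistent only size-by-size.

An independent 1D spherical finite-difference steady state (4 µm mesh,
active-set handling of the anoxic obstacle) lives in the test suite and
bounds the 3D solver's discretisation error (≤5% of p0 on an 80 µm sphere at
12 µm voxels).

## Growth

dt = 1 h resolves the shortest cycle phase (M, 1.4 h). Phase durations are
fractions 0.40/0.35/0.20/0.05 of the doubling time (28 h default), jittered
per cell at birth by Uniform(0.9, 1.1) to desynchronise lineages. Hypoxic
cells (pO2 strictly below 11 mmHg) pause cycle progression while hypoxic
(configurable toggle, default on), die with p_hypoxiaDeath = 0.01 per step,
and the necrotic cells they become are cleared with p_clearNecrotic = 0.001
per step. No minimum-time-under-hypoxia or minimum-time-before-clearance
parameters exist; the small per-step probabilities play that role.
Simulated time runs on the experimental clock: growth starts on day 3 after
seeding (attachment/acclimatisation allowance), and the initial state is a
dense sphere of the configured diameter with uniformly random phases and
clocks.

With these defaults the birth/clearance balance that flattens the growth
curve lies at millimetre scale (rim births scale with r², clearance with the
r³ necrotic volume, giving a balance radius ≈ 3·w·h/(T_d·p_clearNecrotic)
for rim width w); within a three-week window the curve is near-linear with
slow deceleration. The plateau test therefore uses a *scaled* scenario —
reduced D_O2 (0.1e-9 m²/s, shrinking the oxic rim to ~30 µm) and
proportionally faster clearance (0.1/h) — so the same balance mechanism
completes inside a 38³ lattice and a 48-day horizon.

## Treatment cascades

Radiation: each cell draws against its own S_RT (dose divided by the OER at
its voxel, γ weight by phase; defaults γ ≡ 1). Survivors continue without
delay; losers are labelled dying and persist until a division attempt, where
they die with p_mitoticDeath (0.44 within t_delayRT = 3.5 d of exposure,
0.59 after — the switch clock is per exposure) or else produce two dying
daughters. Dying cells blocked by space enter G0 like any other cell; the
fate draw happens only at an actual attempt. This yields outside-in
shrinkage of lethally irradiated spheroids and, at low doses, dying
quiescent cells encapsulated in the core by regrowing survivors.

Hyperthermia: survival follows the AlphaR model on the natural-log scale,
capped at S = 0.0005 above 160 CEM43. Cycle-stage weights γ_HT keep the
fixed ratio 1.5 between G1, S and G2 (M treated like G2), normalised to a
cycling mean of 1; G0 cells are three-fold resistant, applied on the
exponent (−ln S scaled by 1/3) since γ multiplies the exponent — a
"survival-scale" alternative is configurable. Death delays are
Normal(96 h, sd) truncated at zero with sd defaulting to mean/4 (the spread
is not constrained by data); survivor arrests are Uniform(0, 2·30 h) so the
stated mean is honoured with bounded support. Dying heated cells ignore
phase and position, are removed when the delay expires, and compaction plus
the ordinary step loop produce reoxygenation and quiescence reactivation.
Heat sensitivity is deliberately independent of oxygenation and pH.

Combination (simultaneous RT+HT): one draw against S_RTHT — the LQ model
with thermal-dose-dependent α(t43), β(t43) lookup tables (linear
interpolation; the zero-dose entries must equal the RT-only α, β) — routes
cells to radiation death; a second draw against S_HT routes survivors of the
first to heat death; the rest survive with a heat arrest. Expected
surviving fraction: S_RTHT·S_HT.

The LQ and AlphaR coefficients (α, β, α0, β_HT, per-phase γ for RT, the
α(t43)/β(t43) tables) are cell-line inputs that must come from clonogenic
data; the package ships clearly-flagged illustrative defaults (α = 0.2/Gy,
β = 0.02/Gy², α0 = 0.1/CEM43, β_HT = 0.001/CEM43²), and any run leaving them
at defaults logs them as non-measured.

## Diameter metric, calibration

Spheroid diameter is twice the mean of the 100 largest cell-centre distances
from the centroid (all cells when fewer than 100) — the factor 2 resolves
the radius/diameter ambiguity in the metric's verbal definition and is fixed
here by the requirement that a digital sphere of radius R measures ≈ 2R.
Goodness of fit is R² about the reference-curve mean, with the simulated
curve linearly interpolated at the reference times; a constant reference is
rejected as an undefined objective. Calibration is a one-at-a-time grid
search in a user-stated parameter order, each parameter controlling a
distinct curve feature (growth slope, plateau onset, shrinkage rate, peak
location, regrowth time); cross-correlations are not explored, and each
evaluation uses one fixed simulation seed so the objective surface is
deterministic. Support intervals are reported as the grid values within
ΔR² = 0.02 of the optimum — grid-resolution statements, not sampling-theory
confidence intervals.

## Synthetic reference curves

Because the simulator's experimental counterpart data are not distributed
with it, reference growth curves for calibration tests are self-simulated:
run a scenario, sample the diameter every other day from day 4 (the imaging
cadence) on the day-3-offset clock, and add i.i.d. Gaussian noise (default
10 µm, a plausible imaging-cytometer repeatability; the true noise model is
uncharacterised). These stand-ins reproduce the cadence, offset and noise
scale of real curves but not their biological variability between wells, so
recovery tests demonstrate identifiability of the machinery — not accuracy
on real data.

## Numerical and degenerate-input choices

* Strict inequality for hypoxia (11.0 mmHg is *not* hypoxic).
* OER piecewise form is continuous at 11 mmHg; negative pO2 or dose raise.
* β_HT = 0 with α0 > 0 is rejected (AlphaR transition dose undefined).
* Ties in division-site and compaction choices are broken uniformly with
  the seeded RNG; identical seeds give bit-identical trajectories.
* Timer comparisons carry a 1e-9 h epsilon so exact-multiple phase
  durations divide on schedule rather than one step late.
* Empty grids: relaxation returns a uniform field; the diameter metric
  raises; trajectories record zero diameter.

## Known limitations

Fixed voxel size forbids cell-size change, density loosening and mechanical
compression; treated spheroid "loosening" observed experimentally in the
first week after heating is therefore not reproduced. Oxygen is the only
diffusive species. The plateau at default parameters lies beyond desk-scale
lattices (see above). Printed oxygen-model parameters are only
size-consistent locally, which bounds how well a single diffusion
coefficient can be recovered from multi-size fits.
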