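# Methods

## The transwell permeability model

A transwell insert separates a luminal (donor, "blood-side") compartment of
volume V_L from an abluminal (receiver, "brain-side") compartment of volume
V_R by a filter carrying the endothelial monolayer. For a passively diffusing
tracer the amounts X_L, X_R obey the linear two-compartment system

    dX_R/dt = PS·(X_L/V_L − X_R/V_R),    dX_L/dt = −PS·(X_L/V_L − X_R/V_R) − λ·X_L

with PS the permeability–surface product (µL/min) and λ an optional
first-order nonspecific-loss rate acting on the donor side (adsorption to
plastic, metabolism). With λ = 0 the receiver amount has the closed form
X_R(t) = X₀·V_R/(V_L+V_R)·(1 − e^(−kt)), k = PS·(1/V_L + 1/V_R); with λ > 0
the simulator uses the matrix exponential of the 2×2 system. Both are exact
for the linear model; a fourth/fifth-order Runge–Kutta integration of the same
ODE serves as an independent oracle in the tests (agreement ≤ 1e-6 relative)
and is never used as the engine.

The simulator deliberately does **not** assume sink conditions: with the
miniaturized 70/300 µL geometry, donor depletion and receiver back-pressure
are non-negligible within an hour at filter-like permeabilities.

### Estimation

The cleared volume Cl(t) = C_R(t)·V_R/C_L0 is fitted against time by ordinary
least squares with the exact point (0, 0) included (the cleared volume is
identically zero at t = 0); with a single post-zero sample — the routine 1-h
single-timepoint assay — the estimator reduces to Cl(t)/t through the origin.
The slope is PS. Blank (coating-only) wells run alongside give PSf as the
batch mean; each cell well's PSt is corrected to the endothelium-only PSe via
1/PSe = 1/PSt − 1/PSf, and Pe = PSe/A (1 µL/min per cm² = 10⁻³ cm/min).

Finite incubation makes the raw linear-slope estimator *underestimate* PS
(ratio (1 − e^(−kT))/(kT), monotone decreasing in T). Because the blank wells
are far leakier than the cell wells, their slopes are attenuated more, and the
two biases largely cancel through the series correction: at the default
single 60-min sampling, a 0.33×10⁻³ cm/min barrier against a 10×10⁻³ cm/min
filter is recovered with ≈ +0.6% systematic error noise-free, and within a
few percent with 10% measurement noise over a 50-well batch. A property test
documents the uncorrected underestimation.

Wells where PSf ≤ PSt are *flagged* (non-physical: cells add no resistance)
and excluded from summaries rather than clipped, which would bias Pe
downward. Mass balance outside 80–120% (configurable) of the initial amount
also flags a well; flagged wells are excluded from `mean_pe`.

## Measurement-noise model

Fluorescence and LC–MS readouts are positive and roughly heteroscedastic with
constant CV, so noise is multiplicative log-normal with unit mean,
σ² = ln(1 + CV²), applied independently to every *measured* concentration
(including the t = 0 donor aliquot, which is also pipetted and read);
underlying kinetics stay exact. One seeded `numpy` generator per simulation
call, no global RNG state. Unit-mean noise keeps the slope estimator
near-unbiased; the 1/C_L0 dependence contributes a small (+CV²) positive
bias, ≈ +1% at CV = 10%.

## Plate formats and resources

The registry stores the three published insert systems. Each format carries
*assay* volumes (Ringer-HEPES: 500/1500 µL in the 12-well model, 70/300 µL
in the 96-well systems) and *culture* volumes (growth medium: 500/1500 µL
and 75/300 µL respectively) — the 96-well systems fill slightly different
luminal volumes for culture (75 µL) and assay (70 µL), and the published
consumable totals (24 mL medium per 12-well plate, 36 mL per 96-well plate,
hence 576 vs 108 mL per 96 experimental points at three fills) are culture
arithmetic. The abluminal 96-well culture volume is stored as 300 µL, the
upper end of the working 275–300 µL range, which is what the 108 mL total
implies. `n_medium_fills` defaults to 3 (seed fill + two changes over the
6-day coculture) and is exposed because protocols vary. Whole plates are
coated and filled, so totals scale with plates, not points; Matrigel for a
full 96-well plate is 96 × 35 µL = 3.36 mL.

## Brain exposure (recovery and Kp,uu,brain)

U = (CD + CR)·100/C0 and Kp,uu,brain = ((C0 − CD)/CD)·(U/100). Recovery
enters as a *fraction*: applying it in percent would inflate Kp,uu 100-fold
off the physiological 0–2 range. Note U sums concentrations from compartments
of unequal volume, so it is not a mass balance; when the geometry is known an
amount-based balance (CD·V_L + CR·V_R)/(C0·V_L) is reported as separate QC.
CD > C0 (apparent negative transport) is treated as a QC failure — flagged,
Kp,uu reported as 0 — not as real reverse flux. The synthetic IVIVC generator
inverts these two formulas (CD = C0/(1 + Kp,uu/(U/100)), CR = (U/100)·C0 − CD)
so noise-free triplets round-trip exactly; feasibility requires
U/100 + Kp,uu ≥ 1.

The in vitro–in vivo correlation is fitted as a power law by OLS in log-log
space, with R² on the log scale: Kp,uu values span two orders of magnitude
and the comparison is ratio-scaled, so log-log is the natural scale; the
functional form is a package choice where only "nonlinear regression" is
conventionally specified. Degenerate inputs: constant in vivo values give
SS_tot = 0, reported as R² = 0.

## Screening

The 1–3–10 half-log ladder generator validates both bounds against the grid
(1×10ⁿ or 3×10ⁿ, relative tolerance 1e-6) and names the nearest grid points
on error. A full d-decade span yields 2d + 1 points (0.001–100 µM → 11).

Disruption flagging uses mean-Pe > control-mean + k·SD (default k = 3) rather
than per-dose t-tests: screens run with n ≈ 2 replicates per dose, which
makes per-dose tests uninformative, while the control pool is larger. The
rule depends only on the standardized excess over control, hence is invariant
to affine rescaling, and on monotone dose–response data the flag set is
upward-closed. Welch's unequal-variance t-test (two-sided) is the default
two-group comparison throughout; no multiplicity correction is applied across
ladder concentrations by default since the flag rule is not p-value based.

Efflux accumulation is reported as percent increase of the inhibitor-treated
mean over the control mean. The denominator convention is isolated in
`efflux_analysis` so it can be swapped; "percent of dose" is the plausible
alternative reading.

## Synthetic-data generator: what it does and does not emulate

Defaults encode the assay conditions: 96-well Corning geometry
(0.143 cm², 70/300 µL), 1 µM tracer, single 60-min sampling, baseline
endothelial Pe 0.33×10⁻³ cm/min (the non-disrupting level of an intact
barrier). No published value exists for the coated-filter permeability or the
R123 kinetics, so these are synthetic choices made once: filter Pe
10×10⁻³ cm/min (a coated PET membrane is much leakier than a tight
monolayer); efflux uptake 0.02 min⁻¹, passive efflux 0.01 min⁻¹, active
efflux 0.008 min⁻¹ at the 5 µM/120 min assay conditions, which yields an
accumulation increase of ≈40% under full inhibition — the magnitude observed
in miniaturized systems. Only relative/ordinal efflux behaviour is
meaningful. The built-in disruptor model (Hill curve, baseline 0.33×10⁻³,
max 5×10⁻³ cm/min, EC50 2 µM, coefficient 2) places the detectable onset at
0.3 µM on the standard ladder with low-noise screens.

The generator emulates passive two-compartment diffusion, first-order
nonspecific loss, single-compartment cellular accumulation, and
concentration-dependent barrier disruption with multiplicative noise. It does
**not** emulate cell-growth or coculture-differentiation dynamics, spatial
gradients, carrier-mediated transport of the integrity tracer, plate-edge or
batch effects, or correlated noise between compartments. Passing
parameter-recovery tests therefore demonstrates correctness of the estimation
chain under the stated model, not robustness to every artefact of real
plates.

## Numerical choices and problem sizes

- Closed-form/matrix-exponential kinetics; RK45 integration only as a test
  oracle at rtol 1e-10.
- Filter-correction round-trip asserted to 1e-12 relative on moderate PS
  ratios (extreme PSf/PSt ratios lose precision to reciprocal cancellation in
  any floating-point implementation).
- TSV result files are written with shortest round-tripping float
  representations and re-read with round-trip float parsing (≤1e-12 relative
  drift asserted).
- Simulation sizes in tests and the acceptance script — 50-well recovery
  batches, 9-compound IVIVC panels, 11 × 4-replicate dose–response screens,
  2000-permutation oracles — keep the full suite under ~10 s on one CPU while
  leaving Monte-Carlo error well inside the asserted tolerances.
- Sample SD uses the n−1 denominator; SD of a single well is reported as NaN,
  not 0.

## Known limitations

- The clearance-slope estimator is first-order in kT; heavily non-sink
  protocols (long incubations with leaky barriers) should shorten sampling
  rather than rely on the partial bias cancellation described above.
- PSf is estimated per batch from blanks run alongside; no historical-lot
  pooling.
- The screen's k·SD flag inherits the vehicle pool's sampling noise; with few
  controls, marginally elevated doses near the detection edge can flip across
  seeds.
- Kp,uu prediction assumes measured concentrations are free (unbound)
  concentrations; protein-binding correction is upstream of this package.
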