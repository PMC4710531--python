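# Methods

## Model

A simulated female is a point process of oocyte-batch recruitments plus a
deterministic growth law per batch. Recruitment intervals and clutch
sizes are independent draws from truncated lognormal distributions
(intervals: µ = 1.21, σ = 0.57 on the log scale, truncated to [1, 25]
days; clutch sizes: µ = 4.11, σ = 0.96, truncated to [1, 317] eggs),
both fitted to spawning records of control fathead minnows in paired
spawning designs. Growth is driven solely by plasma VTG: absorbed mass
obeys dM/dt = ρ·C·V with volume affine in mass, V = w·R·M + V_Oog
(w = 0.156 mg·nmol⁻¹, the VTG molecular mass), so volume grows
exponentially at rate w·R·ρ·C while C is constant. A batch spawns all
its eggs the moment V reaches the 0.52 µL threshold; batches grow
independently, with no resource competition, atresia or energetics, and
no fertilization or hatching stage (the assay data the model targets
show those endpoints unaffected by the chemicals of interest).

Every simulation runs an 81-day start-up — 60 days of recruitment from
sexual maturation plus the assay's 21-day acclimation — before exposure
day 0; start-up times are reported as negative study days. The VTG
protocol is piecewise constant: the pre-exposure level (default
0.1 nmol·µL⁻¹, a typical control measurement) up to day 0, the measured
exposure concentration afterwards. The switch applies to all live
batches at the step time. Continuously time-varying VTG is deliberately
out of scope; compensatory VTG recovery during long exposures is the
known failure mode of the piecewise-constant assumption (it overpredicts
fecundity when plasma VTG rebounds mid-study).

## Integration and event detection

Because the dynamics are linear within each constant-concentration
segment, the primary path propagates the exact solution
V(t) = V₀·exp(w·R·ρ·C·Δt) segment by segment and solves the threshold
crossing with a logarithm — no step-size or root-finding error. A
numerical path (`solve_ivp`, default rtol 1e-3 / atol 1e-10, terminal
event on the threshold) integrates the same equations and is kept purely
as a fidelity check; the test suite requires the two paths to agree on
spawn times to relative error < 1e-6 at tight tolerances. A crossing
landing exactly on the window end counts as spawned. Spawn events are
binned to integer study days by flooring the continuous crossing time,
matching daily egg collection.

## Parameters

| name | units | default | provenance |
|---|---|---|---|
| w_vtg | mg·nmol⁻¹ | 0.156 | VTG molecular mass |
| v_threshold | µL | 0.52 | mature-oocyte volume |
| c_vtg_pre_default | nmol·µL⁻¹ | 0.1 | control plasma VTG |
| startup_days | d | 81 | 60 d maturation + 21 d acclimation |
| clutch/interval distributions | — | see above | fitted to control spawning data |
| ρ_VTG_Ooc, R_VTG, V_Oog | h⁻¹, µL·mg⁻¹, µL | calibrated | see below |

ρ, R and V_Oog have no published values in the sources this package
draws on, and the dynamics depend on them only through V_Oog and the
product R·ρ (given w). They are therefore configuration, not constants.
The shipped defaults set V_Oog to a 25-µm-diameter sphere (8.18·10⁻⁶ µL,
a plausible oogonium size; any choice is absorbed by rate calibration
and cannot change spawn timing), R_VTG = 1 µL·mg⁻¹ as a unit convention,
and ρ from `calibrate_rates`, which inverts the closed-form maturation
time t* = ln(V_threshold/V_Oog)/(w·R·ρ·C) so that t* at the control
concentration 0.1 nmol·µL⁻¹ equals the mean truncated recruitment
interval (3.99 days, computed from the interval distribution at run
time). The rationale: a control female should mature a batch in about
one recruitment interval, which is what keeps acclimated control fish
spawning steadily — the state the 21-day assay selects for. Only the
product is identifiable; the individual ρ and R defaults are reported by
`ogdm calibrate` with that caveat. The rate constant is specified per
hour and converted to the per-day simulation clock exactly once, at
parameter construction.

Under this calibration the model's throughput at saturating VTG is the
mean clutch size over the mean interval, 78.3/3.99 ≈ 19.6
eggs·female⁻¹·day⁻¹, which is what control simulations produce.

## Randomness

Samplers use rejection from the untruncated lognormal (acceptance
probability > 0.9 for both shipped distributions), so truncation bounds
hold exactly, draw by draw. Clutch draws are rounded to the nearest
integer and resampled if rounding leaves the bounds; rounding was an
open choice and round-to-nearest is the least biased. Cohort runs derive
one substream per (master seed, replicate, fish id) via `SeedSequence`
with a 31-bit hash of the fish id, so adding or removing a fish never
perturbs another fish's draws and every run is bit-reproducible from its
seed. The first batch is recruited at the window start (study day −81)
rather than after one sampled interval — configurable
(`first_recruit_at_start`); with an 81-day start-up the difference is
washed out by steady state. Recruitment continues through the whole
window with no shutdown rule.

## Metrics

Average fecundity, eggs per spawn and spawns per female are exact
quotients; eggs per spawn for a non-spawning unit is a typed
`UNDEFINED` sentinel, converted to zero only in presentation-layer
exports so downstream statistics are not polluted. Group-design binning
merges same-day spawns within a group into one event whose clutch is the
day's sum; it conserves total eggs (hence average fecundity) and can
only reduce spawn counts. The KS comparison uses the asymptotic
two-sample statistic; exact small-sample p-values are out of scope.

## Synthetic cohorts

`generate_cohort` emulates the study designs the model is evaluated
against: groups of females per treatment, control plasma VTG drawn from
a lognormal whose (µ, σ) are ML-fitted at run time to the packaged
measured control column (mean ≈ 0.086 nmol·µL⁻¹), and exposure arms as
multiplicative depressions of the control draw — the mode of action of
steroidogenesis inhibitors on plasma VTG. What the generator does not
emulate: within-tank correlation, measurement error in VTG, time-varying
VTG (compensation), or male/fertility effects. Tests passing on
synthetic cohorts therefore validate the simulator's internal
contracts — conservation, monotonicity in VTG, distributional
correctness of the samplers, calibration identities — not the field
accuracy of fecundity predictions for any particular chemical.

## Problem sizes and numerical choices

The default experiment (12 fish × 50 replicates × 21 days plus start-up)
runs in a couple of seconds; the test suite uses 10⁵-draw sampler checks
(ECDF sup-distance < 0.01), 10⁴-draw ML parameter recovery (±0.05 on µ
and σ), 100-cohort conservation sweeps and 200-replicate monotonicity
grids with common random numbers to couple concentrations exactly.
Degenerate inputs are rejected, never clamped: σ ≤ 0, inverted bounds,
non-positive volumes/rates, zero females or days, empty KS samples all
raise. Zero VTG yields an infinite maturation time (a never-spawning
fish), not an error.

## Known limitations

Piecewise-constant VTG only; single species parameterization (fathead
minnow); no population dynamics layer; per-spawn metrics inherit the
paired-design provenance of the clutch/interval fits, so group-design
comparisons should use the binned variants; the original tool's output
files are reproduced as schemas (CSV/TSV dialect fixed here), not byte
layouts.
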