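# Methods

This note documents the models behind spirobench, the defaults and their
rationale, the numerical choices, and what the simulation-based tests do and
do not demonstrate about real recordings.

## Device forward model

**Pressure path.** The device infers flow from the pressure drop across a
fixed obstruction (a pneumotachograph). We model the obstruction with the
standard orifice-plate relation ΔP = k·Q²·sign(Q); the true characteristic of
any particular obstruction is device-specific, so k is a calibration constant,
chosen per sensor such that full-scale pressure corresponds to the sensor's
maximum rated flow. Two sensors cover the physiologic range: a high-range unit
(50–900 L/min, 0–10 kPa full scale) and a low-range unit (15–100 L/min,
0–0.5 kPa). Each output is an affine voltage V = V₀ + s·ΔP with additive
Gaussian noise (default SD 1 mV), clipped to [0, 5 V] and quantised by a
10-bit ADC (step ≈ 4.9 mV) — the resolution typical of the hobbyist-class
microcontrollers such open hardware uses. Sample rate defaults to 100 Hz
(minimum 50 Hz).

The 1 mV noise default keeps the zero-flow channel inside the ADC dead band,
so an idle device integrates to ~0 volume; larger noise interacts with the
zero-clamped square-root inversion to produce a positive rectification bias at
rest, which real spirometry front-ends suppress with analog filtering that we
do not model.

**Dual-range fusion.** Each channel is inverted independently
(Q = √(max((V−V₀)/s, 0)/k); voltages below the offset clamp to zero flow since
only forced exhalation is analysed) and the two estimates are cross-faded
linearly across the 50–100 L/min overlap band, with the high-range sensor's
own estimate as the blending reference so the weight never depends on the
fused output. Below the band the low-range estimate is used verbatim, above it
the high-range estimate.

**Low-flow limitation.** Equally spaced ADC levels in voltage map to
√-compressed levels in flow, so resolution collapses near zero flow: with the
default design the smallest resolvable flow is ≈ 2.4 L/min, and rounding in
voltage under-reads flow on average (Q(V) is concave). Expiratory tails below
~5 L/min — prominent in the obstructive phenotype — are therefore partially
truncated, costing up to ~3% of FVC with the ADC engaged. This mirrors the
low-flow limitation acknowledged for the physical design. The
parameter-recovery harness consequently reports ideal-transduction (noise-free,
ADC-bypassed) recovery separately from noisy-ADC bias.

**Gas path.** Each electrochemical cell plus its potentiostat/transimpedance
readout is lumped into one linear gain (V/ppm) with a baseline voltage;
linearity of voltage in analyte concentration is the asserted behaviour of
these sensors. Defaults: NO 2.0 V/ppm, CO 0.4 V/ppm, baseline 0.6 V, noise SD
3 mV, detection floors 0.03 ppm NO and 2 ppm CO (the lower ends of the
physiologic asthma ranges 0.03–0.13 ppm NO and 2–7 ppm CO). `calibrate_gas_sensor`
refits gain and baseline by least squares and rejects fits with R² < 0.99 —
the diagnostic that would have caught a drifting or nonlinear NO cell.

## Breath simulator

**Protocol.** 60 s tidal breathing → 5 s rest → n forced maneuvers (default
3), each preceded by a 1.5 s deep inhalation; maneuvers are separated by 8 s
of recovery breathing (the protocol source does not specify inter-maneuver
behaviour; these are package choices). All segments are annotated in the
trace. Tidal breathing is a 0.25 Hz sinusoid sized for a 0.5 L tidal volume.

**Forced expiration.** Flow rises linearly to PEF over `rise_time` (default
0.1 s) then decays as Q = PEF·exp(−(t/τ)^b). Partial volumes have a closed
form via the regularised lower incomplete gamma function, so (τ, b) are solved
(bounded least squares on log parameters, shape initialised from the phenotype
preset) to deliver the requested FEV1 and FVC exactly; residuals above 0.5%
raise a parameter-infeasibility error naming the violated constraint (e.g.
FEV1 = FVC leaves no tail volume under a smooth decay sustained to 6 s).
Ground-truth metrics are evaluated from the closed form using the same
back-extrapolated time-zero convention as the analysis (t₀ = rise_time/2,
BEV = PEF·rise_time/8), so recovery tests measure the pipeline rather than a
timing-convention mismatch.

**Phenotypes and cohorts.** Group anchors (FEV1/FVC means and SDs) follow the
published baseline spirometry of the benchmark cohort: control 3.74±0.54 /
4.42±0.66 L, asthma 2.37±1.10 / 3.02±1.24 L, COPD 1.06±0.55 / 2.05±0.70 L.
PEF anchors (8.5 / 6.0 / 3.5 L/s), decay shapes (1.3 / 0.9 / 0.6 — COPD's
b < 1 gives the scooped loop) and expiratory durations (7 / 7.5 / 9 s, long
enough to satisfy the 6-s rule after time-zero correction) are simulator
choices. Subject draws are correlated lognormals with moments matched to the
anchors (positive support without truncation bias); PEF scales sublinearly
with the subject's FEV1 and is eased downward if a severely obstructed draw
cannot be realised as a smooth (b ≥ 0.25) profile. Within-subject
maneuver-to-maneuver variability is a multiplicative lognormal effort factor
(SD 2%) applied to the whole flow profile; paired "devices" carry independent
0.2% calibration jitter and independent noise.

**Gas profile.** Channel concentration approaches its true value with a 1.5 s
equilibration time constant and carries a zero-mean random linear drift
(SD 0.5%/min), motivating the analysis default of discarding the first 10 s of
the tidal window before averaging. The summary is the mean over the retained
window (end-tidal peak-picking is deliberately not the default because the
windowed mean is what the recording convention reports); NO is additionally
reported in ppb (exactly 1000 × ppm). Any gas window that starts after a
maneuver is flagged protocol-violating, since forced expiration transiently
depresses exhaled NO.

## Analysis conventions

- Zero offsets: per-channel median over the annotated rest window (fallback:
  first 2 s, with a warning). Gas inversion uses the calibrated baseline, not
  the rest median, because breath gas is present at rest.
- Volume: cumulative trapezoid (exact for piecewise-linear flow).
- Time zero: tangent at maximal flow on the volume–time curve, per the
  standard back-extrapolation method; BEV is the volume already expired at t₀.
- FEV1: volume between t₀ and t₀+1 s, linearly interpolated between samples
  (induced error < 0.5 mL at 100 Hz for physiologic flows).
- End of test: earliest sample after which every full trailing 1-s window
  gains < 0.025 L; partial trailing windows are not plateau evidence. FVC is
  the maximal cumulative expired volume (equal to the plateau volume within
  the plateau criterion; reading at plateau onset would truncate real tail
  volume). FET spans t₀ to the end of recorded expiration, with the plateau
  reported separately as the end-of-test flag.
- Grading: repeatability requires the two largest FEV1 (and FVC) values to
  agree within 0.150 L; ties pass trivially (sorted descending, elements 0 and
  1 compared). Best values take max FEV1 and max FVC independently, possibly
  from different maneuvers; the ratio comes from the maneuver with the largest
  FEV1+FVC sum. BEV < max(0.150 L, 5% FVC) and FET ≥ 6 s are labelled
  extended grading. Percent-predicted is a pluggable registry — no reference
  equations ship, because equation choice is a clinical decision.
- Agreement: maneuver i on device A pairs with maneuver i on device B;
  incomplete pairs are excluded and counted. Limits of agreement use the fixed
  1.96 multiplier (configurable), SD with n−1. The two-factor ANOVA uses
  type-II sums of squares for unbalanced cells; an effect with numerically
  zero sum of squares reports F = 0, p = 1; a single-level factor degrades to
  one-way with a warning (which also makes the F = t² reduction checkable).
  Both per-maneuver and per-subject-mean ANOVA modes exist; per-maneuver is
  the default.

## Problem sizes in the test-suite and acceptance run

Recovery sweeps use 200 simulated maneuvers (single-maneuver sessions),
grading oracles 10,000 random triplets, the ANOVA null calibration 500
replicates of the 43-subject × 3-maneuver × 2-device design, gas recovery 100
full sessions, and the paired benchmark 43 subjects with three maneuvers per
device — sizes chosen to match the emulated study design while keeping a full
run in the tens of seconds on one core.

## What the simulations do and do not show

The generator produces idealised physiology: deterministic profile families,
stationary sinusoidal tidal breathing, Gaussian sensor noise, no coughs,
glottic closures, leaks, early terminations or variable effort curvature, and
no temperature/humidity (BTPS) effects. Passing recovery and benchmark tests
therefore demonstrates that the *pipeline* is unbiased and self-consistent
under the modelled noise processes — not that a physical device meets these
tolerances on patients. The paired-device benchmark is a designed property of
the simulator defaults (matched nominal calibrations, 2% effort variability):
with those defaults the expected per-maneuver FEV1 limits-of-agreement
half-width is 1.96·√2·0.02·√E[FEV1²] ≈ 0.15 L for the three-group cohort —
i.e. of the same order as the 0.150 L repeatability bound, dominated almost
entirely by effort variability rather than by the instrument.

Known limitations: no inspiratory metrics; no real NO-sensor failure modes
(only the calibration diagnostics that would expose them); the obstruction
coefficient k and all gas gains are synthetic constants, not measurements of
any physical unit.
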