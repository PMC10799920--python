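# Methods

## Scope and model structure

`tmesense` models bulk batch cultures of engineered EcN biosensor strains in
a well-mixed plate well. Three sensing promoters map environmental channels
to transcriptional activity through Hill input functions:

| promoter | channel | mode | default half-max | default Hill n |
|----------|---------|------|------------------|----------------|
| pLldR | lactate (mM) | activating | 2 mM | 1.5 |
| pCadC | [H⁺] = 10^(−pH) (M) | activating | 10⁻⁶ M (pH 6) | 1 |
| pPepT | O₂ (% v/v) | repressing | 0.5 % | 2 |

The pPepT half-max of 0.5% O₂ encodes the reported triggering of this
promoter when oxygen falls below roughly half a percent; the pLldR half-max
sits inside the 0–10 mM characterization grid; the pCadC half-max centers
the 5.3–7.3 pH characterization range. The mild pLldR cooperativity (n=1.5)
is a model-shape choice that keeps the 0.1 mM response small relative to
the 1 mM response, as the characterization data show; pCadC is modeled
non-cooperative and pPepT with n=2 (sharp hypoxia transition).

The culture state is (N_u, N_f, R, E, D): unflipped/flipped live densities,
per-cell reporter and lysis protein, debris. Equations are in the README.
Key structural assumptions:

- **Quasi-steady-state integrase.** TP901 turns over fast relative to
  population dynamics, so the per-cell flip propensity is
  k_flip·A(u)·φ/γ_I. Flipping is irreversible (terminator inversion), which
  gives the switch its memory: the flipped fraction is non-decreasing under
  constant induction with lysis off.
- **Growth-coupled gene expression.** All synthesis terms carry the nutrient
  factor φ = max(1 − B/K, 0), where B = N_u + N_f + D is total biomass.
  This is the standard coupling of transcription/translation capacity to
  growth in batch culture: expression stops as the culture enters stationary
  phase. It is what produces the observed rise-peak-decay shape of the
  OD-normalized fluorescence — without it the SWITCH readout would be
  monotone non-decreasing and neither a ~20 h peak nor a finite persistence
  time could exist.
- **Debris occupies capacity.** Lysed biomass enters a debris pool D that
  still holds carrying capacity (the spent resources are not returned) and
  decays slowly (γ_D = 0.02 /h, a fixed structural constant). Debris also
  scatters light with weight c_D < 1 per unit biomass. This single
  mechanism yields the three qualitative lysis signatures at once: lower
  OD600 under induction, lower OD-normalized fluorescence (the denominator
  counts debris while only live flipped cells fluoresce), and a
  dilution–death feedback loop that admits damped population oscillations.
  The oscillatory regime requires growth fast relative to lysis-protein
  turnover with a sharp death response (e.g. r ≈ 0.8 /h, γ_E ≈ 0.8 /h,
  h = 4); the shipped calibration, whose growth rate is pinned by the slow
  ~18 h fluorescence peak, is overdamped.
- **Death acts on all live cells.** φX174E sits on the sensing plasmid, so
  δ(E) applies equally to N_u and N_f; death is a Hill function of the
  per-cell lysis protein with δ(0) = 0 and δ < δ_max always.
- **Consortia couple only through capacity.** Members share one K; each
  strain's crowding term sums live cells and debris of every member. No
  cross-feeding or signal depletion. A consortium of one is identical to a
  single-strain simulation, and symmetric members keep exactly equal shares.

Units: time in hours, rates per hour, densities in culture units with
carrying capacity 1 (one density unit ≡ 1.0 OD600), fluorescence in the
A.U. of the OD-normalized readout. The inoculum is 0.1 density units,
matching the OD 0.1 dilution of the characterization protocol.

## Measurement model

OD600 = c_cells·(N_u+N_f) + c_D·D. Total fluorescence is a flat instrument
background plus fluor_scale·R·(reporting cells); the normalized readout is
(total − background)/OD600. Only live cells carry measurable reporter —
reporter released by lysis is assumed lost/unfolded, one consistent choice
where the data do not constrain it; the denominator effect of debris is
what encodes the dimmer lysis strains. For DIRECT strains the population
cancels algebraically and the readout is purely per-cell.

## Calibration of the shipped defaults

The shipped parameter file is produced by `scripts/calibrate_defaults.py`
from ten anchors (`tmesense/data/anchors.csv`): the 70 → 120 A.U. end-point
pair of the lactate sensor at 10 mM, the 1.9× and 2.8× switch
amplifications of the acid and hypoxia sensors, the 25 A.U. (1 mM) /
18 A.U. (10 mM) non-monotone lysis dose-response, the ~20 h peak, the 132 h
persistence of the lactate and acid sensors, and the 0.5% O₂ half
activation. Absolute fluorescence anchors carry 10% relative tolerance
(two-significant-figure values), time anchors 25% ("approximately"-grade),
and residuals are weighted by tolerance×target, so the loss is the sum of
squared tolerance-normalized misfits. Optimization is bounded least squares
on log-scaled parameters (rate constants span orders of magnitude),
multi-start where the loss surface warrants it.

Two readouts — peak time and persistence time — are quantized on the 0.5 h
output grid and therefore give a gradient-based fitter no signal. The
procedure handles them explicitly: a coarse scan pins the growth rate on the
peak-time anchor first; the detection threshold is then set to the trace
level at the anchored persistence time (the data do not define "detectable",
so the threshold is an explicit calibrated parameter, 0.83 A.U. in the
shipped file); a final joint `fit_parameters` polish over the full anchor
set produces the shipped values. All ten anchors end within tolerance
(continuous anchors to ~10⁻¹⁰ relative; peak time 18 h vs the ~20 h target).

Physical bounds matter: unconstrained, the lysis fit reproduces 25/18 A.U.
with a debris OD weight of ~15 (debris scattering 15× more than intact
cells), which would make lysis cultures *denser* than non-lysing ones.
The shipped fit constrains c_D ∈ (0.05, 0.9), landing at 0.39.

With ~10 anchors and ~30 parameters most parameters are only jointly
constrained; identifiability is reported, not assumed (below).

## Synthetic plate data

`tmesense.synthetic` emulates the characterization design: strains ×
conditions (lactate {0, 0.1, 1, 5, 10} mM; pH {5.3, 5.8, 6.3, 7.3}; O₂
{0, 20}%) × 3 biological replicates × read times, plus untransformed-host
background wells modeled as a zero-gain strain (background signal at normal
growth OD). Noise is multiplicative lognormal on the circuit fluorescence
(default CV 10%), additive Gaussian on OD600 (default sd 0.01) and on the
instrument background (default sd 2 A.U.) — a stipulated plate-reader error
structure, configurable because replicate-level data to estimate it from
are not available. Processing mirrors the standard workflow: subtract the
condition-matched background-well mean, floor at zero, divide by the well's
OD600, average replicates (mean ± s.e.m.). With noise off, generate →
process returns the simulator's normalized fluorescence to machine
precision.

What the generator does *not* emulate: well-position/edge effects,
evaporation, growth-phase-dependent autofluorescence, pipetting covariance
between replicates, or instrument drift. Passing recovery tests therefore
show the estimation machinery is correct and the design informative under
idealized noise — not that real plates would be as kind.

## Parameter recovery

`parameter_recovery_experiment` runs generate → fit → compare over seeded
independent datasets, starting each fit from a log-normally perturbed
parameter vector. The default free set (pLldR direct gain, pLldR half-max,
strong-promoter activity α_P7) is recovered on a two-topology plate
(`recovery_design`); a single-topology plate leaves α_P7 invisible and the
span×gain product degenerate, which is exactly the kind of structural
non-identifiability the report is meant to expose. Parameters whose median
relative error exceeds 50% are flagged non-identifiable rather than
silently accepted. Noiseless recovery is exact to optimizer tolerance
(~10⁻¹⁰ median relative error); at 10% CV with triplicates the per-parameter
error distribution is reported.

## Numerical choices

- LSODA (stiff-capable) with rtol 10⁻⁸ / atol 10⁻¹⁰; halving tolerances
  moves observables by < 10⁻⁴ relative.
- Environment schedules are piecewise-constant (batch medium replacement);
  integration restarts at each breakpoint so discontinuities never cross a
  solver step.
- Output grid 0.5 h by default; summaries (peak, persistence) are evaluated
  exactly on the grid, no interpolation. Persistence is the last grid time
  at or above the detection threshold, 0 if never reached.
- Solver round-off below zero is clipped at 0; genuine negative states
  (beyond 10⁻⁹) are rejected as invariant violations.
- Hill functions are evaluated on the log-ratio scale, so extreme signals
  or exponents neither overflow nor lose the [basal, basal+span] bounds.
- Simulation problem sizes throughout (150–300 h horizons, 5-point dose
  grids, 2–3 recovery datasets) are chosen so the full pipeline runs in
  seconds on a laptop while leaving the reported quantities
  grid-converged.

## Known limitations

- The concrete ODE structure (growth-coupled expression, capacity-occupying
  debris) is this package's own resolution of a model family described only
  qualitatively; alternative structures (e.g. reporter carried by debris,
  resource-explicit growth) could fit the same anchors.
- Lysis released-payload kinetics, plasmid loss, quorum effects, spatial
  structure and single-cell stochasticity are out of scope.
- The 48 h end-point read time is taken from the dose-response
  characterization; an alternative 16–20 h overnight read appears in the
  protocol notes and would require recalibration.
- Anchors constrain only a low-dimensional combination of the full
  parameter vector; the shipped defaults are one well-fitting point, not a
  unique estimate.
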