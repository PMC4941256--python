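# Methods

## The population model

`cycleflux` describes a proliferating cell population as densities
n_p,g(a, t) of live cells of cell-cycle phase p ∈ {G1, S, G2M} and division
generation g at age a (time since entering the phase).  Cells transit
G1 → S → G2M; completing G2M they divide, and both daughters enter G1 of
generation g + 1 at age 0.  Generations 0–5 are tracked explicitly; the
last compartment is lumped and self-renewing (its divisions stay inside
it), matching time-lapse experiments that resolve at most four divisions
over 96 h.

Phase transit times are gamma distributed, parameterized by the mean
duration T̄_p (hours) and coefficient of variation CV_p.  The gamma family
was chosen because it has strictly positive support, is closed under the
(mean, CV) parameterization the model is specified in, and its survival
function gives a closed-form discrete hazard on the age grid.  Cell-line
defaults (BxPC-3: 9/8/4.5 h, Capan-1: 12/9/5 h, CVs 0.25/0.15/0.25) are
nominal, documented values giving mean cycle times of 21.5 h and 26 h;
they are the ground truth of the synthetic-data generator, not published
estimates.

### Drug perturbations

A treatment is a set of typed modules, each acting on one phase and a set
of generations, with an activation profile in time (measured from the
start of that drug's exposure interval):

* **delay** (and its S-phase alias **synthesis_inhibition**): fractional
  slow-down d ∈ [0, 1] of transit speed; simultaneous delays compose
  multiplicatively on speed.  A delay of 0.88 in S means DNA is
  synthesized at 12% of the normal rate.  The alternative reading of a
  "delay" — a fraction of cells delayed — was rejected because the printed
  S-phase delay magnitudes coincide with the stated percentage reductions
  of the DNA synthesis rate.
* **block**: probability p that a cohort arriving at the checkpoint at the
  end of the phase is arrested into a blocked pool (counted in its phase
  of arrest in FC read-outs); the rest pass.
* **recycle**: first-order rate (per hour) at which a blocked pool resumes
  cycling; cells arrested at the G1 checkpoint resume at S entry, S at G2M
  entry, G2M at division.
* **death**: first-order per-hour removal.  Death acts on both in-transit
  and blocked cells of its (phase, generation); removed cells leave the
  live pool immediately and appear in no observable.  Commitment windows
  ("cells still in generation 0 at 48 h die") are expressed as step-window
  profiles on death modules.

Profiles are `constant`, `step_window` (on/off at given hours) and
logistic `sigmoid` (value ½ at `half_max`, rising 10%→90% over `rise`
hours, default 6 h; a falling variant models recovery).  The gemcitabine
synthesis recovery is a single falling sigmoid with half-maximum at 18 h
composed with a constant long-term residual delay; at the low dose this
puts the synthesis rate at 56% of normal at 18 h, i.e. "about half", and
the recovery timing is dose-independent by construction.  A module's
`window` gates it to the exposure interval (`during`), the washout period
(`post`, as in fitting exposure and washout separately), or both
(`always`, used for drugs like gemcitabine whose effects persist after a
6 h pulse).

When two drugs in a sequence drive the same (effect, phase, generation)
simultaneously, the later-starting drug's module supersedes the earlier
one's from its own start; all other after-effects of the first drug
persist through the gap.  This is configurable (`overlap_policy`).

## Numerics

Transport is solved on an age grid (default bin 0.5 h, dt equal to the
bin).  Within a (phase, generation) compartment the transit speed is
uniform, so a delay is an exact reparameterization of the compartment's
age clock: each step the compartment accrues `speed × dt` of effective
age; one whole accumulated bin triggers an upwind advance of the age
distribution.  Exits accrue continuously — over a step traversing a
fraction c of a bin, the per-bin survival (1 − h_a) is raised to the
power c — so a full traversal reproduces the discrete gamma hazard
exactly and the trajectory is smooth in the delay magnitudes.  The scheme
is positivity-preserving by construction and exact (to rounding) for the
unperturbed population.

Discretization error is O(age_bin): cells entering a slowed compartment
mid-cycle gain up to one bin of effective age, which compounds across
generations.  Measured against the stochastic oracle on the hardest
shipped configuration (gemcitabine, 88% synthesis inhibition), the
largest FC-percentage bias is ≈0.6 points at 0.5 h bins, halving with
each bin refinement; engine-vs-oracle equivalence checks therefore run at
1/16 h bins, where residual bias is below the Monte-Carlo noise of a
10⁴-cell experiment.

The initial condition is balanced exponential growth: the closed-form
stable distribution of the continuous-time model (Euler–Lotka root of
2·E[e^(−λTc)] = 1, survival-weighted exponential age profile) refined by
power iteration with the engine's own unperturbed step, so a control
simulation grows at a constant rate from t = 0 with no transient (checked
to 1% over 96 h; in practice ~10⁻¹⁰ relative).  Near-deterministic
cycles (all CVs ≲ 0.03) mix slowly; the iteration accepts a residual
distribution oscillation below 10⁻⁶ with a warning.

### The stochastic microsimulator

`microsimulate` is an independent brute-force implementation: every cell
draws its gamma transit times, advances its own progress at the
delay-scaled speed, takes Bernoulli checkpoint decisions on arrival,
waits exponentially in blocked pools and dies at the active death hazard.
It shares only the perturbation rate tables with the deterministic
engine, and serves as the oracle in the equivalence tests.

## Observables

Three read-outs are computed from the live population only (dead cells
are assumed debris-gated out of FC and invisible to live-cell TL counts):
flow-cytometric %G1/%S/%G2M pooled over generations with blocked cells
counted in their phase of arrest; time-lapse cell counts per generation
(including cells that will later die); and the absolute live cell number.
They are consistent decompositions of one population at every time.

## Synthetic data

The generator reproduces the study's replicate structure: per FC time
point, 3 independent replicates of the percentage triple with additive
Gaussian noise (SD 2.5 points), clipped at 0 and renormalized to 100; per
TL time point, 5 wells with lognormal multiplicative noise (CV 8%) per
generation count; cell-count triplicates (CV 5%); and SRB dose-response
grids with 8 replicate plates (two experiments of four) with lognormal
noise (CV 7%) on the surviving fraction.  FC is sampled every 24 h and TL
every 6 h over 0–96 h.  Noise magnitudes are nominal values matched to
the scatter such experiments typically show; they are the fixed study
conditions of every simulation experiment in the test suite.  What the
generator does not emulate: DNA-histogram shape (only the deconvolved
percentages), TL lineage-tracking errors, well-to-well growth drifts, or
dead-cell debris.  Passing recovery tests therefore demonstrate that the
estimation machinery inverts the model under the stated noise, not that
the model is identifiable from any particular laboratory's raw data.

## Fitting

The objective is a weighted SSE over replicate means: FC residuals in
percentage points, TL/count residuals on log counts (floored at half a
cell, which deliberately breaks unit invariance only for sub-cell
counts), each divided by its replicate SD.  Because a 3–5-replicate SD is
a very noisy weight, variances are moderated toward the pooled per-stream
variance, sd² ← (sd²_raw + sd²_pooled)/2, floored at 0.3·sd_pooled — the
usual stabilization for weighted least squares with few replicates; with
raw per-observation SDs the nested-model F-test runs anti-conservative
(type-I ≈ 0.12 rather than 0.05 in the null calibration).

Estimation is multi-start Nelder–Mead: Latin-hypercube starts within the
bounds plus the skeleton's current values, each refined locally with an
explicit initial simplex (5% of the box per coordinate; the default
simplex degenerates for parameters starting at 0).  Derivative-free local
search was chosen because the simulator's advance events make the
objective piecewise smooth rather than differentiable.  Parameters shared
across generations are expressed either as one module spanning several
generations or as one `ParameterSpec` tying several module magnitudes.
Parameters whose activation window contains no observation are fixed
automatically with a warning.

Uncertainty intervals are a residual bootstrap: standardized residuals of
the best fit are resampled within each stream, added back to the fitted
curves, and the model is refit locally; 2.5–97.5 percentiles of the
bootstrap draws are reported.  This stands in for the original study's
uncertainty analysis, whose details are not available to this package; it
is a defensible generic choice, not a reimplementation.

Nested variants are compared with an F-test on the weighted SSE,
F = ((SSE_r − SSE_f)/Δk)/(SSE_f/(n − k_f)), α = 0.05.  The null
calibration in the acceptance suite uses an interior null (a delay shared
between generations versus generation-specific delays); for an extra
module whose null magnitude sits on the boundary of its range the test is
conservative, which is the standard boundary caveat.

## Sequential combinations

A two-drug sequence is simulated as one run with both models and the
sequence schedule; the full population state (age densities, blocked
pools, generation structure) carries across the switch by construction,
and each model's profiles run on its own exposure clock.  The
no-interaction expectation uses the unmodified single-drug models;
interaction is quantified by freeing a chosen subset of the second
drug's parameters, refitting against combination data, and flagging a
parameter as changed when its bootstrap interval is disjoint from the
single-treatment interval.

## Isobologram analysis

Factorial SRB grids are analyzed per ray: a constrained four-parameter
logistic (bottom ≥ 0, top ≤ 1, slope > 0, lmfit) is fitted for drug A at
each fixed dose of drug B and vice versa, inverted at the 30% and 50%
inhibition levels to give iso-effective pairs (rays whose fixed dose
alone already exceeds the level are excluded; inversions beyond the
tested range are flagged as extrapolations), and each pair is scored with
the Loewe Combination Index CI = a/ICx_A + b/ICx_B.  CI uncertainty comes
from a bootstrap over replicate plates.  Bliss independence and
median-effect variants are deliberately out of scope.

## Problem sizes used by the tests and the acceptance script

Engine-vs-oracle equivalence: 10 (suite) / 4 (script) randomized
scenarios at 10⁴ cells (8 × 1250-cell replicate sub-runs), 1/16 h bins.
Parameter recovery: three seeded noise replicates per target at the
default design (570 observations), 8 optimizer starts, median reported.
F-test calibration: 200 (suite) / 100 (script) null simulations and
12–15 low-noise power simulations on a 72 h, 1 h-bin configuration.
Null-interaction control: 20 (suite) / 10 (script) seeded replicates with
10-draw bootstraps.  These sizes keep the full suite and the script each
within a few minutes on a single core while leaving Monte-Carlo error
well inside the decision margins.

## Known limitations

* Discretization bias O(age_bin) under strong slow-down (quantified
  above); halve the bin when absolute per-generation timing matters.
* Advance events make trajectories piecewise smooth in delay magnitudes;
  gradients across an event boundary are undefined (hence derivative-free
  optimization).
* Divisions inside the lumped last generation do not preserve the
  founding-lineage weight (they are self-renewing by design).
* Concentration is a label selecting a parameter set; there is no
  pharmacokinetics, spatial structure, cell-size or molecular state.
* The residual bootstrap assumes exchangeable standardized residuals
  within a stream; with very few time points its intervals are rough.
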