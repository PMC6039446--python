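# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `filtergate`, in the package's own words.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Permeation models

A permeation model is a strongly connected directed graph over ion
configurations of the selectivity filter, with every reaction represented
by a forward/backward edge pair and a designated transport cycle whose
forward traversal moves exactly one elementary charge outward.  Three
specs ship as JSON documents:

* `five_state_roux` — the five-state hopping cycle: internal uptake
  (1→2, rate k₁₂,₁·a_in), concerted translocation (2↔3, Eyring group 23),
  release of the outermost ion to the outer mouth (3→4), unbinding to the
  external bath (4→5, rebinding k₅₄,₁·a_out), and a second translocation
  resetting the filter (5↔1, Eyring group 51).  State 3 is the only
  three-ion configuration with S0 occupied; state 4 differs from it only
  by that ion sitting in the outer mouth.
* `four_state` — the same cycle with the outer-mouth state removed:
  release 3→5 is direct and rebinding 5→3 is proportional to external
  activity.
* `hard_knock_on` — a five-state cycle for direct (water-free) knock-on
  with voltage on the two concerted translocation steps.  The edge-by-edge
  assignment is an explicitly approximate reading of the published scheme
  (the original supplementary equations are not available) and lives in
  the JSON spec, not in code, so it can be revised without a release.

Rate laws: `plain` edges are constants; `bind_internal`/`bind_external`
edges scale with the K⁺ activity of the respective bath (mM); `eyring`
edges carry exp(s·V/V_char) forward and exp(−(1−s)V/V_char) backward with
a shared barrier position s ∈ [0,1] and characteristic voltage V_char
(mV per e-fold).  The backward form is the standard single-barrier choice;
only the forward form is conventionally quoted, and fitting one (s,
V_char) pair per group presumes exactly this complementary split.
Voltage drops only across the Eyring steps — the filter is assumed to
carry ~80 % of the field, so voltage dependence of the peripheral steps is
neglected.

Activities use a built-in table of KCl mean activity coefficients at 25 °C
(standard literature values, molality/molarity conflated at this
precision), interpolated linearly in ln c between nodes and extended below
the lowest node by the Debye–Hückel limiting-law shape so γ→1 as c→0.
The table is configurable; the shipped values are a documented stand-in
for the exact coefficients used in any particular laboratory.

## Steady state, current, and the King–Altman oracle

The stationary distribution solves P·Q = 0 with sum(P) = 1 by
Grassmann–Taksar–Heyman state elimination (batched over conditions): a
direct dense solve of the stationarity system that uses only additions,
multiplications and divisions of non-negative rates.  Avoiding
subtractive cancellation keeps every component of P accurate in a
*relative* sense even when occupancies span many decades, where an LU
solve of the normalised system loses the small components.  The classical
King–Altman spanning-tree expansion (Dₘ = Σ over trees directed toward m
of rate products; Pₘ = Dₘ/ΣD) is implemented by exhaustive enumeration,
deliberately restricted to ≤ 8 states, and serves purely as an independent
test oracle; for a pure five-cycle the enumeration yields 25 tree products
of 4 rate constants each.  The open-channel current is e times the net
stationary flux through any transport-cycle edge (identical on all of
them), reported in pA with outward positive.  At 16 pA one transport
cycle takes e/I = 10 ns.

## Thermodynamic consistency (Nernst constraint)

Electrode drift is corrected against the Nernst potential in the
experimental workflow, so the model must reverse exactly at E_K.  For a
pure cycle this requires (a) the products of forward and backward base
rates around the cycle to balance at 0 mV — one backward rate (k₂₁ in the
shipped specs) is eliminated in favour of the others — and (b)
Σ_groups 1/V_char = F/RT, so the full cycle carries one charge across the
whole field.  Both are enforced structurally in the fit parameterisation
(the eliminated rate is recomputed every evaluation; the inverse
characteristic voltages are a softmax split of F/RT), so every candidate
parameter vector is consistent by construction.  With the flag off, all
backward rates and characteristic voltages are free and any reversal
offset is simply reported, never hidden.  The constraint assumes the cycle
takes up exactly one ion internally and releases one externally; model
specs violating that stoichiometry are rejected at constraint time.

## Gating links and the Kmf collapse

The closing rate is k_OM = w·Pₘ (conformational coupling), w/Pₘ
(occupancy-stiffened open state), or w·P₄/P₃, with w > 0 a single scale
independent of voltage and concentration.  The opening rate k_MO is
carried through the data model but never linked to occupancies.

The collapse diagnostic interpolates each internal-concentration series'
predicted k_OM onto a common abscissa grid (33 points across the shared
range) and reports the mean coefficient of variation across series — once
against raw voltage and once against Kmf = V − E_K.  The empirical
saturating form

  P₄/P₃ ≈ c₂ / (c₁·exp(q₁·Kmf/V_T) + exp(q₂·Kmf/V_T))

is fitted to the pooled ratio points by least squares in log space, with
q₁, q₂ free scalings (different reactions feel different fractions of the
field).  The form is treated as an empirical four-parameter description,
not re-derived; the testable content is the collapse itself, which the
score quantifies model-free.

## Global fit

Objective: unit-weight squared residuals in pA for the IV curves plus
squared residuals of ln k_OM at negative voltages (fitting the logarithm
gives the two data types about equal weight; per-point σ-weighting is
deliberately not applied, and both weights are configurable).  The k_OM
mask defaults to V < 0 because the closing rate at positive voltages is
dominated by a different (inner-gate) process outside this model's scope.
The fitted current column is the effective current I_OF (which absorbs
averaging over the even-faster O–F gate); a config switch allows fitting
I_true instead.

Optimisation: Nelder–Mead over unconstrained transforms (ln base rates,
logit s, softmax V_char split, ln w), multi-start with log-normal
perturbations of the initial guess (sd 0.5 decades, 20 restarts by
default, seeded), followed by a Levenberg–Marquardt polish of the top
candidates on the residual vector.  The polish is an engineering addition:
the simplex reliably finds the basin but stalls short of the optimum at
machine precision, which matters for noise-free recovery checks.  The
gating scale w is initialised in closed form from the log-mean mismatch of
the masked rate data.  Objective evaluations are deterministic
(bit-identical for identical inputs); per-curve residual breakdowns always
sum to the reported error.

Model comparison fits every candidate link independently (its restart seed
derived from the link label and the config seed, so duplicate entries
reproduce) and tabulates best error sums; per-link failures are recorded
without aborting the table.

## Fast-gating simulation and histogram fitting

Event simulation draws, per gating event, the sink state (probability
proportional to branch rates) and the exponential dwell; the star topology
lets whole O/closed event sequences be drawn vectorised.  The start state
is drawn from the scheme's stationary distribution; a closed state with no
return path is absorbing and is flagged.

Rendering lays the two-level current (I_true in O, 0 pA closed) on an
internal fine grid (default 1 µs; event boundaries placed by rounding
cumulative times so long-run timing is unbiased), filters with a digital
4-pole Bessel low-pass designed by bilinear transform with cutoff
prewarping, magnitude-normalised so the configured cutoff is the −3 dB
point and rescaled to exact unit DC gain, then decimates to the sampling
rate (defaults: 1 kHz cutoff, 5 kHz sampling).  The renderer refuses
schemes whose shortest expected dwell spans fewer than 5 fine-grid steps —
microsecond O–F dwells require a sub-microsecond grid, which is a config
choice, not a code change.  No bit-compatibility with any legacy analysis
program is claimed.

Amplitude histograms of the noise-free samples are convolved with a
Gaussian kernel of the baseline sd on the bin grid (default bin width
sd/2, range padded by 5 sd, total count preserved; an under-resolved
kernel warns).  I_app is the mean of the 10-point block-averaged trace;
fixtures for the averaging checks exclude slow (S) events by construction,
so the analytic forms I_OF = I_true·k_FO/(k_OF+k_FO) and I_app = I_true·p_O
(p_O from the O/M/F subsystem) apply; these stationary-averaging forms are
this package's derivation, validated against long-trace Monte-Carlo
averages within Monte-Carlo error.

The histogram fit minimises the per-bin squared deviation between
count-normalised histograms (χ²-style weighting available by config) by
Nelder–Mead over log-rates and I_true.  The objective is stochastic, and
three measures make it tractable:

* **Smooth common random numbers.**  Each fit fixes one seed; the event
  simulator draws dwell times as standard exponentials scaled by the
  current rates and sink choices as fixed uniforms cut by the branch
  probabilities, from per-role child streams.  The simulated trace then
  varies smoothly with the parameters, so the simplex descends a smooth
  surface instead of re-drawn jitter.
* **Basin screening.**  The (I_true, k_OM, k_MO) landscape has local
  basins in which a wrong true current with compensating averaging
  reproduces the apparent level.  A coarse grid of I_true multipliers ×
  k_MO scalings (with the open-state duty derived from the histogram mean
  via I_app = I_true·p_O) is screened first, and the simplex runs from
  the best-ranked starts (up to 3).
* **Two-stage durations.**  The working objective simulates 5 s of model
  time per evaluation; each candidate result is then refined at 3× that
  duration, where competing basins separate from the simulation noise
  (experimental records are minutes long, so the refined regime is the
  faithful one).  A result is accepted when its refined error is within
  2.5× the reproducibility floor — the squared histogram distance between
  two independent simulations of the same scheme at the refined duration,
  measured and reported with every fit — and fresh random streams are
  tried when the search stalls far (20×) above it.

Parameters whose two-fold perturbation moves the objective by less than
twice the floor are flagged non-identifiable (e.g. I_true in an
all-closed record).  The bin width, trace lengths, rendering-grid step for
sub-millisecond (O–M only) fixtures (2 µs: ≥ 25 steps per mean dwell),
and stopping/acceptance thresholds are engineering defaults, chosen for
the accuracy/runtime trade-off documented in the recovery tests.

## Drift correction and averaging

The apparent reversal of an I_OF(V) curve is the real root (nearest E_K,
with a warning when several fall in range) of a cubic polynomial fitted to
the 8 points around the sign change; all of the condition's curves are
shifted so that root lands on E_K, and the detected offset is reported.
Replicates on differing voltage grids are interpolated with not-a-knot
cubic splines onto the union grid restricted to the overlap before
pointwise mean/sd; not-a-knot end conditions reproduce cubic polynomials
exactly, which the tests exploit as an oracle.

## Synthetic study

The default design mirrors the experimental layout: symmetric KCl at
50/100/250/500/1000/1500 mM, internal-varied 50/250/500/750/1000/1500 mM
against 100 mM external, and the mirror-image external-varied set — 18
series on the 17-point grid −160…+160 mV (20 mV steps), 3 replicates,
multiplicative log-normal noise on rate constants (CV 15 % default,
capped at 25 %) and additive Gaussian noise on currents (0.5 pA default,
capped at 1 pA), matching the reported replicate error-bar scale.  75 mM
appears nowhere in the default design; the published panel colour-coding
leaves its placement ambiguous, and omitting it keeps the symmetric and
varied sets the same size.

The ground truth (five-state model, k_OM = w·P₄/P₃, w = 3×10⁴ s⁻¹, base
rates ~10⁸ s⁻¹ with binding coefficients 2×10⁶ s⁻¹mM⁻¹, barriers s₂₃ = 0.20,
V₂₃ = 90 mV, s₅₁ = 0.72, V₅₁ fixed by the one-charge budget) was chosen
once, by screening random parameter draws purely for the qualitative
phenomenology the study conditions demand: near-linear symmetric IV around
100 mM reaching a few to ~15 pA, conductance rising with concentration and
saturating near 1 M, an exponential rise of k_OM toward negative voltages,
a left shift of that rise with internal K⁺ that collapses on Kmf, and
insensitivity to external K⁺ at negative voltages.  It is synthetic and is
presented as such, never as a fitted experimental parameter set.  The
synthetic effective current is I_OF = duty·I_cycle with the duty factor
defaulting to the stationary O–F form k_FO/(k_OF+k_FO) = 0.971
(voltage-independent by default; a slope is configurable).  A constant
duty factor means the noise-free global-fit optimum lies exactly on the
truth ray scaled by 0.971 with w unchanged — a systematic 2.9 % offset
that the recovery tests account for.  The synthetic k_MO is a smooth
phenomenological curve (1.2×10⁴·exp(V/300 mV)); it is never fitted.

What passing tests do and do not show: the synthetic study has exactly the
generating model inside the candidate set, homoscedastic noise of known
form, no slow-gating contamination, no baseline drift within a recording,
and activities from the same table used in fitting.  Recovery and
model-selection results therefore demonstrate correctness and statistical
power of the machinery under the stated conditions — not that real
recordings of any particular channel identify the same link.

## Problem sizes and determinism

Default problem sizes used by the test suite and acceptance script: 100+
random instances for the oracle equivalence; the full 18-condition design
(306 conditions) for every global fit; 5 restarts per link and 10 noisy
repetitions for the 11-link comparison; 20-second targets and 5-second
fit simulations for 10–20 histogram fixtures.  All randomness flows from
explicit seeds; datasets, traces and fits are bit-reproducible given the
same library versions.

## Known limitations

* The hard-knock-on spec is a best-effort topology; its error sums are
  meaningful for machinery tests, not as a verdict on the published model.
* No uncertainty quantification (profile likelihood, bootstrap) on fitted
  parameters; the comparison table ranks point fits only.
* Slow (O–S) gating is simulable but excluded from the averaging
  identities and never analysed by dwell times.
* The collapse-form fit is empirical; its parameters have no direct
  mechanistic reading.
* Linear-solve conditioning degrades for rate ratios far beyond the
  10⁶–10⁹ s⁻¹ regime exercised here; the oracle tests cover that regime
  only.
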