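# Methods

## Discrete trial-level model

One scalar CNS response component is modelled per simulator instance
(multi-component responses are handled by running independent instances,
one α each; the decomposition is linear by the superposition assumption,
so no cross-component coupling is modelled).  The carried learner state is
the pair (i_R, expected): the reactive response and the predicted
outcome.  That these must be *two* quantities is the content of the
stability theorem demonstrated numerically by
`single_quantity_variant` — collapsing them makes the outcome grow as
n·x, without bound.

Per open trial (active or placebo):

    y = x + i_R + gamma + baseline_shift + misattributed
    e = y - expected
    i_R <- i_R + alpha * e * f        (f = precision_factor if the trial
                                       is error-blocked, else 1)
    expected <- y

Trial kinds:

- **hidden** — the administration is not perceived: y = x +
  baseline_shift, no error is computed (reported as NaN) and neither i_R
  nor the expectation updates.
- **virtual** — an outcome simulation: the cognitively inferred outcome
  plays the role of the experienced one.  The stored expectation is also
  updated to the simulated outcome; the model treats a virtual trial as a
  full administration trial in every respect except that nothing is
  ingested.  (The alternative — leaving the expectation untouched —
  would make repeated identical suggestions accumulate i_R without
  bound, which contradicts the stability property.)
- **error-blocked** — the prediction-error signal is attenuated by the
  `precision_factor` in [0, 1] (a single scalar standing for a
  pharmacological degradation of error precision).  The attenuation is
  applied only on trials flagged `error_blocked`: the blocking agent is
  co-administered on specific trials of a protocol, not a property of
  the subject.  The recorded `e` column is always the raw observable
  error; attenuation affects only the i_R update.

Misattribution enters the experienced outcome (and hence the error)
additively and never contaminates x.  A *resistant* misattributed
response corresponds to the self-consistent state expected = y, in which
no further error is computed; users construct it by setting the initial
state accordingly.

Edge cases: α = 0 disables learning (y_n = x_n); α = 1 uses the limit
forms (y_n = n·x) in the closed-form helpers; |α| ≥ 1 is accepted by the
simulator but flagged with an `InstabilityWarning` (and is a hard error
for the asymptote/extinction closed forms, which do not exist there).

Records store i_R *after* the trial's update; the closed-form helper
returns the value elicited *during* trial n (the two differ by one
update step, y_n − x vs y_{n+1} − x).

## Resistant-to-extinction accumulation

A cycle = n_active open active trials followed by n_blocked_placebo
placebo trials under error blocking.  During blocked placebo trials the
expectation keeps tracking the experienced outcome while i_R stays put,
so the reactive floor i_R0 left at the end of a cycle survives; the next
acquisition run rides on top of it.  With perfect blocking
(precision_factor = 0) and enough active trials per cycle to reach the
asymptote, each cycle adds x·α/(1 − α) to i_R0 — the accumulation used
here runs 60 active trials per cycle, which for |α| ≤ 0.5 puts the
per-cycle truncation error far below 1e−12.  With intact error
computation (factor 1) the placebo block is ordinary extinction and
i_R0 → 0.

## Continuous-time model

The continuous model is implemented as the discrete recursion run per
time bin on a fine grid, which is also how it is simulated in practice:
a trial window of duration T0 minutes is sampled at T_sample ≤ τ/20
(enforced), giving N = round(T0/T_sample) bins.

Within a trial, the reactive output is the first-order low-pass of the
per-bin reactive memory r(b) with time constant τ (zero state at trial
onset — the reaction builds up from the moment the administration is
perceived), so y(t) = x(t) + smooth_τ(r)(t).  The filter is the exact
zero-order-hold discretization of an R-C stage in strictly causal form
(out[k] = a·out[k−1] + (1−a)·in[k−1], a = e^(−Δt/τ)): unit DC gain, and
a unit step reaches 1 − e^(−t/τ) exactly on the grid.

Across trials, each bin runs the discrete update r(b) ← r(b) + α·e(b)
with e(b) = y(b) − ŷ(b).  The expectation ŷ combines two sources,
weighted by the pattern confidence:

    ŷ = w⁺ · y_P + w⁻ · history,   w⁻ = 1 − w⁺

where y_P is the learned within-trial pattern (snapshot of the last
active trial's outcome) and `history` is the per-bin outcome history.
The history is an exponential moving average across trials with
retention parameter defaulting to 0, i.e. expectation = last trial's
outcome — the same simplification the discrete model uses; setting
`history_retention` > 0 recovers a longer weighted average.  (The
expectation-averaging hypothesis is inherently ambiguous between
across-trial and within-trial filtering; this implementation filters
across trials per bin and lets τ act within the trial, which makes the
continuous model reduce exactly to the discrete recursion bin by bin —
verified by `discrete_consistency_check`.)

Confidence weights follow a bounded potentiation/depression rule:

    occurrence:     w⁺ ← w⁺ + η⁺ (1 − w⁺)
    non-occurrence: w⁺ ← w⁺ (1 − η⁻)

with η⁺, η⁻ ∈ (0, 1].  Defaults: **η⁺ = 0.5, η⁻ = 1.0**.  The
depression default encodes that in a deterministic protocol a single
non-occurrence falsifies the pattern belief; it also makes the model
internally consistent: during extinction the expectation must fall back
to the outcome history for the placebo response to decay geometrically
with ratio α (a sticky pattern term keeps injecting the stale learned
pattern into the error and distorts the decay).  Occurrence detection
comes from the trial label (active = occurred, placebo = not), not from
the data.  Initial pattern memory: y_P ≡ 0, w⁺ = 0.

Consequences checked by the tests: after repeated identical active
trials the reactive component converges to a τ-smoothed copy of the
stimulus response scaled toward α/(1 − α) (reactive mimicking); a
following placebo trial reproduces that component (correlation > 0.95 in
the packaged scenario); peak prediction errors decay by ≈ α per active
trial; per-trial plateaus for boxcar stimuli match the discrete closed
form within a fraction of a percent when τ ≤ T0/10; halving T_sample
changes plateaus by < 0.5%.

## Packaged demonstration scenario

`fig1_scenario()` builds the reference conditions for a
hormone-release-like response: T0 = 150 min, τ = 10 min, α = 0.45,
T_sample = 0.5 min (= τ/20), five open active administrations of a
fixed single-peak stimulus curve followed by placebo trials.

## Synthetic stimulus curves and noise

`pk_curve` generates a two-exponential absorption/elimination curve
v(t) ∝ e^(−k_elim·t) − e^(−k_abs·t), normalized so its sampled maximum
equals the dose.  The defaults k_abs = 0.03/min, k_elim = 0.012/min put
the peak near 51 min in the 150-min window; they are illustrative free
choices (nothing in the model constrains them), not fitted to any
measured hormone data.  Equal rates fall back to t·e^(−kt).

Observation noise is additive i.i.d. Gaussian on recorded responses
only — it never perturbs the learner's internal dynamics, which the
model treats as deterministic.  A seed is mandatory for every stochastic
operation; σ = 0 returns the input values unchanged.  What the
generator does **not** emulate: state-dependent or autocorrelated
measurement error, inter-subject variability in α or x, drifting
pharmacokinetics across trials, or cognitive γ fluctuations.  Passing
recovery tests therefore show identifiability under the model's own
assumptions, not robustness to real clinical measurement processes.

## Estimation

- x from hidden trials: sample mean ± standard error (hidden responses
  equal x up to observation noise by construction).
- α from acquisition: the successive-difference ratio
  (y_{n+1} − y_n)/(y_n − y_{n−1}) equals α exactly and is used whenever
  the ratios are mutually consistent (relative spread ≤ 1e−9); otherwise
  the closed form y_n = x(1 − αⁿ)/(1 − α) is fit by bounded nonlinear
  least squares (|α| ≤ 0.999, initialized from the median ratio).
  Ratios amplify noise, hence the least-squares path for noisy data.
  A flat nonzero trace is reported as α = 0; a flat zero trace is
  underdetermined.
- α from extinction: the successive ratio y_{n+1}/y_n, with a log-linear
  regression of ln|y_n| on n (slope = ln|α|, sign from the ratio signs)
  as the noisy path.  A zero response makes the exact ratio undefined
  and raises.

Round-trip recovery on noiseless traces is exact to ≲ 1e−10; under the
default recovery study conditions (x = 1, α = 0.45, σ = 0.05, 10 trials,
200 seeded replicates) the mean absolute error of α̂ is ≈ 0.017.

## Problem sizes

The package's own studies use: 200 random parameter draws for the
closed-form oracles (n ≤ 50 trials), 60 active trials per accumulation
cycle, 10 boxcar trials for the consistency check at τ = 5 min
(N = 600 bins), the 150-min scenario at 300 bins over 9 trials, and 200
replicates for the recovery study — sizes at which every quantity is
converged well past the tolerances quoted above while the full suite
runs in seconds.

## Known limitations

- The error-precision mechanism is a single multiplicative scalar; no
  hierarchical precision model is attempted.
- Pattern occurrence is taken from trial labels; the model does not
  infer from data whether the learned pattern occurred.
- The continuous model's symbolic transfer-function form is not
  implemented; the construction recipe (fine-step recursion + first-order
  filter + periodic pattern buffer) is the implementation, validated by
  its reduction to the discrete model.
- No fitting to real plasma-concentration data is provided; the
  estimators operate on the package's own trace format.
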