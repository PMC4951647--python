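# placebosim

Quantitative modelling of the response to drug administration and of the
placebo response it leaves behind, built on implicit **UCS-revaluation
learning**: the trial-by-trial, prediction-error-driven re-evaluation of an
unconditioned stimulus (the administration itself).

## Who this is for

Researchers in computational neuroscience, placebo research and
pharmacodynamic modelling who want to simulate open/hidden/placebo
administration protocols, explore resistant-to-extinction response
engineering, and test how well the model's parameters can be recovered
from response traces — all without any external data.

## The model

The response of a target CNS component to an *open* (perceived)
administration in trial *n* decomposes linearly as

    y_n = x_n + i_R,n + γ_n + b_n

where *x* is the active pharmacological effect, *i_R* the self-induced
**reactive response** (the implicit placebo component, which mimics the
drug's effect), *γ* a cognitive contribution (expectations, suggestions)
and *b_n* a baseline drift.  The reactive response is updated by the
prediction error *e* against the expected outcome (by default, the last
experienced outcome):

    e_n   = y_n − y_{n−1}
    i_R,n = i_R,n−1 + α · e_{n−1}

with **reactive efficiency** α; stability requires 0 < |α| < 1.  For a
constant stimulus this yields geometric acquisition
y_n = x(1 − αⁿ)/(1 − α), the asymptote y∞ = x/(1 − α), and — once the
active effect is withdrawn — geometric extinction y_n = x αⁿ/(1 − α).
Hidden (covert) administrations deliver *x* without triggering or updating
*i_R*; virtual trials (cognitively simulated outcomes) and misattributed
responses drive the same error machinery; blocking the error computation
during placebo trials leaves a resistant-to-extinction reactive floor
*i_R0* that accumulates by x·α/(1 − α) per protocol cycle.

A continuous-time extension handles pharmacodynamic curves x(t) over a
trial window T0, with a first-order low-pass (time constant τ) shaping
expectation and reactive output and a learned within-trial pattern with
confidence weights (w⁺, w⁻) — so the reactive system learns to *mimic*
the drug's time course.

An estimation module operationalizes the measurement program: hidden
trials give x (sample mean), open acquisition/extinction traces give α
(exact successive-difference/ratio computations, or bounded least squares
under noise).

## Worked example

```python
import placebosim as ps

params = ps.ModelParams(alpha=0.5)
trials = [ps.Trial(kind="active", x=1.0)] * 8 + [ps.Trial(kind="placebo")] * 5
records = ps.run_protocol(trials, params)
print(ps.records_to_frame(records)[["trial_index", "kind", "y", "e", "i_R"]])
```

prints (see `examples/acquisition_and_extinction.py`)

```
 trial_index    kind      y       e    i_R
           1  active 1.0000  1.0000 0.5000
           2  active 1.5000  0.5000 0.7500
           3  active 1.7500  0.2500 0.8750
           ...
           8  active 1.9922  0.0078 0.9961
           9 placebo 0.9961 -0.9961 0.4980
          10 placebo 0.4980 -0.4980 0.2490
          ...
```

The open response climbs from x = 1 toward x/(1 − α) = 2 while the error
shrinks by α per trial; the first placebo trial elicits the learned
reactive component (≈ 1 = x·α/(1 − α)), which then extinguishes with
ratio α.

The other scripts in `examples/` each demonstrate one capability:
the two-quantities stability theorem (`theorem_two_quantities.py`),
resistant-response accumulation (`resistant_accumulation.py`),
continuous-time reactive mimicking of a single-peak release curve
(`reactive_mimicking_continuous.py`) and parameter recovery
(`parameter_recovery.py`).

## Command line

A thin CLI wraps the library:

```bash
placebosim simulate --config protocol.yaml --out trace.csv
placebosim estimate trace.csv --out estimates.csv
placebosim theorem-demo --n-trials 100 --out demo.csv
placebosim fixtures --out-dir fixtures/
```

The config schema (YAML; JSON accepted) is documented in
`src/placebosim/io.py`: a `params` mapping (`alpha`, and for continuous
mode `tau`, `T0`, `T_sample`, `eta_plus`, `eta_minus`), an ordered
`trials` list (`kind`, `x` or `curve`, optional `repeat`,
`gamma`, `misattributed`, `baseline_shift`, `error_blocked`,
`simulated_outcome`), optional `init`, and `noise.sigma` with a mandatory
`seed` for stochastic runs.  Traces are plain CSV.

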