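"""Operational measurement of x and alpha from administration traces.

Hidden (covert) administrations expose the pure pharmacological effect x;
open acquisition and extinction traces expose the reactive efficiency
alpha through their geometric structure.  With observation noise, alpha
is recovered by least squares on the acquisition closed form.
"""

import numpy as np

import placebosim as ps

x_true, alpha_true = 1.0, 0.45

# noiseless: exact recovery from a simulated subject
trials = ([ps.Trial(kind="hidden", x=x_true)] * 3
          + [ps.Trial(kind="active", x=x_true)] * 8
          + [ps.Trial(kind="placebo")] * 4)
trace = ps.records_to_frame(ps.run_protocol(trials, ps.ModelParams(alpha=alpha_true)))
print("Noiseless trace estimates:")
print(ps.estimate_from_trace(trace).to_string(index=False, float_format="%.6g"))

# noisy: Monte-Carlo over 200 seeded acquisition traces
errors = [
    abs(ps.estimate_alpha(
        ps.noisy_acquisition_trace(x_true, alpha_true, 10, sigma=0.05, seed=rep)
    ).value - alpha_true)
    for rep in range(200)
]
print(f"\nNoisy recovery (sigma = 0.05, 10 trials, 200 replicates):")
print(f"mean absolute error of alpha_hat = {np.mean(errors):.4f}")
print("\nThe exact successive-difference/ratio paths recover the parameters to")
print("machine precision; under noise the least-squares fit stays well within")
print("0.05 of the true reactive efficiency.")
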