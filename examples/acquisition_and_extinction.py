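"""Acquisition and extinction of the implicit placebo response.

Repeated open administrations of a drug with constant effect x build up a
self-induced reactive component i_R through prediction-error learning;
switching to placebo extinguishes it geometrically.
"""

import placebosim as ps

x, alpha = 1.0, 0.5
params = ps.ModelParams(alpha=alpha)

trials = [ps.Trial(kind="active", x=x)] * 8 + [ps.Trial(kind="placebo")] * 5
records = ps.run_protocol(trials, params)

print(ps.records_to_frame(records)[["trial_index", "kind", "y", "e", "i_R"]]
      .to_string(index=False, float_format="%.4f"))

y_inf, i_R_inf = ps.asymptotic_response(x, alpha)
print(f"\nAsymptotic open response  y_inf = x/(1-alpha)       = {y_inf:.4f}")
print(f"Asymptotic reactive part  i_R_inf = x*alpha/(1-alpha) = {i_R_inf:.4f}")
print("\nDuring acquisition y climbs from x toward y_inf as errors shrink by a")
print("factor alpha per trial; the first placebo response equals the learned")
print("reactive component, then decays with the same ratio alpha per trial.")
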