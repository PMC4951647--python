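"""Why the brain must store prediction and reactive response separately.

If a single quantity served as both the predicted outcome and the
self-induced reactive response, each administration would add the active
effect on top of the previous prediction and the outcome would grow
without bound — contradicting the observed saturation of drug responses.
"""

import numpy as np

import placebosim as ps

x, alpha, n = 1.0, 0.5, 100

single = ps.single_quantity_variant(x, n)
records = ps.run_protocol([ps.Trial(kind="active", x=x)] * n,
                          ps.ModelParams(alpha=alpha))
two = np.array([r.y for r in records])

print(f"trial   one-quantity y   two-quantity y")
for k in (1, 2, 5, 10, 50, 100):
    print(f"{k:5d}   {single[k-1]:14.4f}   {two[k-1]:14.4f}")

print(f"\nOne-quantity model: y_n = n*x grows without bound (y_{n} = {single[-1]:.0f}).")
print(f"Two-quantity model: y_n saturates below x/(1-alpha) = {x/(1-alpha):.2f}.")
print("Stability therefore requires two separately updated quantities.")
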