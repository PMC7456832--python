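"""Generate one confounded mediation dataset and compare the five estimators.

The condition has post-treatment confounding: the treatment shifts both
measured confounders (g = h = 0.59), which also carry the influence of an
unmeasured confounder U onto the outcome.  The true indirect effect is
b*(a + d*g + f*h) = 0.759; adjusting for the confounders in a plain
regression opens the collider path through M and overestimates it badly.
"""

from seqmed import (PathCoefficients, SimulationCondition, estimate_all_methods,
                    generate_dataset, true_effects, two_confounder_battery)
from seqmed.estimators import estimates_frame

coefs = PathCoefficients(a=0.59, b=0.59, c_prime=0.0, d=0.59, f=0.59,
                         g=0.59, h=0.59)
cond = SimulationCondition("example", coefs, sample_size=500)
data = generate_dataset(cond, seed=0)

truth = true_effects(coefs)
print(f"true total = {truth.total:.3f}, CDE = {truth.cde:.3f}, "
      f"indirect = {truth.indirect:.3f}\n")

frame = estimates_frame(estimate_all_methods(data, two_confounder_battery()))
print(frame.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nindirect_hat is total minus direct; sequential g-estimation and the "
      "doubly robust variant land closest to 0.759 on this draw, while the "
      "adjusted regression overshoots.")
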