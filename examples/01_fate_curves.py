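"""The two probability curves that drive cell fate after DNA damage.

Repair follows a narrow Gaussian window just after the damage (most repair
happens within the first couple of cell cycles); adaptation follows a delayed
logistic ramp whose slope p controls how synchronously cells override the
checkpoint.  Prints both curves at the first few steps.
"""

import numpy as np

from ddadapt import ModelParams, alpha_at, beta_at

params = ModelParams()  # baseline: alpha_m=0.5, mu_a=1, beta_m=0.5, mu_b=3.886, p=3

print(f"{'step':>4} {'alpha (repair)':>15} {'beta (adaptation)':>18}")
for t in np.arange(0, 8.1, 1.0):
    print(f"{t:4.0f} {alpha_at(t, params):15.5f} {beta_at(t, params):18.5f}")

h = 1e-6
slope = (beta_at(params.mu_b + h, params) - beta_at(params.mu_b - h, params)) / (2 * h)
print(f"\nslope of beta at its centre: {slope:.4f}  (= p*beta_m/4 = {params.p / 8:.4f})")
print("Repair peaks at step 1 and is gone by step 3; adaptation only becomes")
print("likely after step ~3, so cells try repair first and adapt as a fallback.")
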