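# Baseline parameter set for the DNA-damage cell-fate model.
# One time unit = one cell-cycle step.
n0: 20000        # initial damaged cells
nmax: 100000     # carrying capacity of the environment
gamma1: 0.1      # per-step death probability of damaged cells
gamma_ad: 0.35   # per-step death probability of adapted cells
gamma_r: 0.0     # per-step death probability of repaired cells
delta: 0.02      # adapted -> repaired transition probability per step
alpha_m: 0.5     # peak repair probability
sigma: 0.5       # repair-window width (steps)
mu_a: 1.0        # repair-window centre (steps)
beta_m: 0.5      # maximal adaptation probability
p: 3.0           # adaptation-curve slope parameter
mu_b: 3.886      # adaptation half-maximum time (steps)
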