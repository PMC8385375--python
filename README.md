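# ddadapt — cell-fate dynamics after DNA damage

`ddadapt` models the survival of a population of budding-yeast cells that
all receive DNA damage at time zero.  Each checkpoint-arrested cell faces
three fates per cell cycle: **repair** (probability `α(t)`, a narrow Gaussian
window just after the damage), **adaptation** — overriding the checkpoint and
dividing despite persistent damage — (probability `β(t)`, a delayed logistic
ramp), or **death**.  Adapted cells divide but die often (damaged-chromosome
missegregation) and can still repair later through alternative pathways.  The
package asks the evolutionary question behind these kinetics: *when* should
cells adapt, and does the cell-to-cell **heterogeneity** of adaptation timing
(the logistic slope `p`) ever pay off — i.e. is adaptation a bet-hedging
strategy for unpredictable damage environments?

It is a library for systems-biology modellers: importable API first,
`examples/` scripts per capability, plus a thin `ddadapt` CLI.

## The model

Probability curves (one time unit = one cell cycle, ≈ 1.5–2 h):

```
α(t) = α_m exp(−(t − μ_a)² / σ²)          repair window, peak α_m at μ_a
β(t) = β_m / (1 + exp(−p (t − μ_b)))      adaptation ramp, β′(μ_b) = p β_m / 4
```

**Stochastic model** — compartment counts (D damaged, A adapted, R repaired)
evolve by per-step multinomial draws: damaged cells die (γ₁), adapt (β(n)) or
repair (α(n)); adapted cells die (γ_ad) or repair (δ); at the end of each
step A and R double within the carrying capacity `N_max`, remaining space
filled proportionally.

**Continuous model** — the mean-field ODE counterpart with logistic growth,
`N = D + A + R`:

```
D' = −(γ₁ + β(t) + α(t)) D
A' = β(t) D − (γ_ad + δ) A + A (1 − N/N_max)
R' = α(t) D + δ A − γ_r R + R (1 − N/N_max)
```

A lineage-resolved variant splits `R = R_d + R_a` (repaired directly vs
repaired after adaptation) to measure how much of the surviving population
carries adaptation's mutational legacy.

The central observable is the **saturation time** `T_S`: the first time the
healthy compartment fills the environment (stochastic: `R ≥ N_max`;
continuous: `N_max − R(t) < 1`).  Smaller `T_S` = better population survival.

**Fluctuating environments** — the damage source stays on for a random stop
time τ (Gaussian, exponential, or uniform law); no repair is possible before
τ.  Two readings of what happens after τ are implemented (`resume_mode`):
the repair window re-centred on τ (`"restarted"`, the default) or kept on
the absolute clock and therefore mostly lost when τ outlives it
(`"absolute"`).  The two readings answer differently on whether timing
heterogeneity is adaptive — see `docs/methods.md` for the full analysis.

## Worked example

```python
import numpy as np
from ddadapt import ModelParams, sweep_mu_b, run_ode

params = ModelParams()                      # baseline parameter set
res = sweep_mu_b(params, np.arange(1.0, 6.01, 0.25))
print(res.argmin, res.ts_at_argmin)
```

This sweeps the adaptation centre `μ_b` (ODE model, stable environment,
p = 3), refines the minimum by golden-section search, and prints

```
3.176  32.236
```

— the survival-optimal adaptation timing sits ~2.2 cell cycles *after* the
repair window (μ_a = 1), and shifting the repair window moves the optimum
with it (`optimal_mu_b_vs_mu_a`): repair is always tried first, adaptation
is the fallback.  The landscape is extremely flat: `T_S(μ_b = 3.9)` is only
0.3% above the minimum.

Running `python examples/05_population_structure.py` prints the lineage
composition at saturation:

```
   p  % adapted ancestry (random)   (stable)
 0.5                         28.6        3.1
 1.0                         15.8        1.4
 3.0                          6.0        0.6
```

With heterogeneous timing (p = 1) in a random environment, ~16% of the
surviving population descends from adapted cells — heterogeneity promotes
genetic diversity, not just survival.  The other examples cover the
stochastic/ODE comparison and the fluctuating-environment sweeps.

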