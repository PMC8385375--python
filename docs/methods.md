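# Methods

## The model

A population of `N0` yeast cells receives DNA damage once, at time 0, and
arrests at the G2/M checkpoint.  Arrested (damaged) cells face three
exclusive fates per cell cycle: death, repair, or adaptation — checkpoint
override followed by division with persistent damage.  Adapted cells keep
dividing, die at a high rate (missegregation of damaged chromosomes), and
can still reach the repaired state through alternative repair pathways
available after division.  Repaired cells and their descendants are
"healthy"; the population has recovered when healthy cells fill the
environment's carrying capacity `Nmax`.  The **saturation time** `T_S`
(first time with `R ≥ Nmax`, continuous: `Nmax − R(t) < 1`) is the fitness
proxy throughout: smaller `T_S`, better population survival.

Time is measured in cell cycles (≈ 1.5–2 h each); nothing converts to hours.
Two curves carry all time dependence:

* repair probability `α(t) = α_m exp(−(t − μ_a)²/σ²)` — a transient window:
  most lesions are either repaired within the first couple of cycles or not
  at all;
* adaptation probability `β(t) = β_m / (1 + exp(−p(t − μ_b)))` — a delayed
  ramp; its slope at the midpoint is `p β_m/4`, so `p` measures how
  synchronously cells adapt (`p` large: sharp, homogeneous timing; `p ≈ 1`:
  timing spread over several cycles, matching the experimentally observed
  5–15 h spread).

`α` and `β` are used directly as per-step probabilities (discrete model) and
as rates (continuous model); they are not densities and are never
renormalised.

### Parameters (defaults = the study's baseline)

| name       | meaning                                   | default |
|------------|-------------------------------------------|---------|
| `n0`       | initial damaged cells                     | 20 000  |
| `nmax`     | carrying capacity (cells)                 | 100 000 |
| `gamma1`   | per-step death hazard, damaged            | 0.10    |
| `gamma_ad` | per-step death hazard, adapted            | 0.35    |
| `gamma_r`  | per-step death hazard, repaired           | 0.0     |
| `delta`    | adapted → repaired per step               | 0.02    |
| `alpha_m`  | peak repair probability                   | 0.5     |
| `sigma`    | repair-window width (steps)               | 0.5     |
| `mu_a`     | repair-window centre (steps)              | 1.0     |
| `beta_m`   | maximal adaptation probability            | 0.5     |
| `p`        | adaptation slope (dimensionless)          | 3.0     |
| `mu_b`     | adaptation half-maximum time (steps)      | 3.886   |

All probabilities are validated to [0, 1] at construction.  The discrete
model additionally needs `γ₁ + α(n) + β(n) ≤ 1` at every step; that bound
depends on how the curves overlap, is violated by legitimate sweep settings
(e.g. `μ_b → 0`), and does not constrain the rate-based ODE — so it is
enforced where the multinomial actually exists (`run_stochastic` /
`markov_step` raise), not in the constructor.

## Discrete stochastic model: conventions

Cells are simulated as compartment counts with one multinomial draw per
compartment per step — exactly the law of the underlying per-cell Markov
chain, orders of magnitude faster than agents.  Conventions the model text
leaves open, fixed here:

* **step indexing** — the first transition after damage uses `n = 1`, so the
  repair window (centre `μ_a = 1`) peaks at the first step;
* **exclusivity** — per-step fates are simultaneous and exclusive (one
  multinomial), conserving cell number exactly;
* **order within a step** — transitions first, division second; newly
  repaired/adapted cells divide in the same step they transitioned;
* **division** — each dividing cell adds one daughter; if demand `A + R`
  exceeds the free space `Nmax − (D+A+R)`, exactly the free slots are
  allocated proportionally (largest-remainder rounding).  Damaged cells
  occupy space but do not divide;
* **RNG** — one `numpy` Generator per run; replicate `r` of an averaging run
  uses `base_seed + r`.  Runs are bit-reproducible from the seed.

## Continuous model: numerics

The mean-field ODE (see README for the equations) is integrated with
`scipy.integrate.solve_ivp` (RK45, `rtol 1e-8`, `atol 1e-8·Nmax`), from
`(N0, 0, 0)`.  Design points:

* **saturation detection** — a terminal event `R − (Nmax − 1)` with positive
  crossing direction; the solver's dense-output root finder locates `T_S`.
  The criterion is one-sided (R approaches `Nmax` from below);
* **crowding** — the logistic factor `(1 − N/Nmax)` multiplies only the
  growth terms of A and R and is *not* clipped if N transiently overshoots;
* **undershoot guard** — compartments are clamped to ≥ 0 inside the RHS.
  This non-smooth guard sets the practical convergence floor: `T_S` is
  reproducible to ~3·10⁻⁴ time units across tolerance choices and solvers
  (RK45 vs DOP853), far below any physically meaningful difference;
* **homogeneity** — the dynamics are degree-1 homogeneous in
  `(D, A, R, Nmax)`: doubling `N0` and `Nmax` scales trajectories exactly.
  `T_S` itself shifts by ~+1.9 steps because the 1-cell saturation margin is
  absolute (a doubled population must close a relatively smaller gap); tests
  assert the trajectory proportionality, not `T_S` equality;
* **lineage split** — the 4-compartment variant (`R = R_d + R_a`) is an
  exact refinement; the summed split reproduces the 3-compartment R to
  < 10⁻⁴·Nmax along the whole trajectory.

The discrete and continuous models agree only qualitatively — the continuous
one lets cells transition and grow *between* steps, so it runs ahead of the
discrete mean from the very first step (after one step, ODE `D(1) ≈ 14 500`
vs discrete mean ≈ 7 975 at baseline) and saturates ~6 steps later at
baseline (growth rate 1 vs doubling, and an asymptotic approach to the
absolute 1-cell margin).  Their optimum locations, which is what the
analysis uses, fall within half a step of each other; the acceptance suite
asserts a 3-standard-error pointwise band as specified and that test fails,
documenting the discrepancy rather than hiding it.

## Fluctuating environments

The generator emulates a damage source that stays active for an
unpredictable time — chronic irradiation or telomere deprotection of random
duration — rather than a single instantaneous insult.  A stop time `τ` is
drawn from a law (Gaussian mean 1.7, variance 2.25 truncated at 0 — the
study's setting; exponential with mean 1.7; or uniform on [0, 3.4] with
post-stop repair amplitude fading as `e^(−0.3 τ)` — the non-printed
parameters are package choices, configurable and excluded from acceptance).
While the source is on, no repair is possible (`α_env ≡ 0` before `τ`); the
adaptation clock is never gated, since cells have been checkpoint-arrested
from `t = 0`.

**What happens to the repair window after τ is the single most consequential
modelling choice in this package**, and the available description admits two
readings, both implemented as `Environment.resume_mode`:

* `"restarted"` (default): `α_env(t) = α(t − τ)` — repair opportunity
  follows the end of the damage phase, delayed but undiminished;
* `"absolute"`: `α_env(t) = α(t)` for `t ≥ τ` — the window runs on the
  absolute clock, so a source outliving it (mean τ = 1.7 vs window centre 1,
  width 0.5) destroys most repair opportunity and leaves adaptation as the
  only survival route.

The two readings reproduce *different halves* of the published behaviour,
and no single reading we could construct (including fading amplitudes and
gating the `δ` channel) reproduces both:

| phenomenon                                             | restarted | absolute |
|--------------------------------------------------------|-----------|----------|
| interior optimum of expected `T_S` at `p ≈ 1`           | no (boundary, max p) | **yes** (≈ 0.6) |
| `T_S` nearly flat in `p` (vs stable environment)        | no        | **yes** (spread 0.7 vs 2.4) |
| ~17% adapted ancestry at `p = 1`                        | **yes** (15.8%) | no (59%) |
| ancestry plateau past `p = 3`, stable case ≪ random     | **yes**   | no       |

The survival analyses (`examples/04`, the fluctuating p-sweep acceptance
check) therefore use the absolute reading — the bet-hedging phenomenon
*is* the possibility of permanently losing the repair window — while the
lineage analyses use the default restarted reading, under which the ancestry
composition matches.  Both are one keyword apart everywhere in the API, and
this discrepancy is stated rather than averaged away.

### Ensembles and averaging

Expectations over the stop-time law use deterministic composite-trapezoid
quadrature on the density: 200 nodes spanning `[0, q_0.9999]`, weights
renormalised after the truncation at 0 (a source stopping "before the
start" stops at 0).  The quadrature mean matches the closed-form
truncated-normal mean to ~10⁻³; a seeded Monte-Carlo estimator is kept for
cross-validation and agrees within its standard error.  Averaging semantics:
the scalar of interest (`T_S`, ancestry fraction) is computed *per
environment realization* and then averaged — the expectation of the
functional, not the functional of the mean trajectory.  Ensemble-averaged
trajectories on a common grid are separately available
(`average_trajectories`) for subpopulation time-course output; nodes that
fail to saturate by `t_max` are excluded with their weight mass logged
(warning above 5%, error above 50%).

## Sweeps and optima

1-D sweeps evaluate `T_S` on a user grid (defaults: `μ_b ∈ [0, 10]` step
0.05; `p ∈ [0.1, 5]` step 0.05–0.1) and refine an interior grid minimum by
golden-section search between its two neighbours to ~10⁻³ (deterministic
models only; stochastic sweeps carry Monte-Carlo standard errors instead).
Boundary minima are reported unrefined and flagged, which is itself
informative: in the `(μ_b, p)` plane, intermediate adaptation timing puts
the optimal `p` at the top of the tested range ("sharper is better"),
while very late timing (`μ_b = 7`) produces a genuine interior optimum near
`p ≈ 0.6` — heterogeneity partially compensating for mistimed adaptation.
Non-saturating grid points are NaN sentinels, excluded from argmins.

A caution that applies to every optimum here: the `T_S` landscapes are
extremely flat (sub-1% relief across the basin).  Optimum *locations* are
therefore sensitive to modelling details that barely change `T_S` itself —
the stable-environment timing optimum sits at `μ_b ≈ 3.18` in this
implementation, ~0.7 steps earlier than the published 3.886, although
`T_S` differs by only 0.3% between the two points, and none of a dozen
tested model variants moves the argmin to the published location.  Values of
`T_S` are robust; third-decimal argmin coordinates are not.

## Problem sizes

Tests and the acceptance script use: 200-node quadrature ensembles (60–100
nodes where only a range or ordering is asserted); stochastic averages over
200–1 000 replicates at full population size (mean-`T_S` standard error
≈ 0.1–0.2 steps, ample for the half-step comparisons made); `t_max` 500 for
stable runs and 2 000 for gated environments.  The full default test run
finishes in ~3 minutes on one CPU; the acceptance script in ~2.

## Limitations

* No re-damage of repaired cells and no repeated damage episodes; the
  environment only gates the first repair window.
* Compartment-level stochasticity only: no per-cell covariates, no
  cell-cycle phase structure, no spatial effects.
* The carrying capacity acts through a single global crowding term;
  dead cells vanish instantly.
* The synthetic environments are on/off gates with simple stop-time laws;
  real damage intensity varies continuously.  Passing tests show the model
  reproduces its own stated dynamics and (partially) the published optima —
  they do not validate the kinetics against experimental survival data.
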