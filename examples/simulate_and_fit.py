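"""Simulate one correlated-pair dataset and fit the four CJS structures.

With gamma=rho=0 the generator is the standard CJS model; here we inject
strong survival correlation and watch what each model structure reports.
"""

from pairbond_cjs import (
    ALL_STRUCTURES,
    HistoryCounts,
    SimulationConfig,
    empirical_history_frequencies,
    fit_cjs,
    simulate_dataset,
)

config = SimulationConfig(gamma=0.9, rho=0.0, seed=42)
data = simulate_dataset(config)
print(f"{data.n_individuals} animals over {data.n_occasions} occasions; "
      f"{len(set(map(int, data.entity_index)))} entities")

freqs = empirical_history_frequencies(data)
print("most common histories:",
      dict(sorted(freqs.items(), key=lambda kv: -kv[1])[:3]))

counts = HistoryCounts.from_dataset(data)
for structure in ALL_STRUCTURES:
    fit = fit_cjs(counts, structure)
    est = ", ".join(f"{k}={v:.3f}" for k, v in fit.estimates.items())
    print(f"{fit.structure.name:10s} logL={fit.log_lik:9.2f} "
          f"deviance={fit.deviance:6.2f} df={fit.df_deviance:2d}  {est}")
# Estimates stay near the generating phi=0.7, p=0.8 in every structure:
# pair correlation does not bias the MLEs, it degrades their stated precision.
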