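"""Generate a synthetic multi-omics time-course study.

Five groups (control plus four post-treatment time points), five replicates
each; planted gene and metabolite modules follow distinct temporal
trajectories and drive lung-function-like phenotype parameters.
"""

from fibronet import simulate as sim

config = sim.SimConfig(n_genes=500, n_metabolites=100, seed=0)
counts, design, truth = sim.generate_counts(config)
metabolites, _ = sim.generate_metabolites(config, truth)
phenotypes, _ = sim.generate_phenotypes(config, truth)

print(f"counts matrix:      {counts.shape[0]} genes x {counts.shape[1]} samples")
print(f"metabolite matrix:  {metabolites.shape[0]} x {metabolites.shape[1]}, "
      f"{metabolites.values.isna().to_numpy().mean():.1%} missing")
print(f"phenotypes:         {', '.join(phenotypes.features)}")
module_sizes = {m: len(truth.module_genes(m)) for m in range(config.n_modules)}
print(f"planted gene modules: {module_sizes}")
print(f"groups: {design.groups} (reference: {design.reference})")

# Each module's trajectory is the standardized log-scale effect per group;
# the missing metabolite entries mimic detection-limit censoring in MS data.
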