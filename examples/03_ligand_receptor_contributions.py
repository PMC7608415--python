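"""Rank the ligand-receptor pairs driving one cluster-cluster interaction.

Each connected A-B cell pair's affinity is decomposed into per-LR-pair
fractions; averaging over connected pairs ranks the molecular drivers.
"""

import pseudospace as ps

expr, lr, truth = ps.default_benchmark(seed=0)
result = ps.run_pipeline(expr, lr, ps.RunConfig(seed=0), contributions_for="all")

table = result.contributions[("A", "B")]
print(f"A-B contributions averaged over {table.n_pairs} connected cell pairs "
      f"(cutoff {table.cutoff:.3f}):")
print(table.table.to_string(index=False))
print(f"planted driver was {truth.dominant_pair('A', 'B')}")

# The planted L1-R1 pair carries essentially the whole A-B affinity; the
# five decoy pairs split the remaining fraction of a percent.
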