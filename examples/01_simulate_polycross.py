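"""Generate a synthetic polycross cohort with ground truth.

Builds the default study-like trial — 26 maternal families pollinated by a
21-male polymix with unequal contributions, plus maternal record errors,
dual-genotype mothers, pollen contamination and selfing — and prints what
the truth bundle knows about it.
"""

import pxgs

cfg = pxgs.SimConfig(n_snps=2000, offspring_per_family=58, seed=1)
founders = pxgs.simulate_founders(cfg)
geno, truth = pxgs.simulate_polycross(founders, cfg)

print(f"founders: {founders.genotypes.n_samples} "
      f"({len(founders.female_ids)} females, {len(founders.male_ids)} males)")
print(f"offspring: {geno.n_samples} x {geno.n_snps} SNPs")
print("\ninjected error profile (true statuses):")
print(truth.status_flags["status"].value_counts().to_string())
print(f"\ndual-genotype mothers: {sorted(truth.hidden_mothers)}")
print("male contribution weights (first 5):", truth.male_weights[:5].round(3))
# Each offspring's row in the truth bundle records its true and recorded
# parents, so any downstream reconstruction can be scored exactly.
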