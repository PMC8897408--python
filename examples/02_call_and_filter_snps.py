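"""Genotype-likelihood SNP calling and the museum-data filter cascade.

Calls biallelic SNPs from simulated pileups via the per-read likelihood
model, then applies the depth / missingness / MAF / triallelic filters.
"""

import museopop as mp

cfg = mp.SpeciesTreeConfig(n_windows=20, seed=1)
sim = mp.simulate_genealogies(cfg)
panel = mp.mutate_sequences(sim)
pile = mp.generate_pileups(
    panel, mean_depth=20, phred=30, seed=1,
    positions={w: win.positions for w, win in enumerate(sim.windows)})

table = mp.call_snps(pile)
table = mp.filter_sites(table)
passing = table.passing()
thinned = mp.thin_snps(passing)

print(f"candidate sites: {pile.n_sites}")
print(f"SNPs called (LRT p < 1e-6): {table.n_sites}")
print(f"passing all filters:        {int(table.passed.sum())}")
print(f"after 10-kb thinning:       {thinned.n_sites}")
print(f"minimum minor-allele chromosomes at MAF 0.12, 16 diploids: "
      f"{mp.min_minor_allele_chromosomes(16, 0.12)}")
# The MAF filter dominates: with 16 diploids a passing site needs the minor
# allele on at least 4 of 32 chromosomes, removing rare variants that
# post-mortem damage and sequencing error tend to mimic.
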