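"""Simulate a small museum-resequencing dataset with known truth.

Five oriole-like taxa on a rooted species tree, short damaged fragments,
and per-site pileups — the raw material every later example consumes.
"""

import museopop as mp

cfg = mp.SpeciesTreeConfig(n_windows=20, seed=1)
sim = mp.simulate_genealogies(cfg)
panel = mp.mutate_sequences(sim)
reads = mp.fragment_and_damage(panel, mp.DamageModel(d5=0.3, d3=0.3),
                               mean_depth=5, seed=1)
pile = mp.generate_pileups(panel, mean_depth=20, phred=30, seed=1)

n_seg = sum(len(w.positions) for w in sim.windows)
print(f"simulated {len(sim.windows)} unlinked 10-kb windows, "
      f"{sim.n_individuals} diploid individuals, {n_seg} segregating sites")
print(f"fragments: {reads.n_reads} (mean length "
      f"{reads.length.mean():.0f} bp), pileup sites: {pile.n_sites}")
print("individuals:", ", ".join(sim.individuals[:6]), "...")
# Segregating sites scale with both the effective sizes and the split
# depths; fragment lengths mimic degraded museum DNA inserts.
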