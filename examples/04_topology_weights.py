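"""Topology weighting across per-window NJ trees in two ILS regimes.

Deep, clean splits put all weight on the species topology; a rapid
radiation (splits ~1 generation apart) spreads it evenly over the three
in-group resolutions — the classic incomplete-lineage-sorting signature.
"""

from museopop.experiments import topology_deep_split, topology_radiation

summary, w = topology_deep_split(seed=1, n_windows=30)
print("deep-split regime (splits >> Ne):")
print(summary.to_string(index=False))
print(f"-> species topology weight {w:.3f} (expect ~1)\n")

summary, w3 = topology_radiation(seed=1, n_windows=120)
print("rapid-radiation regime (splits 1 generation apart):")
print(summary.to_string(index=False))
print(f"-> three in-group topologies at weights "
      f"{', '.join(f'{x:.2f}' for x in w3)} (expect ~0.33 each)")
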