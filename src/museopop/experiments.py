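"""Canonical simulation studies exercising each analysis end to end.

Each function defines one fixed study design — demography, sample sizes,
depths and replicate counts chosen once to emulate the museum-resequencing
setting — runs the package on freshly simulated data and returns the
measured quantities. They back both the test suite and the reproduction
script, so the numbers those report are always recomputed, never stored.
"""

from __future__ import annotations

import numpy as np

from . import consensus as cons
from . import dstat as ds
from . import likelihoods as lk
from . import simulate as sim
from . import structure as struct
from . import trees as tr


# ---------------------------------------------------------------------------
# ABBA-BABA calibration and power
# ---------------------------------------------------------------------------

def _four_taxon_config(seed: int, f: float, n_windows: int) -> sim.SpeciesTreeConfig:
    pulses = (sim.AdmixturePulse(50_000.0, "P3", "P2", f),) if f > 0 else ()
    return sim.SpeciesTreeConfig(
        labels=("P1", "P2", "P3", "O"),
        merges=(sim.PopulationMerge(100_000.0, "P2", "P1"),
                sim.PopulationMerge(200_000.0, "P3", "P1"),
                sim.PopulationMerge(600_000.0, "O", "P1")),
        ne=100_000.0,
        samples={"P1": 4, "P2": 4, "P3": 4, "O": 2},
        pulses=pulses, n_windows=n_windows, seed=seed,
    )


def dstat_replicate(seed: int, f: float = 0.0,
                    n_windows: int = 800) -> ds.DStatResult:
    """One four-taxon replicate: simulate, polarize, D with window-block jackknife."""
    cfg = _four_taxon_config(seed, f, n_windows)
    data = sim.simulate_genealogies(cfg)
    idx = {lab: [i for i, p in enumerate(data.ind_pop) if p == lab]
           for lab in ("P1", "P2", "P3", "O")}
    freq_l: dict[str, list] = {k: [] for k in ("p1", "p2", "p3", "o")}
    blocks = []
    for w in range(cfg.n_windows):
        dose = data.true_genotypes(w)
        if not len(dose):
            continue
        for key, lab in (("p1", "P1"), ("p2", "P2"), ("p3", "P3"), ("o", "O")):
            freq_l[key].append(dose[:, idx[lab]].sum(1) / (2 * len(idx[lab])))
        blocks.append(np.full(dose.shape[0], w))
    freqs = {k: np.concatenate(v) for k, v in freq_l.items()}
    block_ids = np.concatenate(blocks)
    pol, keep = ds.polarize(freqs, "o")
    return ds.d_statistic(pol["p1"][keep], pol["p2"][keep], pol["p3"][keep],
                          pol["o"][keep], block_ids=block_ids[keep])


def dstat_calibration(n_reps: int = 100, seed: int = 0, f: float = 0.0,
                      n_windows: int = 800):
    """Replicated D tests; returns (results, fraction meeting the criterion).

    Under ``f == 0`` the criterion is |Z| < 3 (correct null calibration);
    under gene flow it is D > 0 and Z > 3 (power to detect the pulse).
    """
    results = [dstat_replicate(seed * 100_003 + i, f=f, n_windows=n_windows)
               for i in range(n_reps)]
    if f == 0:
        frac = float(np.mean([abs(r.z) < 3 for r in results]))
    else:
        frac = float(np.mean([(r.d > 0) and (r.z > 3) for r in results]))
    return results, frac


# ---------------------------------------------------------------------------
# divergence-time recovery through the full calling pipeline
# ---------------------------------------------------------------------------

def divergence_recovery(seed: int = 0, split: float = 50_000.0,
                        n_windows: int = 100, depth: float = 30.0,
                        ne: float = 1_000.0):
    """Recover a known split time from pileups via consensus p-distances.

    Small effective sizes keep ancestral polymorphism (which the p/(2 mu)
    clock cannot see past) well below the 10% recovery tolerance.
    Returns ``(estimated_T, true_split)``.
    """
    cfg = sim.SpeciesTreeConfig(
        labels=("A", "B"), merges=(sim.PopulationMerge(split, "B", "A"),),
        ne=ne, samples={"A": 4, "B": 4}, n_windows=n_windows, seed=seed)
    data = sim.simulate_genealogies(cfg)
    panel = sim.mutate_sequences(data)
    pile = sim.generate_pileups(panel, mean_depth=depth, phred=30)
    calls, dep = lk.call_all_sites(pile)
    mean_depth = dep.mean(axis=0)
    by_contig = {}
    for c in range(len(pile.contigs)):
        m = pile.contig_idx == c
        by_contig[pile.contigs[c]] = cons.build_consensus(
            calls[m], dep[m], mean_depth, pile.individuals, pile.contigs[c])
    wins = cons.extract_windows(
        by_contig, {c: cfg.window_length for c in pile.contigs},
        window=cfg.window_length, step=cfg.window_length,
        min_contig=cfg.window_length - 1)
    aln, _ = cons.concatenate(wins)
    dm = cons.p_distance(aln)
    t_hat = cons.mean_between_population_time(dm, data.pop_map, "A", "B")
    return t_hat, split


# ---------------------------------------------------------------------------
# topology-weighting regimes
# ---------------------------------------------------------------------------

def _window_weights(cfg: sim.SpeciesTreeConfig, group_map, outgroup: str,
                    seed: int):
    data = sim.simulate_genealogies(cfg)
    panel = sim.mutate_sequences(data)
    weights = []
    for w in range(cfg.n_windows):
        seqs = sim.iupac_individual_sequences(panel, w)
        aln = cons.Alignment(data.individuals, seqs)
        dm = cons.p_distance(aln)
        if dm.undefined_pairs:
            continue
        gm = {ind: group_map[data.pop_map[ind]] for ind in data.individuals}
        weights.append(tr.topology_weights(tr.nj_tree(dm), gm,
                                           outgroup=outgroup, window=str(w),
                                           seed=seed))
    return weights


def topology_deep_split(seed: int = 0, n_windows: int = 60):
    """Clean-split regime (splits >> Ne): the species topology dominates.

    Returns ``(summary DataFrame, weight of the true species topology)``.
    """
    cfg = sim.SpeciesTreeConfig(
        ne=5_000.0, samples={"MEL": 2, "TRA": 2, "ROB": 2, "ARD": 1, "NIG": 1},
        n_windows=n_windows, seed=seed)
    gm = {"MEL": "MEL", "TRA": "TRA", "ROB": "ROB", "ARD": "OUT", "NIG": "OUT"}
    weights = _window_weights(cfg, gm, "OUT", seed)
    summary = tr.weight_summary(weights)
    label = "(((MEL,TRA),ROB),OUT)"
    row = summary[summary["topology"] == label]
    w = float(row["mean_weight"].iloc[0]) if len(row) else 0.0
    return summary, w


def topology_radiation(seed: int = 0, n_windows: int = 300,
                       gap: float = 1.0):
    """Near-simultaneous splits: massive ILS, three topologies ~ 1/3 each.

    ``gap`` is the interval (generations) between the two in-group splits.
    Returns ``(summary DataFrame, weights of the three in-group topologies)``.
    """
    base = 200_000.0
    cfg = sim.SpeciesTreeConfig(
        labels=("MEL", "TRA", "ROB", "ARD", "NIG"),
        merges=(sim.PopulationMerge(base, "TRA", "MEL"),
                sim.PopulationMerge(base + gap, "ROB", "MEL"),
                sim.PopulationMerge(150_000.0, "NIG", "ARD"),
                sim.PopulationMerge(800_000.0, "ARD", "MEL")),
        ne=100_000.0,
        samples={"MEL": 2, "TRA": 2, "ROB": 2, "ARD": 1, "NIG": 1},
        n_windows=n_windows, seed=seed)
    gm = {"MEL": "MEL", "TRA": "TRA", "ROB": "ROB", "ARD": "OUT", "NIG": "OUT"}
    weights = _window_weights(cfg, gm, "OUT", seed)
    summary = tr.weight_summary(weights)
    labels = ["(((MEL,TRA),ROB),OUT)", "(((MEL,ROB),TRA),OUT)",
              "(((ROB,TRA),MEL),OUT)"]
    out = []
    for lab in labels:
        row = summary[summary["topology"] == lab]
        out.append(float(row["mean_weight"].iloc[0]) if len(row) else 0.0)
    return summary, out


def weight_entropy_grid(seed: int = 0, gaps=(1.0, 30_000.0, 300_000.0),
                        n_windows: int = 80):
    """Mean weight entropy (bits) over a grid of inter-split intervals.

    Entropy should shrink as the interval between the in-group splits
    grows (less incomplete lineage sorting).
    """
    ents = []
    for gap in gaps:
        _, w3 = topology_radiation(seed, n_windows=n_windows, gap=gap)
        p = np.clip(np.asarray(w3) / max(sum(w3), 1e-12), 1e-12, 1)
        ents.append(float(-(p * np.log2(p)).sum()))
    return list(gaps), ents


# ---------------------------------------------------------------------------
# structure recovery
# ---------------------------------------------------------------------------

def structure_recovery(seed: int = 0, n_windows: int = 60,
                       depth: float = 30.0, k_values=range(1, 11),
                       reps: int = 15, max_iter: int = 400,
                       tol: float = 1e-5):
    """Paper-shaped five-taxon study: four clusters (islands merge).

    Simulates the museum sampling scheme, calls and filters SNPs from
    pileups at the segregating sites, then runs admixture replicates over
    the K grid plus a GL PCA. Returns a dict of the recovered quantities.
    """
    cfg = sim.SpeciesTreeConfig(
        ne={"MEL": 50_000.0, "TRA": 50_000.0, "ROB": 50_000.0,
            "ARD": 50_000.0, "NIG": 50_000.0},
        merges=(sim.PopulationMerge(127_000.0, "TRA", "MEL"),
                sim.PopulationMerge(20_000.0, "NIG", "ARD"),
                sim.PopulationMerge(224_000.0, "ROB", "MEL"),
                sim.PopulationMerge(500_000.0, "ARD", "MEL")),
        n_windows=n_windows, seed=seed)
    data = sim.simulate_genealogies(cfg)
    panel = sim.mutate_sequences(data)
    pile = sim.generate_pileups(
        panel, mean_depth=depth, phred=30,
        positions={w: win.positions for w, win in enumerate(data.windows)})
    table = lk.filter_sites(lk.call_snps(pile)).passing()

    lik_table, best = struct.replicate_runs(table.gl, k_values=k_values,
                                            reps=reps, seed=seed,
                                            max_iter=max_iter, tol=tol)
    dk = struct.delta_k(lik_table)

    # cluster purity at K=4: islands share one cluster, every individual
    # should sit almost fully in its taxon's cluster
    model = best[4]
    taxon_of = [data.pop_map[n] for n in table.individuals]
    merged = ["ISL" if t in ("ARD", "NIG") else t for t in taxon_of]
    groups = sorted(set(merged))
    assign = {}
    for g in groups:
        rows = [i for i, t in enumerate(merged) if t == g]
        assign[g] = int(np.argmax(model.q[rows].sum(axis=0)))
    off = 1.0 - np.array([model.q[i, assign[merged[i]]]
                          for i in range(len(merged))])
    distinct_clusters = len(set(assign.values()))

    dose = struct.expected_genotypes(table.gl, table.maf, table.missing)
    pca_res = struct.pca(dose, table.maf)
    monotone = all(
        np.all(np.diff(m.log_likelihood_path) >= -1e-6) for m in best.values())
    return {
        "n_snps": table.n_sites,
        "best_k": dk.best_k,
        "delta_k_table": dk,
        "max_offcluster": float(off.max()),
        "distinct_clusters": distinct_clusters,
        "em_monotone": monotone,
        "pca": pca_res,
        "individuals": table.individuals,
        "taxa": taxon_of,
        "likelihood_table": lik_table,
    }


# ---------------------------------------------------------------------------
# damage recovery
# ---------------------------------------------------------------------------

def damage_recovery(seed: int = 0, d5: float = 0.3, decay: float = 0.5,
                    n_fragments: int = 100_000):
    """Inject a deamination curve and recover it from simulated fragments.

    Returns ``(profile, injected_ct5, injected_ga3)`` with the injected
    geometric curves evaluated at the profiled offsets.
    """
    cfg = sim.SpeciesTreeConfig(
        labels=("A",), merges=(), ne=10_000.0, samples={"A": 2},
        n_windows=2, seed=seed)
    data = sim.simulate_genealogies(cfg)
    panel = sim.mutate_sequences(data)
    dmg = sim.DamageModel(d5=d5, d3=d5, decay=decay)
    # depth scaled so the fragment count lands near the target
    mean_depth = n_fragments * dmg.fragment_mean / (
        cfg.n_windows * cfg.window_length * 2)
    reads = sim.fragment_and_damage(panel, dmg, mean_depth=mean_depth,
                                    seed=seed)
    prof = lk.estimate_damage_profile(reads)
    inj5 = d5 * decay ** prof.offsets.astype(float)
    inj3 = dmg.d3 * decay ** prof.offsets.astype(float)
    return prof, inj5, inj3
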