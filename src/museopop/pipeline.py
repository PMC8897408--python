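"""End-to-end orchestration: simulate -> genotype -> windowed analyses.

Coordinates are 0-based half-open internally and in BED output, 1-based in
VCF and human-readable reports. Stage artifacts are plain text (VCF, FASTA,
BED, TSV, Newick, JSON) and byte-identical under a fixed seed and config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import consensus as cons
from . import dstat as dst
from . import fst as fstmod
from . import likelihoods as lk
from . import simulate as sim
from . import structure as struct
from . import trees as trmod

log = logging.getLogger("museopop")

STAGES = ("simulate", "genotype", "windows", "trees", "twisst", "dstat",
          "fst", "structure")


@dataclass
class RunConfig:
    """Pipeline configuration; a plain YAML mapping on disk."""

    out_dir: str = "museopop_out"
    seed: int = 0
    source: str = "simulate"           # "simulate" | "files"
    pileup_tsv: str | None = None
    pop_map_path: str | None = None
    stages: Sequence[str] = STAGES
    # stage parameter blocks
    species_tree: sim.SpeciesTreeConfig = field(default_factory=sim.SpeciesTreeConfig)
    damage: sim.DamageModel = field(default_factory=sim.DamageModel)
    mean_depth: float = 20.0
    phred: int = 30
    filters: lk.FilterConfig = field(default_factory=lk.FilterConfig)
    divergence: cons.DivergenceConfig = field(default_factory=cons.DivergenceConfig)
    window_size: int = 10_000
    window_step: int = 100_000
    min_contig: int = 100_000
    fst_window: int = 50_000
    fst_pops: tuple[str, str] = ("MEL", "TRA")
    z_cutoff: float = 1.15
    k_values: Sequence[int] = (1, 2, 3, 4, 5, 6)
    admixture_reps: int = 3
    dstat_outgroup: str = "ARD"
    dstat_population_triple: tuple[str, str, str] | None = None
    bootstrap_reps: int = 0
    threads: int = 1

    def validate(self) -> None:
        if self.source not in ("simulate", "files"):
            raise ValueError("source must be 'simulate' or 'files'")
        if self.source == "files":
            for p in (self.pileup_tsv, self.pop_map_path):
                if p is None or not Path(p).exists():
                    raise ValueError(f"input path missing or nonexistent: {p}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if key == "species_tree":
                st = sim.SpeciesTreeConfig()
                for k2, v2 in val.items():
                    if k2 == "merges":
                        v2 = tuple(sim.PopulationMerge(*m) for m in v2)
                    if k2 == "pulses":
                        v2 = tuple(sim.AdmixturePulse(*p) for p in v2)
                    setattr(st, k2, v2)
                cfg.species_tree = st
            elif key == "damage":
                cfg.damage = sim.DamageModel(**val)
            elif key == "filters":
                cfg.filters = lk.FilterConfig(**val)
            elif key == "divergence":
                cfg.divergence = cons.DivergenceConfig(**val)
            elif hasattr(cfg, key):
                setattr(cfg, key, tuple(val) if isinstance(val, list) else val)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg


@dataclass
class RunReport:
    seed: int
    version: str
    parameters: dict
    stage_counts: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    stage_status: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True, default=str)


def read_population_map(path) -> dict[str, str]:
    """Two-column TSV (individual, taxon) -> mapping; duplicates rejected."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
            ind, taxon = fields[0], fields[1]
            if ind in mapping:
                raise ValueError(f"{path}:{ln}: duplicated individual {ind!r}")
            mapping[ind] = taxon
    if not mapping:
        raise ValueError(f"{path}: empty population map")
    return mapping


def write_population_map(mapping: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for ind, taxon in mapping.items():
            fh.write(f"{ind}\t{taxon}\n")


def write_site_table_vcf(table: lk.SiteTable, contig_lengths: Mapping[str, int],
                         path) -> None:
    """SiteTable as an uncompressed, bgzip-friendly VCF with FILTER strings."""
    dose = lk.hard_call(table)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=museopop\n")
        for c in table.contigs:
            fh.write(f"##contig=<ID={c},length={contig_lengths.get(c, 0)}>\n")
        for fid, desc in (("lowDP", "too many depth-filtered individuals"),
                          ("missing", "more than allowed missing individuals"),
                          ("maf", "minor allele frequency below threshold"),
                          ("triallelic", "significant third allele")):
            fh.write(f'##FILTER=<ID={fid},Description="{desc}">\n')
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="ML minor allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=PL,Number=3,Type=Integer,Description="Phred-scaled GLs">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.individuals) + "\n")
        gt_strings = ["0/0", "0/1", "1/1"]
        for s in range(table.n_sites):
            filters = []
            if table.fail_missing[s]:
                filters.append("missing")
            if table.fail_maf[s]:
                filters.append("maf")
            if table.fail_biallelic[s]:
                filters.append("triallelic")
            filt = ";".join(filters) if filters else "PASS"
            ref = chr(sim.BASE_ASCII[table.major[s]])
            alt = chr(sim.BASE_ASCII[table.minor[s]])
            cols = []
            for i in range(table.n_individuals):
                pl = np.round(-10 * table.gl[s, i] / np.log(10)).astype(int)
                gt = "./." if dose[s, i] == lk.MISSING else gt_strings[dose[s, i]]
                cols.append(f"{gt}:{table.depth[s, i]}:{pl[0]},{pl[1]},{pl[2]}")
            fh.write(f"{table.contigs[table.contig_idx[s]]}\t{table.pos[s]}\t.\t"
                     f"{ref}\t{alt}\t.\t{filt}\tMAF={table.maf[s]:.4f}\tGT:DP:PL\t"
                     + "\t".join(cols) + "\n")


def load_site_table_vcf(path) -> lk.SiteTable:
    """Rebuild a SiteTable from a multi-sample VCF (GT and PL honored)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    contigs: list[str] = []
    cmap: dict[str, int] = {}
    rows = []
    for var in vcf:
        if var.CHROM not in cmap:
            cmap[var.CHROM] = len(contigs)
            contigs.append(var.CHROM)
        gl = np.zeros((len(individuals), 3))
        depth = np.zeros(len(individuals), dtype=np.int32)
        pls = var.format("PL")
        dps = var.format("DP")
        if pls is not None:
            gl = -np.asarray(pls, dtype=np.float64) / 10.0 * np.log(10)
            gl -= gl.max(axis=1, keepdims=True)
        else:
            # fall back to certain genotypes from GT
            for i, g in enumerate(var.gt_types):
                if g != 3:   # not unknown
                    trip = np.full(3, -100.0)
                    trip[{0: 0, 1: 1, 2: 2}[g]] = 0.0
                    gl[i] = trip
        if dps is not None:
            depth = np.asarray(dps).reshape(-1).astype(np.int32)
        maf = None
        if var.INFO.get("MAF") is not None:
            maf = float(var.INFO.get("MAF"))
        rows.append((cmap[var.CHROM], var.POS, gl, depth, maf,
                     len(var.ALT) > 1))
    S, N = len(rows), len(individuals)
    table = lk.SiteTable(
        contigs=contigs,
        contig_idx=np.array([r[0] for r in rows], dtype=np.int32),
        pos=np.array([r[1] for r in rows], dtype=np.int64),
        major=np.zeros(S, dtype=np.uint8), minor=np.ones(S, dtype=np.uint8),
        maf=np.array([r[4] if r[4] is not None else np.nan for r in rows]),
        pval_snp=np.zeros(S), pval_tri=np.ones(S),
        gl=np.stack([r[2] for r in rows]) if rows else np.empty((0, N, 3)),
        depth=np.stack([r[3] for r in rows]) if rows else np.empty((0, N), np.int32),
        individuals=individuals,
    )
    multi = np.array([r[5] for r in rows], dtype=bool)
    table.pval_tri = np.where(multi, 0.0, 1.0)   # flag non-biallelic on filter
    if np.isnan(table.maf).any():
        p, _ = lk.ml_allele_frequency(table.gl, table.depth > 0)
        table.maf = np.where(np.isnan(table.maf), np.minimum(p, 1 - p), table.maf)
    return table


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full(config: RunConfig) -> RunReport:
    """Execute the configured stages in dependency order.

    A stage failure halts its dependents but independent branches complete;
    the report records per-stage status, counts, timing and a checksum
    manifest of every artifact.
    """
    from . import __version__

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    report = RunReport(seed=config.seed, version=__version__,
                       parameters=_echo_params(config))
    state: dict = {}
    deps = {
        "simulate": (), "genotype": ("simulate",) if config.source == "simulate" else (),
        "windows": ("genotype",), "trees": ("windows",), "twisst": ("trees",),
        "dstat": ("genotype",), "fst": ("genotype",), "structure": ("genotype",),
    }
    enabled = [s for s in STAGES if s in config.stages]
    if config.source == "files" and "simulate" in enabled:
        enabled.remove("simulate")
    failed: set[str] = set()
    for stage in enabled:
        if any(d in failed or (d in enabled and report.stage_status.get(d) != "ok")
               and d not in report.stage_status for d in deps[stage]):
            pass
        if any(d in failed for d in deps[stage]):
            report.stage_status[stage] = "skipped (dependency failed)"
            continue
        t0 = time.time()
        try:
            _run_stage(stage, config, state, out, report)
            report.stage_status[stage] = "ok"
        except Exception as exc:   # keep independent branches alive
            log.error("stage %s failed: %s", stage, exc)
            report.stage_status[stage] = f"failed: {exc}"
            failed.add(stage)
        report.stage_seconds[stage] = round(time.time() - t0, 3)
        log.info("stage %s: %s (%.2fs)", stage,
                 report.stage_status[stage], report.stage_seconds[stage])
    for p in sorted(out.glob("*")):
        if p.is_file():
            report.manifest[p.name] = _sha256(p)
    report.to_json(out / "report.json")
    report.manifest["report.json"] = _sha256(out / "report.json")
    return report


def _echo_params(config: RunConfig) -> dict:
    def enc(obj):
        if hasattr(obj, "__dict__"):
            return {k: enc(v) for k, v in vars(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, Mapping):
            return {k: enc(v) for k, v in obj.items()}
        return obj
    return enc(config)


def _run_stage(stage: str, config: RunConfig, state: dict, out: Path,
               report: RunReport) -> None:
    if stage == "simulate":
        st = config.species_tree
        data = sim.simulate_genealogies(st, seed=config.seed)
        panel = sim.mutate_sequences(data, seed=config.seed)
        pile = sim.generate_pileups(panel, mean_depth=config.mean_depth,
                                    phred=config.phred, seed=config.seed)
        state.update(simdata=data, panel=panel, pileup=pile,
                     pop_map=data.pop_map,
                     contig_lengths={c: st.window_length for c in data.contigs})
        sim.write_truth_vcf(data, out / "truth.vcf")
        st.save(out / "simulate.config.txt")
        write_population_map(data.pop_map, out / "pop_map.tsv")
        report.stage_counts["simulate"] = {
            "windows": len(data.windows),
            "segregating_sites": int(sum(len(w.positions) for w in data.windows)),
        }
    elif stage == "genotype":
        if config.source == "files":
            pile = sim.PileupSet.from_tsv(config.pileup_tsv,
                                          config.filters.min_base_quality)
            state["pileup"] = pile
            state["pop_map"] = read_population_map(config.pop_map_path)
            lengths: dict[str, int] = {}
            for ci, p in zip(pile.contig_idx, pile.pos):
                name = pile.contigs[ci]
                lengths[name] = max(lengths.get(name, 0), int(p))
            state["contig_lengths"] = lengths
        pile = state["pileup"]
        missing_inds = [n for n in pile.individuals if n not in state["pop_map"]]
        if missing_inds:
            raise ValueError(f"individuals absent from the population map: {missing_inds}")
        table = lk.call_snps(pile, config.filters)
        table = lk.filter_sites(table, config.filters)
        state["table"] = table
        write_site_table_vcf(table, state["contig_lengths"], out / "sites.vcf")
        table.to_dataframe().to_csv(out / "sites.tsv", sep="\t", index=False)
        report.stage_counts["genotype"] = {
            "sites_called": int(table.n_sites),
            "sites_passing": int(table.passed.sum()),
        }
    elif stage == "windows":
        pile = state["pileup"]
        calls, depth = lk.call_all_sites(pile)
        mean_depth = depth.mean(axis=0)
        by_contig: dict[str, list] = {}
        for c in np.unique(pile.contig_idx):
            m = pile.contig_idx == c
            seqs = cons.build_consensus(calls[m], depth[m], mean_depth,
                                        pile.individuals,
                                        pile.contigs[c],
                                        min_depth=config.filters.min_depth)
            by_contig[pile.contigs[c]] = seqs
        window = min(config.window_size,
                     min(state["contig_lengths"].values()))
        wins = cons.extract_windows(
            by_contig, state["contig_lengths"], window=window,
            step=config.window_step,
            min_contig=min(config.min_contig,
                           min(state["contig_lengths"].values()) - 1))
        aln, coord_map = cons.concatenate(wins)
        state["windows"] = wins
        state["concat"] = aln
        if aln.n_seqs:
            aln.to_fasta(out / "concatenated.fasta")
            dm = cons.p_distance(aln)
            dm.to_tsv(out / "p_distance.tsv")
            T = cons.divergence_generations(dm, config.divergence)
            np.savetxt(out / "divergence_generations.tsv", T, delimiter="\t",
                       header="\t".join(dm.labels), comments="")
            state["distance"] = dm
        with open(out / "windows.bed", "w") as fh:
            for w in wins:
                fh.write(f"{w.contig}\t{w.start}\t{w.end}\n")
        report.stage_counts["windows"] = {"windows_retained": len(wins),
                                          "columns": int(aln.length if aln.n_seqs else 0)}
    elif stage == "trees":
        wins = state["windows"]
        window_trees = []
        for w in wins:
            dm = cons.p_distance(w.alignment)
            if dm.undefined_pairs:
                continue
            window_trees.append((f"{w.contig}:{w.start}-{w.end}", trmod.nj_tree(dm)))
        state["window_trees"] = window_trees
        with open(out / "window_trees.nwk", "w") as fh:
            for name, tree in window_trees:
                fh.write(tree.as_string(schema="newick").strip() + "\n")
        if state.get("distance") is not None:
            point, support = trmod.bootstrap_support(
                state["concat"], n_reps=config.bootstrap_reps, seed=config.seed)
            with open(out / "concatenated_tree.nwk", "w") as fh:
                fh.write(point.as_string(schema="newick"))
        report.stage_counts["trees"] = {"window_trees": len(window_trees)}
    elif stage == "twisst":
        pop_map = state["pop_map"]
        taxa = sorted(set(pop_map.values()))
        outgroup = config.dstat_outgroup
        group_map = dict(pop_map)
        weights = []
        for name, tree in state["window_trees"]:
            weights.append(trmod.topology_weights(
                tree, group_map, outgroup=outgroup, window=name,
                seed=config.seed))
        trmod.write_weights_tsv(weights, out / "topology_weights.tsv")
        summary = trmod.weight_summary(weights)
        summary.to_csv(out / "topology_summary.tsv", sep="\t", index=False)
        report.stage_counts["twisst"] = {"windows": len(weights),
                                         "topologies": len(summary)}
    elif stage == "dstat":
        table = state["table"].passing()
        dose = lk.hard_call(table)
        results = dst.abba_baba_scan(
            dose, table.individuals, state["pop_map"],
            outgroup_taxon=config.dstat_outgroup,
            block_ids=table.contig_idx, mode="individual",
            min_blocks=min(10, max(2, len(set(table.contig_idx)))))
        df = dst.results_to_dataframe(results)
        df.to_csv(out / "dstat_individual.tsv", sep="\t", index=False)
        if config.dstat_population_triple:
            res = dst.abba_baba_scan(
                dose, table.individuals, state["pop_map"],
                outgroup_taxon=config.dstat_outgroup,
                block_ids=table.contig_idx, mode="population",
                population_triple=config.dstat_population_triple,
                min_blocks=min(10, max(2, len(set(table.contig_idx)))))
            dst.results_to_dataframe(res).to_csv(
                out / "dstat_population.tsv", sep="\t", index=False)
        report.stage_counts["dstat"] = {"comparisons": len(results)}
    elif stage == "fst":
        table = state["table"].passing()
        dose = lk.hard_call(table)
        pop_map = state["pop_map"]
        pa, pb = config.fst_pops
        ia = [i for i, n in enumerate(table.individuals) if pop_map.get(n) == pa]
        ib = [i for i, n in enumerate(table.individuals) if pop_map.get(n) == pb]
        comp = fstmod.wc_fst_components(dose, ia, ib, table.contig_idx,
                                        table.pos, table.contigs)
        track = fstmod.fst_windows(comp, state["contig_lengths"],
                                   window=config.fst_window)
        try:
            track, info = fstmod.zscore_outliers(track, z_cutoff=config.z_cutoff,
                                                 min_sites=1)
            fstmod.write_outlier_bed(track, out / "fst_outliers.bed")
        except ValueError:
            info = {"n_eligible": 0}
        track.to_dataframe().to_csv(out / "fst_windows.tsv", sep="\t", index=False)
        fstmod.write_manhattan_tsv(track, out / "fst_manhattan.tsv")
        report.stage_counts["fst"] = {"windows": int(track.n_windows),
                                      **{k: v for k, v in info.items()
                                         if isinstance(v, (int, bool))}}
    elif stage == "structure":
        table = state["table"].passing()
        dose_exp = struct.expected_genotypes(table.gl, table.maf, table.missing)
        res = struct.pca(dose_exp, table.maf)
        import pandas as pd

        pd.DataFrame(res.coordinates[:, :4],
                     index=table.individuals,
                     columns=[f"PC{i+1}" for i in range(4)]).to_csv(
            out / "pca_coordinates.tsv", sep="\t")
        lik_table, best = struct.replicate_runs(
            table.gl, k_values=config.k_values, reps=config.admixture_reps,
            seed=config.seed)
        lik_table.to_csv(out / "admixture_likelihoods.tsv", sep="\t", index=False)
        for k, model in best.items():
            pd.DataFrame(model.q, index=table.individuals,
                         columns=[f"k{j+1}" for j in range(k)]).to_csv(
                out / f"admixture_Q_K{k}.tsv", sep="\t")
        try:
            dk = struct.delta_k(lik_table)
            dk.to_dataframe().to_csv(out / "delta_k.tsv", sep="\t", index=False)
            best_k = dk.best_k
        except ValueError:
            best_k = None
        report.stage_counts["structure"] = {
            "snps_used": int(table.n_sites), "best_k": best_k}
    else:
        raise ValueError(f"unknown stage {stage!r}")
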