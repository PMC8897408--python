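"""Coalescent generator of museum-style resequencing data with known truth.

This module emulates the kind of data obtained by whole-genome resequencing
of historical study skins: a handful of populations on a species tree with
splits on the order of 1e5 generations, short DNA fragments carrying
post-mortem deamination (5' C->T, 3' G->A, decaying geometrically from the
fragment ends), and per-site pileups with phred-scaled sequencing error.

Windows are simulated independently under a discrete-event structured
coalescent (no intra-window recombination): distant genomic windows are
treated as unlinked loci, which is exactly the regime the downstream
window-based analyses assume. Mutations follow an infinite-sites
approximation with Jukes-Cantor base choice on i.i.d. uniform ancestral
bases.

Every stage is deterministic given the global seed: the seed expands to
per-stage, per-window substreams through ``stage_rng`` (numpy
``SeedSequence`` with a fixed ``spawn_key`` of stage id and window index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: base encoding used throughout: A=0, C=1, G=2, T=3
BASES = b"ACGT"
BASE_ASCII = np.frombuffer(BASES, dtype=np.uint8)
BASE_CODE = {b: i for i, b in enumerate("ACGT")}
COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)

# Fixed stage identifiers for the seed-expansion scheme. New stages append;
# existing ids never change, so seeds stay reproducible across versions.
STAGE_IDS = {
    "genealogy": 0,
    "mutate": 1,
    "fragment": 2,
    "pileup": 3,
    "bootstrap": 4,
    "topology": 5,
    "admixture": 6,
    "pca": 7,
    "pipeline": 8,
    "jackknife": 9,
}


def stage_rng(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Deterministic per-stage, per-window random generator.

    ``seed`` is the single user-facing seed; ``stage`` selects one of the
    fixed entries of :data:`STAGE_IDS` and ``index`` the window (or
    replicate) within the stage.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=(STAGE_IDS[stage], int(index)))
    return np.random.Generator(np.random.PCG64(ss))


class ConfigurationError(ValueError):
    """Raised when a demographic or damage configuration is inconsistent."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationMerge:
    """Backwards-in-time merge: at ``time`` all lineages of ``source`` join ``dest``."""

    time: float
    source: str
    dest: str


@dataclass(frozen=True)
class AdmixturePulse:
    """Forward-time pulse: a fraction ``fraction`` of ``target`` ancestry at
    ``time`` derives from ``source``.

    Backwards in time each lineage present in ``target`` at the pulse jumps
    into ``source`` with probability ``fraction``.
    """

    time: float
    source: str
    target: str
    fraction: float


DEFAULT_LABELS = ("MEL", "TRA", "ROB", "ARD", "NIG")
# Rooted species tree (((MEL,TRA),ROB),(ARD,NIG)): the continental pair splits
# most recently, the island pair (ARD,NIG) is the deep sister clade.
DEFAULT_MERGES = (
    PopulationMerge(127_000.0, "TRA", "MEL"),
    PopulationMerge(150_000.0, "NIG", "ARD"),
    PopulationMerge(224_000.0, "ROB", "MEL"),
    PopulationMerge(500_000.0, "ARD", "MEL"),
)
DEFAULT_SAMPLES = {"MEL": 6, "TRA": 5, "ROB": 3, "ARD": 1, "NIG": 1}


@dataclass
class SpeciesTreeConfig:
    """Demography, mutation and windowing parameters for the simulator.

    Defaults mirror the study system: five taxa with the sampling scheme of
    the museum series (6+5+3+1+1 diploids), split times of 127k/224k
    generations within the continental clade and a deep island clade, a
    per-site per-generation mutation rate of 4.6e-9 (collared-flycatcher
    pedigree rate, the standard passerine calibration) and 10-kb windows.
    Effective sizes default to 1e5 diploids, a typical songbird magnitude
    that reproduces the high incomplete-lineage-sorting regime of a rapid
    radiation.
    """

    labels: Sequence[str] = DEFAULT_LABELS
    merges: Sequence[PopulationMerge] = DEFAULT_MERGES
    ne: float | Mapping[str, float] = 100_000.0
    samples: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_SAMPLES))
    pulses: Sequence[AdmixturePulse] = ()
    mu: float = 4.6e-9
    window_length: int = 10_000
    n_windows: int = 100
    seed: int = 0

    def pop_size(self, label: str) -> float:
        if isinstance(self.ne, Mapping):
            return float(self.ne[label])
        return float(self.ne)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.mu <= 0:
            raise ConfigurationError("mutation rate mu must be > 0")
        if self.window_length <= 0 or self.n_windows < 0:
            raise ConfigurationError("window length must be positive")
        labels = list(self.labels)
        if len(set(labels)) != len(labels):
            raise ConfigurationError("duplicate population labels")
        for lab, n in self.samples.items():
            if lab not in labels:
                raise ConfigurationError(f"samples given for unknown population {lab!r}")
            if n < 0:
                raise ConfigurationError("negative sample size")
        if sum(self.samples.values()) == 0:
            raise ConfigurationError("no samples requested")
        for lab in labels:
            if self.pop_size(lab) <= 0:
                raise ConfigurationError(f"effective size of {lab!r} must be > 0")
        for p in self.pulses:
            if not 0.0 <= p.fraction <= 1.0:
                raise ConfigurationError("admixture fraction must lie in [0, 1]")
            if p.time <= 0:
                raise ConfigurationError("pulse time must be positive")
        # Replay merges in time order and check each merges two still-active
        # populations; this enforces child splits < parent splits.
        active = set(labels)
        for ev in sorted(self.merges, key=lambda m: m.time):
            if ev.time <= 0:
                raise ConfigurationError("split times must be strictly positive")
            if ev.source not in active or ev.dest not in active:
                raise ConfigurationError(
                    f"inconsistent split times: merge ({ev.source!r} -> {ev.dest!r}) at "
                    f"t={ev.time:g} involves an already-merged population"
                )
            active.discard(ev.source)
        if len(active) != 1 and len(labels) > 1:
            raise ConfigurationError(
                f"populations {sorted(active)} never merge into a single ancestor"
            )
        # Pulses must act between still-separate populations.
        for p in self.pulses:
            for lab in (p.source, p.target):
                gone = [m for m in self.merges if m.source == lab and m.time <= p.time]
                if gone:
                    raise ConfigurationError(
                        f"pulse at t={p.time:g} references {lab!r} after it merged"
                    )

    # -- plain-text round trip ---------------------------------------------

    def save(self, path) -> None:
        """Write the configuration as a plain-text ``key = value`` file."""
        import json

        with open(path, "w") as fh:
            fh.write(f"labels = {json.dumps(list(self.labels))}\n")
            fh.write("merges = " + json.dumps(
                [[m.time, m.source, m.dest] for m in self.merges]) + "\n")
            ne = self.ne if not isinstance(self.ne, Mapping) else dict(self.ne)
            fh.write(f"ne = {json.dumps(ne)}\n")
            fh.write(f"samples = {json.dumps(dict(self.samples))}\n")
            fh.write("pulses = " + json.dumps(
                [[p.time, p.source, p.target, p.fraction] for p in self.pulses]) + "\n")
            fh.write(f"mu = {self.mu!r}\n")
            fh.write(f"window_length = {self.window_length}\n")
            fh.write(f"n_windows = {self.n_windows}\n")
            fh.write(f"seed = {self.seed}\n")

    @classmethod
    def load(cls, path) -> "SpeciesTreeConfig":
        import json

        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                kv[key.strip()] = json.loads(val.strip())
        return cls(
            labels=tuple(kv["labels"]),
            merges=tuple(PopulationMerge(*m) for m in kv["merges"]),
            ne=kv["ne"],
            samples=kv["samples"],
            pulses=tuple(AdmixturePulse(*p) for p in kv["pulses"]),
            mu=kv["mu"],
            window_length=int(kv["window_length"]),
            n_windows=int(kv["n_windows"]),
            seed=int(kv["seed"]),
        )


@dataclass
class DamageModel:
    """Post-mortem damage and fragmentation model.

    C->T at 5' offset ``i`` occurs with probability ``d5 * decay**i`` (and
    G->A from the 3' end with ``d3 * decay**i``): the geometric decay is the
    standard shape of post-mortem deamination profiles. Fragment lengths are
    log-normal with the given mean/sd in bp, truncated to
    ``[20, window length]``. ``phred`` is the constant base quality attached
    to simulated reads; damage changes the base, never the quality.
    """

    d5: float = 0.2
    d3: float = 0.2
    decay: float = 0.5
    fragment_mean: float = 70.0
    fragment_sd: float = 30.0
    phred: int = 30

    def validate(self) -> None:
        for r in (self.d5, self.d3):
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError("damage rates must lie in [0, 1]")
        if not 0.0 < self.decay <= 1.0:
            raise ConfigurationError("decay constant must lie in (0, 1]")
        if self.fragment_mean < 20:
            raise ConfigurationError("mean fragment length must be >= 20 bp")
        if self.fragment_sd <= 0 or self.phred <= 0:
            raise ConfigurationError("fragment sd and phred must be positive")


# ---------------------------------------------------------------------------
# genealogies
# ---------------------------------------------------------------------------

@dataclass
class WindowGenealogy:
    """One simulated window: coalescent tree plus 0/1 haplotype panel."""

    parent: np.ndarray        # (n_nodes,) int32; -1 at the root
    node_time: np.ndarray     # (n_nodes,) float64, generations
    n_leaves: int
    positions: np.ndarray     # (S,) int64, 0-based within the window, sorted
    derived: np.ndarray       # (S, n_leaves) uint8, 1 = derived state
    pulse_migrants: tuple     # ((n_lineages_in_target, n_moved), ...) per pulse

    @property
    def tmrca(self) -> float:
        return float(self.node_time.max())

    def leaf_descendants(self) -> np.ndarray:
        """Boolean (n_nodes, n_leaves) matrix of leaves below each node."""
        n_nodes = len(self.parent)
        desc = np.zeros((n_nodes, self.n_leaves), dtype=bool)
        desc[np.arange(self.n_leaves), np.arange(self.n_leaves)] = True
        # nodes are created in time order, so a single ascending pass suffices
        for node in range(n_nodes):
            par = self.parent[node]
            if par >= 0:
                desc[par] |= desc[node]
        return desc

    def newick(self, leaf_labels: Sequence[str]) -> str:
        n_nodes = len(self.parent)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        root = -1
        for node, par in enumerate(self.parent):
            if par < 0:
                root = node
            else:
                children[par].append(node)

        def render(node: int) -> str:
            if node < self.n_leaves:
                name = leaf_labels[node]
            else:
                name = ""
            if children[node]:
                inner = ",".join(
                    f"{render(c)}:{self.node_time[node] - self.node_time[c]:.6g}"
                    for c in children[node]
                )
                return f"({inner}){name}"
            return name

        return render(root) + ";"


def _simulate_window(cfg: SpeciesTreeConfig, rng: np.random.Generator) -> WindowGenealogy:
    labels = list(cfg.labels)
    active: dict[str, list[int]] = {lab: [] for lab in labels}
    node = 0
    for lab in labels:
        for _ in range(2 * cfg.samples.get(lab, 0)):
            active[lab].append(node)
            node += 1
    n_leaves = node
    parent = [-1] * n_leaves
    times = [0.0] * n_leaves

    # pulses act before merges when times coincide
    events: list[tuple[float, int, int, object]] = []
    for i, p in enumerate(cfg.pulses):
        events.append((p.time, 0, i, p))
    for i, m in enumerate(cfg.merges):
        events.append((m.time, 1, i, m))
    events.sort(key=lambda e: (e[0], e[1], e[2]))

    pulse_migrants = [(0, 0)] * len(cfg.pulses)
    t = 0.0
    ei = 0
    n_active = n_leaves
    while n_active > 1:
        rates = []
        total = 0.0
        for lab in labels:
            k = len(active[lab])
            r = k * (k - 1) / (4.0 * cfg.pop_size(lab))
            rates.append(r)
            total += r
        next_ev = events[ei][0] if ei < len(events) else np.inf
        if total > 0.0:
            wait = rng.exponential(1.0 / total)
        else:
            wait = np.inf
        if t + wait >= next_ev:
            if not np.isfinite(next_ev):
                raise ConfigurationError(
                    "lineages stranded in unmergeable populations"
                )
            t = next_ev
            _, kind, idx, ev = events[ei]
            ei += 1
            if kind == 0:  # pulse
                lin = active[ev.target]
                k = len(lin)
                if k:
                    move = rng.random(k) < ev.fraction
                    moved = [lid for lid, m in zip(lin, move) if m]
                    active[ev.target] = [lid for lid, m in zip(lin, move) if not m]
                    active[ev.source].extend(moved)
                    pulse_migrants[idx] = (k, len(moved))
            else:  # merge
                active[ev.dest].extend(active[ev.source])
                active[ev.source] = []
            continue
        t += wait
        # choose the population in which the coalescence happens
        u = rng.random() * total
        acc = 0.0
        for lab, r in zip(labels, rates):
            acc += r
            if u < acc:
                chosen = lab
                break
        lin = active[chosen]
        i, j = rng.choice(len(lin), size=2, replace=False)
        a, b = lin[i], lin[j]
        new = len(parent)
        parent.append(-1)
        times.append(t)
        parent[a] = parent[b] = new
        lin[:] = [x for x in lin if x not in (a, b)]
        lin.append(new)
        n_active -= 1

    parent_arr = np.asarray(parent, dtype=np.int32)
    time_arr = np.asarray(times, dtype=np.float64)

    # mutations: Poisson per branch, uniform positions, infinite-sites
    # approximation (duplicate positions keep the first-placed mutation)
    branch = np.where(parent_arr >= 0, time_arr[parent_arr.clip(0)] - time_arr, 0.0)
    n_mut = rng.poisson(cfg.mu * cfg.window_length * branch)
    mut_nodes = np.repeat(np.arange(len(parent)), n_mut)
    positions = rng.integers(0, cfg.window_length, size=mut_nodes.size)
    uniq_pos, first = np.unique(positions, return_index=True)
    mut_nodes = mut_nodes[first]

    geneal = WindowGenealogy(
        parent=parent_arr,
        node_time=time_arr,
        n_leaves=n_leaves,
        positions=uniq_pos.astype(np.int64),
        derived=np.empty((0, n_leaves), dtype=np.uint8),
        pulse_migrants=tuple(pulse_migrants),
    )
    desc = geneal.leaf_descendants()
    geneal.derived = desc[mut_nodes].astype(np.uint8)
    return geneal


@dataclass
class SimulatedData:
    """Genealogies and haplotype panels for all windows of a run."""

    config: SpeciesTreeConfig
    individuals: list[str]
    ind_pop: list[str]
    contigs: list[str]
    windows: list[WindowGenealogy]

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def pop_map(self) -> dict[str, str]:
        return dict(zip(self.individuals, self.ind_pop))

    def true_genotypes(self, window: int) -> np.ndarray:
        """(S, n_individuals) derived-allele dosage for one window."""
        d = self.windows[window].derived
        return (d[:, 0::2] + d[:, 1::2]).astype(np.int8)


def individual_names(cfg: SpeciesTreeConfig) -> tuple[list[str], list[str]]:
    names, pops = [], []
    for lab in cfg.labels:
        for i in range(cfg.samples.get(lab, 0)):
            names.append(f"{lab}_{i + 1:02d}")
            pops.append(lab)
    return names, pops


def simulate_genealogies(cfg: SpeciesTreeConfig, seed: int | None = None) -> SimulatedData:
    """Simulate one independent genealogy + haplotype panel per window.

    Haplotypes are 0/1 ancestral/derived states at the segregating sites;
    consecutive haplotype pairs form diploid individuals, grouped by
    population in the order of ``cfg.labels``.
    """
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    names, pops = individual_names(cfg)
    windows = [
        _simulate_window(cfg, stage_rng(seed, "genealogy", w))
        for w in range(cfg.n_windows)
    ]
    contigs = [f"win{w + 1:05d}" for w in range(cfg.n_windows)]
    return SimulatedData(cfg, names, pops, contigs, windows)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass
class SequencePanel:
    """Full A/C/G/T haplotype sequences per window (codes 0..3)."""

    config: SpeciesTreeConfig
    individuals: list[str]
    ind_pop: list[str]
    contigs: list[str]
    seqs: list[np.ndarray]          # (n_hap, L) uint8 per window
    ancestral: list[np.ndarray]     # (L,) uint8 per window
    site_positions: list[np.ndarray]
    derived_base: list[np.ndarray]

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def window_length(self) -> int:
        return self.config.window_length


def mutate_sequences(sim: SimulatedData, seed: int | None = None) -> SequencePanel:
    """Turn 0/1 haplotype panels into nucleotide sequences.

    Ancestral bases are i.i.d. uniform over A/C/G/T; each derived state gets
    a Jukes-Cantor base (uniform over the three non-ancestral bases). Two
    haplotypes with TMRCA ``T`` then differ at ``2*mu*T*L`` positions in
    expectation.
    """
    cfg = sim.config
    if seed is None:
        seed = cfg.seed
    L = cfg.window_length
    seqs, ancs, poss, dbs = [], [], [], []
    for w, win in enumerate(sim.windows):
        rng = stage_rng(seed, "mutate", w)
        anc = rng.integers(0, 4, size=L, dtype=np.uint8)
        seq = np.repeat(anc[None, :], win.n_leaves, axis=0)
        pos = win.positions
        shift = rng.integers(1, 4, size=pos.size).astype(np.uint8)
        db = (anc[pos] + shift) % 4
        if pos.size:
            block = np.where(win.derived.T == 1, db[None, :], anc[pos][None, :])
            seq[:, pos] = block
        seqs.append(seq)
        ancs.append(anc)
        poss.append(pos)
        dbs.append(db)
    return SequencePanel(cfg, list(sim.individuals), list(sim.ind_pop),
                         list(sim.contigs), seqs, ancs, poss, dbs)


def iupac_individual_sequences(panel: SequencePanel, window: int) -> np.ndarray:
    """(n_ind, L) ASCII array of diploid consensus bases with IUPAC hets."""
    from .consensus import IUPAC_PAIR_ASCII

    seq = panel.seqs[window]
    h1 = seq[0::2]
    h2 = seq[1::2]
    return IUPAC_PAIR_ASCII[h1, h2]


# ---------------------------------------------------------------------------
# fragments and damage
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Short fragments with per-base quality, strand and end offsets.

    Sequences are stored flattened (``offsets`` delimits reads) in read
    orientation: minus-strand fragments hold the reverse complement of the
    source haplotype. ``ref`` is the aligned, damage-free reference in the
    same orientation, used by damage profiling.
    """

    window: np.ndarray      # (R,) int32
    ind: np.ndarray         # (R,) int32
    hap: np.ndarray         # (R,) uint8 (0/1 within the individual)
    start: np.ndarray       # (R,) int64, 0-based on the window
    length: np.ndarray      # (R,) int64
    strand: np.ndarray      # (R,) uint8, 0='+', 1='-'
    seq: np.ndarray         # flattened uint8 codes
    ref: np.ndarray         # flattened uint8 codes (pre-damage)
    offsets: np.ndarray     # (R+1,) int64 into seq/ref
    qual: int
    individuals: list[str]
    contigs: list[str]

    @property
    def n_reads(self) -> int:
        return len(self.start)

    def read_seq(self, i: int) -> np.ndarray:
        return self.seq[self.offsets[i]:self.offsets[i + 1]]

    def read_ref(self, i: int) -> np.ndarray:
        return self.ref[self.offsets[i]:self.offsets[i + 1]]

    def read_str(self, i: int) -> str:
        return BASE_ASCII[self.read_seq(i)].tobytes().decode()

    def subset(self, mask: np.ndarray) -> "ReadSet":
        mask = np.asarray(mask, dtype=bool)
        keep = np.flatnonzero(mask)
        base_keep = np.concatenate([
            np.arange(self.offsets[i], self.offsets[i + 1]) for i in keep
        ]) if keep.size else np.empty(0, dtype=np.int64)
        lengths = self.length[keep]
        return ReadSet(
            window=self.window[keep], ind=self.ind[keep], hap=self.hap[keep],
            start=self.start[keep], length=lengths, strand=self.strand[keep],
            seq=self.seq[base_keep], ref=self.ref[base_keep],
            offsets=np.concatenate([[0], np.cumsum(lengths)]),
            qual=self.qual, individuals=self.individuals, contigs=self.contigs,
        )


def fragment_and_damage(panel: SequencePanel, damage: DamageModel,
                        mean_depth: float = 20.0,
                        seed: int | None = None) -> ReadSet:
    """Shear haplotypes into fragments and apply deamination damage.

    The number of fragments per individual per window targets ``mean_depth``
    given the mean fragment length. Damage converts C->T with probability
    ``d5 * decay**i`` at 5' offset ``i`` and G->A with ``d3 * decay**i``
    from the 3' end, on the fragment in read orientation. Base qualities are
    untouched: damage is a real base change, not a quality event.
    """
    damage.validate()
    cfg = panel.config
    if seed is None:
        seed = cfg.seed
    L = cfg.window_length
    n_ind = panel.n_individuals
    reads_per_ind = max(1, int(round(mean_depth * L / damage.fragment_mean)))

    sigma2 = np.log1p((damage.fragment_sd / damage.fragment_mean) ** 2)
    mu_ln = np.log(damage.fragment_mean) - sigma2 / 2.0

    win_l, ind_l, hap_l, start_l, len_l, strand_l, seq_l, ref_l = ([] for _ in range(8))
    for w, seq in enumerate(panel.seqs):
        rng = stage_rng(seed, "fragment", w)
        n = reads_per_ind * n_ind
        ind = np.repeat(np.arange(n_ind, dtype=np.int32), reads_per_ind)
        hap = rng.integers(0, 2, size=n, dtype=np.uint8)
        length = np.clip(
            np.round(rng.lognormal(mu_ln, np.sqrt(sigma2), size=n)), 20, L
        ).astype(np.int64)
        start = (rng.random(n) * (L - length + 1)).astype(np.int64)
        strand = rng.integers(0, 2, size=n, dtype=np.uint8)

        # flattened extraction
        total = int(length.sum())
        offs = np.concatenate([[0], np.cumsum(length)])
        base_read = np.repeat(np.arange(n), length)
        within = np.arange(total) - offs[base_read]
        src_pos = start[base_read] + within
        hap_idx = (2 * ind + hap)[base_read]
        frag = seq[hap_idx, src_pos]
        # reverse-complement minus-strand fragments (read orientation)
        minus = strand[base_read] == 1
        rc_within = length[base_read] - 1 - within
        src_pos_rc = start[base_read] + rc_within
        frag = np.where(minus, COMPLEMENT[seq[hap_idx, src_pos_rc]], frag)
        ref = frag.copy()

        # geometric deamination from both ends
        off5 = within
        off3 = length[base_read] - 1 - within
        u = rng.random(total)
        ct = (frag == BASE_CODE["C"]) & (u < damage.d5 * damage.decay ** off5)
        u2 = rng.random(total)
        ga = (frag == BASE_CODE["G"]) & (u2 < damage.d3 * damage.decay ** off3)
        frag = frag.copy()
        frag[ct] = BASE_CODE["T"]
        frag[ga] = BASE_CODE["A"]

        win_l.append(np.full(n, w, dtype=np.int32))
        ind_l.append(ind)
        hap_l.append(hap)
        start_l.append(start)
        len_l.append(length)
        strand_l.append(strand)
        seq_l.append(frag)
        ref_l.append(ref)

    lengths = np.concatenate(len_l)
    return ReadSet(
        window=np.concatenate(win_l), ind=np.concatenate(ind_l),
        hap=np.concatenate(hap_l), start=np.concatenate(start_l),
        length=lengths, strand=np.concatenate(strand_l),
        seq=np.concatenate(seq_l), ref=np.concatenate(ref_l),
        offsets=np.concatenate([[0], np.cumsum(lengths)]),
        qual=damage.phred, individuals=list(panel.individuals),
        contigs=list(panel.contigs),
    )


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

@dataclass
class PileupSet:
    """Per-site, per-individual observed base counts with qualities.

    ``counts`` is (n_sites, n_individuals, 4). When all bases share one
    phred score, ``qual`` holds it and per-read log-likelihood sufficient
    statistics are derived on the fly; heterogeneous qualities (e.g. from a
    pileup TSV) are carried in ``suff`` (see :mod:`museopop.likelihoods`).
    """

    contigs: list[str]
    contig_idx: np.ndarray   # (S,) int32
    pos: np.ndarray          # (S,) int64, 1-based
    counts: np.ndarray       # (S, N, 4) uint16
    individuals: list[str]
    qual: float | None = 30.0
    suff: np.ndarray | None = None   # (S, N, 4, 3) float64

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=2, dtype=np.int64)

    # -- TSV round trip -----------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write per-base records: contig pos individual base phred strand off5 off3.

        Count-based pileups have no read provenance, so strand and offsets
        are written as ``.``.
        """
        q = int(self.qual) if self.qual is not None else 30
        with open(path, "w") as fh:
            fh.write("contig\tpos\tindividual\tbase\tphred\tstrand\toffset5\toffset3\n")
            for s in range(self.n_sites):
                contig = self.contigs[self.contig_idx[s]]
                for i, name in enumerate(self.individuals):
                    for b in range(4):
                        for _ in range(int(self.counts[s, i, b])):
                            fh.write(
                                f"{contig}\t{self.pos[s]}\t{name}\t{chr(BASES[b])}"
                                f"\t{q}\t.\t.\t.\n"
                            )

    @classmethod
    def from_tsv(cls, path, min_base_quality: int = 20) -> "PileupSet":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"contig": str, "base": str})
        df = df[df["phred"] >= min_base_quality]
        contigs = list(dict.fromkeys(df["contig"]))
        individuals = sorted(df["individual"].unique())
        cmap = {c: i for i, c in enumerate(contigs)}
        imap = {n: i for i, n in enumerate(individuals)}
        sites = df[["contig", "pos"]].drop_duplicates().sort_values(
            ["contig", "pos"], key=lambda col: col.map(cmap) if col.name == "contig" else col
        )
        skey = {(c, p): s for s, (c, p) in enumerate(zip(sites["contig"], sites["pos"]))}
        S, N = len(skey), len(individuals)
        counts = np.zeros((S, N, 4), dtype=np.uint16)
        suff = np.zeros((S, N, 4, 3), dtype=np.float64)
        for row in df.itertuples(index=False):
            s = skey[(row.contig, row.pos)]
            i = imap[row.individual]
            b = BASE_CODE[row.base]
            counts[s, i, b] += 1
            eps = 10.0 ** (-row.phred / 10.0)
            suff[s, i, b, 0] += np.log(1.0 - eps)
            suff[s, i, b, 1] += np.log(eps / 3.0)
            suff[s, i, b, 2] += np.log(0.5 * (1.0 - eps) + 0.5 * eps / 3.0)
        return cls(
            contigs=contigs,
            contig_idx=np.array([cmap[c] for c in sites["contig"]], dtype=np.int32),
            pos=sites["pos"].to_numpy(dtype=np.int64),
            counts=counts, individuals=individuals, qual=None, suff=suff,
        )


def _pileup_counts_from_haplotypes(h1: np.ndarray, h2: np.ndarray,
                                   mean_depth: float, err: float,
                                   rng: np.random.Generator) -> np.ndarray:
    """Vectorised per-site counts for one diploid individual."""
    L = len(h1)
    counts = np.zeros((L, 4), dtype=np.int64)
    depth = rng.poisson(mean_depth, size=L)
    from_h1 = rng.binomial(depth, 0.5)
    rows = np.arange(L)
    for hap, n in ((h1, from_h1), (h2, depth - from_h1)):
        correct = rng.binomial(n, 1.0 - err)
        errs = n - correct
        counts[rows, hap] += correct
        e1 = rng.binomial(errs, 1.0 / 3.0)
        e2 = rng.binomial(errs - e1, 0.5)
        e3 = errs - e1 - e2
        counts[rows, (hap + 1) % 4] += e1
        counts[rows, (hap + 2) % 4] += e2
        counts[rows, (hap + 3) % 4] += e3
    return counts


def generate_pileups(source: SequencePanel | ReadSet,
                     mean_depth: float = 20.0,
                     phred: int = 30,
                     seed: int | None = None,
                     positions: Mapping[int, np.ndarray] | None = None) -> PileupSet:
    """Sample sequencing reads into per-site base counts.

    From a :class:`SequencePanel`, depth is Poisson(``mean_depth``) per site
    per individual, each read drawn from one of the two haplotypes, and
    sequencing errors hit uniformly one of the three non-true bases at rate
    ``10**(-phred/10)``. ``positions`` optionally restricts output to given
    0-based window positions (sparse pileups over candidate sites).

    From a :class:`ReadSet`, counts aggregate the (damaged) fragments, with
    the same uniform error model applied per sequenced base; ``mean_depth``
    is ignored since depth is set by the fragments themselves.
    """
    if isinstance(source, ReadSet):
        return _pileups_from_reads(source, seed=seed, positions=positions)
    panel = source
    cfg = panel.config
    if seed is None:
        seed = cfg.seed
    err = 10.0 ** (-phred / 10.0)
    N = panel.n_individuals
    contig_idx_l, pos_l, counts_l = [], [], []
    for w, seq in enumerate(panel.seqs):
        rng = stage_rng(seed, "pileup", w)
        if positions is not None:
            pos = np.asarray(positions.get(w, ()), dtype=np.int64)
            if pos.size == 0:
                continue
        else:
            pos = np.arange(cfg.window_length, dtype=np.int64)
        counts = np.zeros((len(pos), N, 4), dtype=np.int64)
        for i in range(N):
            counts[:, i, :] = _pileup_counts_from_haplotypes(
                seq[2 * i, pos], seq[2 * i + 1, pos], mean_depth, err, rng
            )
        contig_idx_l.append(np.full(len(pos), w, dtype=np.int32))
        pos_l.append(pos + 1)  # 1-based
        counts_l.append(counts)
    counts = np.concatenate(counts_l) if counts_l else np.zeros((0, N, 4), dtype=np.int64)
    return PileupSet(
        contigs=list(panel.contigs),
        contig_idx=np.concatenate(contig_idx_l) if contig_idx_l else np.empty(0, np.int32),
        pos=np.concatenate(pos_l) if pos_l else np.empty(0, np.int64),
        counts=np.minimum(counts, np.iinfo(np.uint16).max).astype(np.uint16),
        individuals=list(panel.individuals),
        qual=float(phred),
    )


def _pileups_from_reads(reads: ReadSet, seed: int | None = None,
                        positions: Mapping[int, np.ndarray] | None = None) -> PileupSet:
    if seed is None:
        seed = 0
    rng = stage_rng(seed, "pileup", 0)
    err = 10.0 ** (-reads.qual / 10.0)
    n_windows = len(reads.contigs)
    N = len(reads.individuals)

    base_read = np.repeat(np.arange(reads.n_reads), reads.length)
    within = np.arange(len(reads.seq)) - reads.offsets[base_read]
    # map back to window coordinates (minus strand reads run backwards)
    fwd = reads.start[base_read] + within
    rev = reads.start[base_read] + reads.length[base_read] - 1 - within
    win_pos = np.where(reads.strand[base_read] == 1, rev, fwd)
    base = np.where(reads.strand[base_read] == 1, COMPLEMENT[reads.seq], reads.seq)
    # sequencing error on top of damage
    e = rng.random(len(base)) < err
    base = np.where(e, (base + rng.integers(1, 4, size=len(base))) % 4, base)

    win = reads.window[base_read].astype(np.int64)
    ind = reads.ind[base_read]
    if positions is not None:
        keep = np.zeros(len(base), dtype=bool)
        for w in range(n_windows):
            wanted = np.asarray(positions.get(w, ()), dtype=np.int64)
            if wanted.size:
                keep |= (win == w) & np.isin(win_pos, wanted)
        win, win_pos, ind, base = win[keep], win_pos[keep], ind[keep], base[keep]

    # one site per covered (window, position), in genomic order
    order = np.lexsort((win_pos, win))
    win_s, pos_s, ind_s, base_s = win[order], win_pos[order], ind[order], base[order]
    uniq, inv = np.unique(np.stack([win_s, pos_s]), axis=1, return_inverse=True)
    S = uniq.shape[1]
    counts = np.zeros((S, N, 4), dtype=np.int64)
    np.add.at(counts, (inv, ind_s, base_s), 1)
    return PileupSet(
        contigs=list(reads.contigs),
        contig_idx=uniq[0].astype(np.int32),
        pos=uniq[1].astype(np.int64) + 1,
        counts=np.minimum(counts, np.iinfo(np.uint16).max).astype(np.uint16),
        individuals=list(reads.individuals),
        qual=float(reads.qual),
    )


# ---------------------------------------------------------------------------
# truth output
# ---------------------------------------------------------------------------

@dataclass
class TruthSet:
    """Ground truth for parameter-recovery tests."""

    genotypes: list[np.ndarray]       # per window (S, n_ind) dosage
    split_times: dict[str, float]     # "SRC>DST" -> generations
    admixture: tuple                  # config pulses
    damage: DamageModel | None

    @classmethod
    def from_simulation(cls, sim: SimulatedData,
                        damage: DamageModel | None = None) -> "TruthSet":
        cfg = sim.config
        return cls(
            genotypes=[sim.true_genotypes(w) for w in range(len(sim.windows))],
            split_times={f"{m.source}>{m.dest}": m.time for m in cfg.merges},
            admixture=tuple(cfg.pulses),
            damage=damage,
        )


def write_truth_vcf(sim: SimulatedData, path) -> None:
    """True diploid genotypes as an uncompressed VCF (contigs win00001...)."""
    cfg = sim.config
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=museopop-simulate\n")
        for c in sim.contigs:
            fh.write(f"##contig=<ID={c},length={cfg.window_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sim.individuals) + "\n")
        gts = ["0/0", "0/1", "1/1"]
        for w, win in enumerate(sim.windows):
            dose = sim.true_genotypes(w)
            for s, p in enumerate(win.positions):
                row = "\t".join(gts[d] for d in dose[s])
                fh.write(f"{sim.contigs[w]}\t{p + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{row}\n")


def write_haplotype_fasta(panel: SequencePanel, path) -> None:
    """Haplotype sequences as FASTA, one record per haplotype per window."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for w, seq in enumerate(panel.seqs):
        for h in range(seq.shape[0]):
            name = f"{panel.contigs[w]}|{panel.individuals[h // 2]}|hap{h % 2 + 1}"
            records.append(SeqRecord(Seq(BASE_ASCII[seq[h]].tobytes().decode()),
                                     id=name, description=""))
    SeqIO.write(records, str(path), "fasta")
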