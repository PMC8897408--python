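"""Consensus sequences, window alignments, p-distances, divergence times.

Divergence dating here is deliberately simple: uncorrected p-distances on
masked IUPAC consensus sequences, scaled by a pedigree mutation rate. Two
lineages separated ``T`` generations ago accumulate mutations independently,
so ``p = 2 * mu * T`` and ``T = p / (2 * mu)``; multiplying by a generation
length in years gives absolute time. The approximation ignores ancestral
polymorphism, which inflates estimates by roughly ``2 * Ne`` generations —
acceptable when splits are much older than the coalescent time scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np


# IUPAC encoding of unordered diploid base pairs
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
}
IUPAC_CODES = "ACGTMRWSYK"
_ALLELES = {c: p for p, c in _IUPAC.items()}

#: (4, 4) ASCII IUPAC code for an (allele1, allele2) base-code pair
IUPAC_PAIR_ASCII = np.zeros((4, 4), dtype=np.uint8)
for i, bi in enumerate("ACGT"):
    for j, bj in enumerate("ACGT"):
        IUPAC_PAIR_ASCII[i, j] = ord(_IUPAC[frozenset((bi, bj))])

# scoring table over IUPAC codes: identical codes score 0; otherwise the
# expected allele mismatch between one random allele from each genotype
# (het vs compatible hom = 0.5, het vs incompatible hom = 1, two hets
# sharing one allele = 0.75)
_N_CODES = len(IUPAC_CODES)
_CODE_IDX = np.full(256, -1, dtype=np.int16)
for k, c in enumerate(IUPAC_CODES):
    _CODE_IDX[ord(c)] = k
SCORE_TABLE = np.zeros((_N_CODES, _N_CODES))
for i, ci in enumerate(IUPAC_CODES):
    for j, cj in enumerate(IUPAC_CODES):
        if i == j:
            continue
        ai = sorted(_ALLELES[ci]) * (2 if len(_ALLELES[ci]) == 1 else 1)
        aj = sorted(_ALLELES[cj]) * (2 if len(_ALLELES[cj]) == 1 else 1)
        SCORE_TABLE[i, j] = np.mean([x != y for x in ai for y in aj])


def iupac_code(allele1: str, allele2: str) -> str:
    return _IUPAC[frozenset((allele1, allele2))]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

MASK_NONE, MASK_LOW_DEPTH, MASK_HIGH_DEPTH, MASK_NO_CALL = 0, 1, 2, 3


@dataclass
class ConsensusSequence:
    """Masked IUPAC consensus for one individual on one contig."""

    individual: str
    contig: str
    seq: np.ndarray        # ASCII uint8, masked positions are 'N'
    mask_reason: np.ndarray  # uint8 track (MASK_* constants)

    def __len__(self) -> int:
        return len(self.seq)

    def __str__(self) -> str:
        return self.seq.tobytes().decode()


@dataclass
class Alignment:
    """Equal-length sequences over a shared individual set."""

    labels: list[str]
    seqs: np.ndarray       # (N, L) ASCII uint8

    @property
    def n_seqs(self) -> int:
        return len(self.labels)

    @property
    def length(self) -> int:
        return self.seqs.shape[1]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for lab, row in zip(self.labels, self.seqs):
                fh.write(f">{lab}\n{row.tobytes().decode()}\n")

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        labels, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            rows.append(np.frombuffer(str(rec.seq).upper().encode(), dtype=np.uint8))
        return cls(labels, np.vstack(rows))


@dataclass
class WindowAlignment:
    contig: str
    start: int             # 0-based half-open
    end: int
    alignment: Alignment
    completeness: np.ndarray   # per-individual fraction of non-N positions


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray          # symmetric, zero diagonal; NaN where undefined
    n_compared: np.ndarray      # per-pair compared columns

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isfinite(self.matrix[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)\
            .to_csv(path, sep="\t")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.matrix):
                fh.write(lab + "  " + "  ".join(f"{v:.8f}" for v in row) + "\n")


@dataclass
class DivergenceConfig:
    """Mutation-rate and generation-length calibration."""

    mu: float = 4.6e-9          # per site per generation
    generation_years: float = 3.7

    def validate(self) -> None:
        if self.mu <= 0 or self.generation_years <= 0:
            raise ValueError("mu and generation length must be > 0")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_consensus(calls: np.ndarray, depth: np.ndarray,
                    mean_depth: Sequence[float], individuals: Sequence[str],
                    contig: str, min_depth: int = 10,
                    max_depth_factor: float = 3.0) -> list[ConsensusSequence]:
    """IUPAC consensus per individual with depth masking.

    ``calls`` is (L, N, 2) allele codes (missing = -1); sites with depth
    below ``min_depth`` (inclusive boundary: depth == min_depth stays) or
    strictly above ``max_depth_factor`` times the individual's mean depth
    are masked to N, as are uncalled sites.
    """
    L, N, _ = calls.shape
    out = []
    for i, name in enumerate(individuals):
        md = float(mean_depth[i])
        if md <= 0:
            raise ValueError(f"mean depth of individual {name!r} is zero")
        a1 = calls[:, i, 0]
        a2 = calls[:, i, 1]
        ok = a1 >= 0
        seq = np.full(L, ord("N"), dtype=np.uint8)
        seq[ok] = IUPAC_PAIR_ASCII[a1[ok], a2[ok]]
        reason = np.full(L, MASK_NONE, dtype=np.uint8)
        reason[~ok] = MASK_NO_CALL
        low = depth[:, i] < min_depth
        high = depth[:, i] > max_depth_factor * md
        seq[low | high] = ord("N")
        reason[high] = MASK_HIGH_DEPTH
        reason[low] = MASK_LOW_DEPTH
        out.append(ConsensusSequence(name, contig, seq, reason))
    return out


def extract_windows(consensus: Mapping[str, Sequence[ConsensusSequence]],
                    contig_lengths: Mapping[str, int],
                    window: int = 10_000, step: int = 100_000,
                    min_contig: int = 100_000,
                    min_column_fraction: float = 0.5,
                    min_individual_fraction: float = 0.5) -> list[WindowAlignment]:
    """Tile distant windows across long contigs and keep well-covered ones.

    Windows start at offsets 0, ``step``, 2*``step``, ... on contigs whose
    length strictly exceeds ``min_contig``, wherever the full window fits.
    A window is retained iff at least ``min_column_fraction`` of its columns
    have non-N data in at least ``min_individual_fraction`` of individuals.
    """
    out = []
    for contig, seqs in consensus.items():
        length = contig_lengths[contig]
        if length <= min_contig:
            continue
        labels = [c.individual for c in seqs]
        mat = np.vstack([c.seq for c in seqs])
        n_ind = len(labels)
        for start in range(0, length - window + 1, step):
            sl = mat[:, start:start + window]
            has_data = sl != ord("N")
            covered = has_data.sum(axis=0) >= min_individual_fraction * n_ind
            if covered.sum() >= min_column_fraction * window:
                out.append(WindowAlignment(
                    contig=contig, start=start, end=start + window,
                    alignment=Alignment(labels, sl.copy()),
                    completeness=has_data.mean(axis=1),
                ))
    return out


def concatenate(windows: Sequence[WindowAlignment]):
    """Concatenate window alignments into a supermatrix.

    Returns ``(alignment, coordinate_map)`` where the map lists
    ``(contig, start, end, concat_offset)`` per window and is invertible via
    :func:`map_column`.
    """
    if not windows:
        return Alignment([], np.empty((0, 0), dtype=np.uint8)), []
    labels = windows[0].alignment.labels
    for w in windows[1:]:
        if w.alignment.labels != labels:
            bad = sorted(set(w.alignment.labels) ^ set(labels))
            raise ValueError(f"window individual sets differ: {bad}")
    offset = 0
    coord_map = []
    blocks = []
    for w in windows:
        blocks.append(w.alignment.seqs)
        coord_map.append((w.contig, w.start, w.end, offset))
        offset += w.end - w.start
    return Alignment(labels, np.hstack(blocks)), coord_map


def map_column(coord_map, concat_col: int):
    """Invert the concatenation: column index -> (window index, offset)."""
    for wi, (_, start, end, off) in enumerate(coord_map):
        if off <= concat_col < off + (end - start):
            return wi, concat_col - off
    raise IndexError(f"column {concat_col} outside the concatenation")


def p_distance(alignment: Alignment) -> DistanceMatrix:
    """Uncorrected pairwise distances with pairwise deletion.

    Columns with N (or any non-IUPAC symbol) in either sequence are skipped
    for that pair. IUPAC heterozygotes score fractionally (see
    ``SCORE_TABLE``); a pair with zero comparable columns gets NaN.
    """
    if alignment.n_seqs < 2:
        raise ValueError("p_distance needs at least two sequences")
    enc = _CODE_IDX[alignment.seqs]           # (N, L), -1 for N/unknown
    n = alignment.n_seqs
    dist = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            ok = (enc[i] >= 0) & (enc[j] >= 0)
            m = int(ok.sum())
            comp[i, j] = comp[j, i] = m
            if m == 0:
                dist[i, j] = dist[j, i] = np.nan
                continue
            d = SCORE_TABLE[enc[i, ok], enc[j, ok]].sum() / m
            dist[i, j] = dist[j, i] = d
    return DistanceMatrix(list(alignment.labels), dist, comp)


def divergence_generations(dm: DistanceMatrix,
                           config: DivergenceConfig | None = None) -> np.ndarray:
    """Pairwise divergence times in generations, ``T = p / (2 mu)``."""
    if config is None:
        config = DivergenceConfig()
    config.validate()
    return dm.matrix / (2.0 * config.mu)


def generations_to_years(generations: np.ndarray,
                         generation_years: float = 3.7) -> np.ndarray:
    if generation_years <= 0:
        raise ValueError("generation length must be > 0")
    return np.asarray(generations) * generation_years


def mean_between_population_time(dm: DistanceMatrix,
                                 pop_map: Mapping[str, str],
                                 pop_a: str, pop_b: str,
                                 config: DivergenceConfig | None = None) -> float:
    """Mean pairwise divergence time (generations) between two populations."""
    T = divergence_generations(dm, config)
    ia = [k for k, lab in enumerate(dm.labels) if pop_map[lab] == pop_a]
    ib = [k for k, lab in enumerate(dm.labels) if pop_map[lab] == pop_b]
    if not ia or not ib:
        raise ValueError("population without individuals in the matrix")
    return float(np.nanmean(T[np.ix_(ia, ib)]))
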