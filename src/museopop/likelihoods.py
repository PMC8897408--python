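"""Genotype likelihoods, SNP calling and the hard filter cascade.

Likelihoods follow the classic per-read mixture model: a read carrying base
``b`` supports allele ``a`` with probability ``1 - eps`` if ``b == a`` and
``eps / 3`` otherwise, where ``eps = 10**(-Q/10)``. A diploid genotype is an
equal mixture of its two alleles, and the per-site genotype likelihood is
the product over reads. This is the model low-coverage callers apply to
degraded museum DNA, where carrying the full likelihood triple through the
analyses is safer than committing to hard genotypes.

SNP discovery estimates the maximum-likelihood minor-allele frequency by EM
over the genotype likelihoods and tests it against frequency zero with a
likelihood-ratio test whose null is the boundary mixture
``0.5*delta_0 + 0.5*chi2(1)`` (the frequency sits on the edge of its
parameter space under H0). An analogous test against the third-most-common
allele rejects triallelic sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .simulate import BASE_ASCII, BASE_CODE, PileupSet, ReadSet

MISSING = np.int8(-1)   # sentinel for missing genotypes, never silently 0


@dataclass
class FilterConfig:
    """Thresholds of the site filter cascade."""

    min_base_quality: int = 20
    min_mapping_quality: int = 20
    snp_pvalue: float = 1e-6
    min_depth: int = 10
    max_depth: int = 100
    max_missing: int = 1          # sites fail when MORE individuals are missing
    min_maf: float = 0.12

    def validate(self) -> None:
        if self.min_depth >= self.max_depth:
            raise ValueError("depth bounds require min < max")
        if min(self.min_base_quality, self.min_mapping_quality) < 0:
            raise ValueError("quality thresholds must be non-negative")
        if not (0 < self.snp_pvalue < 1) or not (0 <= self.min_maf <= 0.5):
            raise ValueError("thresholds out of range")


def min_minor_allele_chromosomes(n_diploids: int, min_maf: float = 0.12) -> int:
    """Smallest minor-allele chromosome count compatible with the MAF cutoff.

    With ``n`` diploids a passing site needs ``c / (2n) >= min_maf``, i.e.
    ``c = ceil(2n * min_maf)`` chromosomes supporting the minor allele.
    """
    return int(np.ceil(2 * n_diploids * min_maf))


# ---------------------------------------------------------------------------
# per-read likelihood machinery
# ---------------------------------------------------------------------------

def _read_constants(q: np.ndarray | float):
    eps = 10.0 ** (-np.asarray(q, dtype=np.float64) / 10.0)
    return (np.log(1.0 - eps),
            np.log(eps / 3.0),
            np.log(0.5 * (1.0 - eps) + 0.5 * eps / 3.0))


def _suff_stats(pileup: PileupSet) -> np.ndarray:
    """(S, N, 4, 3) sums of per-read log terms (match / mismatch / het-mix)."""
    if pileup.suff is not None:
        return pileup.suff
    lm, lx, lh = _read_constants(pileup.qual)
    return pileup.counts[..., None].astype(np.float64) * np.array([lm, lx, lh])


def genotype_likelihood(bases: Sequence[str] | np.ndarray,
                        quals: Sequence[float] | np.ndarray,
                        allele1: str, allele2: str,
                        normalize: bool = True) -> np.ndarray:
    """Likelihood triple (hom-``allele1``, het, hom-``allele2``) for one
    individual at one site, on a natural-log scale.

    With ``normalize`` the maximum of the triple is shifted to 0; otherwise
    raw log-likelihoods are returned. An empty read set yields a flat triple
    of zeros — a missing-data marker rather than an exception.
    """
    codes = np.array([BASE_CODE[b] for b in bases], dtype=np.int64)
    q = np.asarray(quals, dtype=np.float64)
    if codes.size == 0:
        return np.zeros(3)
    a1, a2 = BASE_CODE[allele1], BASE_CODE[allele2]
    lm, lx, lh = _read_constants(q)
    hom1 = np.where(codes == a1, lm, lx).sum()
    hom2 = np.where(codes == a2, lm, lx).sum()
    het = np.where((codes == a1) | (codes == a2), lh, lx).sum()
    out = np.array([hom1, het, hom2])
    if normalize:
        out = out - out.max()
    return out


def site_genotype_log_likelihoods(pileup: PileupSet, a1: np.ndarray,
                                  a2: np.ndarray) -> np.ndarray:
    """(S, N, 3) normalized log-likelihood triples for per-site allele pairs.

    ``a1``/``a2`` give the (major, minor) base codes per site. Individuals
    with zero depth receive a flat triple (missing marker).
    """
    suff = _suff_stats(pileup)            # (S, N, 4, 3)
    S, N = suff.shape[:2]
    rows = np.arange(S)
    s_match = suff[..., 0]
    s_mis = suff[..., 1]
    s_het = suff[..., 2]
    mis_total = s_mis.sum(axis=2)
    hom1 = s_match[rows, :, a1] + mis_total - s_mis[rows, :, a1]
    hom2 = s_match[rows, :, a2] + mis_total - s_mis[rows, :, a2]
    het = (s_het[rows, :, a1] + s_het[rows, :, a2]
           + mis_total - s_mis[rows, :, a1] - s_mis[rows, :, a2])
    gl = np.stack([hom1, het, hom2], axis=2)
    gl -= gl.max(axis=2, keepdims=True)
    return gl


# ---------------------------------------------------------------------------
# allele-frequency EM and the site table
# ---------------------------------------------------------------------------

def ml_allele_frequency(gl: np.ndarray, usable: np.ndarray | None = None,
                        p0: float = 0.25, tol: float = 1e-8,
                        max_iter: int = 100):
    """EM estimate of the minor-allele frequency from genotype likelihoods.

    ``gl`` is (S, N, 3) natural-log, genotype = minor-allele count, with a
    Hardy-Weinberg prior at the current frequency. Returns ``(p, logl)``
    where ``logl`` is the per-site log-likelihood at the estimate.
    Starts at ``p0 = 0.25`` and stops at ``|dp| < tol`` or ``max_iter``.
    """
    lik = np.exp(gl)
    S, N = lik.shape[:2]
    if usable is None:
        usable = np.ones((S, N), dtype=bool)
    w = usable.astype(np.float64)
    n_eff = np.maximum(w.sum(axis=1), 1e-12)
    p = np.full(S, p0)
    for _ in range(max_iter):
        pri = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=1)[:, None, :]
        num = lik * pri
        tot = np.maximum(num.sum(axis=2), 1e-300)
        eg = (num[..., 1] + 2.0 * num[..., 2]) / tot
        p_new = (eg * w).sum(axis=1) / (2.0 * n_eff)
        done = np.abs(p_new - p).max() < tol
        p = p_new
        if done:
            break
    pri = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=1)[:, None, :]
    tot = np.maximum((lik * pri).sum(axis=2), 1e-300)
    logl = (np.log(tot) * w).sum(axis=1)
    return p, logl


def _snp_lrt_pvalue(logl_alt: np.ndarray, logl_null: np.ndarray) -> np.ndarray:
    """Boundary-mixture p-value: 0.5*delta_0 + 0.5*chi2(1)."""
    lrt = 2.0 * (logl_alt - logl_null)
    pv = np.where(lrt > 0, 0.5 * stats.chi2.sf(np.maximum(lrt, 0.0), df=1), 1.0)
    return pv


@dataclass
class SiteTable:
    """Called biallelic SNPs with per-individual genotype likelihoods."""

    contigs: list[str]
    contig_idx: np.ndarray      # (S,)
    pos: np.ndarray             # (S,) 1-based
    major: np.ndarray           # (S,) base codes
    minor: np.ndarray
    maf: np.ndarray             # ML minor-allele frequency, in [0, 0.5]
    pval_snp: np.ndarray
    pval_tri: np.ndarray
    gl: np.ndarray              # (S, N, 3) natural log, max 0
    depth: np.ndarray           # (S, N)
    individuals: list[str]
    missing: np.ndarray = None  # (S, N) bool; depth-filtered or no data
    fail_missing: np.ndarray = None
    fail_maf: np.ndarray = None
    fail_biallelic: np.ndarray = None
    filtered: bool = False

    def __post_init__(self):
        S = len(self.pos)
        if self.missing is None:
            self.missing = self.depth == 0
        for name in ("fail_missing", "fail_maf", "fail_biallelic"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(S, dtype=bool))

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def passed(self) -> np.ndarray:
        return ~(self.fail_missing | self.fail_maf | self.fail_biallelic)

    def subset(self, mask: np.ndarray) -> "SiteTable":
        mask = np.asarray(mask)
        return SiteTable(
            contigs=self.contigs, contig_idx=self.contig_idx[mask],
            pos=self.pos[mask], major=self.major[mask], minor=self.minor[mask],
            maf=self.maf[mask], pval_snp=self.pval_snp[mask],
            pval_tri=self.pval_tri[mask], gl=self.gl[mask],
            depth=self.depth[mask], individuals=self.individuals,
            missing=self.missing[mask], fail_missing=self.fail_missing[mask],
            fail_maf=self.fail_maf[mask], fail_biallelic=self.fail_biallelic[mask],
            filtered=self.filtered,
        )

    def passing(self) -> "SiteTable":
        return self.subset(self.passed)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "contig": [self.contigs[i] for i in self.contig_idx],
            "pos": self.pos,
            "major": [chr(BASE_ASCII[m]) for m in self.major],
            "minor": [chr(BASE_ASCII[m]) for m in self.minor],
            "maf": self.maf,
            "pval_snp": self.pval_snp,
            "pval_tri": self.pval_tri,
            "n_missing": self.missing.sum(axis=1),
            "fail_missing": self.fail_missing,
            "fail_maf": self.fail_maf,
            "fail_biallelic": self.fail_biallelic,
            "pass": self.passed,
        })


def call_snps(pileup: PileupSet, config: FilterConfig | None = None) -> SiteTable:
    """Jointly call biallelic SNPs from pileups.

    Per site the two highest-count alleles become major/minor; the ML minor
    frequency comes from the EM over genotype likelihoods and is tested
    against zero. Sites reaching ``p < config.snp_pvalue`` are emitted;
    sites whose third allele is also significant at that threshold carry a
    ``fail_biallelic`` flag (removed by :func:`filter_sites`). Monomorphic
    input therefore yields an empty table, not an error.

    A site enters the test only when its minor allele is seen on >= 2 reads
    overall — below that the LRT cannot approach genome-wide significance.
    """
    if config is None:
        config = FilterConfig()
    config.validate()
    totals = pileup.counts.sum(axis=1, dtype=np.int64)          # (S, 4)
    order = np.argsort(-totals, axis=1, kind="stable")
    major, minor, third = order[:, 0], order[:, 1], order[:, 2]
    cand = totals[np.arange(len(major)), minor] >= 2
    idx = np.flatnonzero(cand)
    if idx.size == 0:
        return _empty_table(pileup)

    sub = PileupSet(
        contigs=pileup.contigs, contig_idx=pileup.contig_idx[idx],
        pos=pileup.pos[idx], counts=pileup.counts[idx],
        individuals=pileup.individuals, qual=pileup.qual,
        suff=None if pileup.suff is None else pileup.suff[idx],
    )
    maj, mnr, thr = major[idx], minor[idx], third[idx]
    gl = site_genotype_log_likelihoods(sub, maj, mnr)
    depth = sub.depth
    usable = depth > 0
    p_hat, logl1 = ml_allele_frequency(gl, usable)
    logl0 = (gl[..., 0] * usable).sum(axis=1)
    pval = _snp_lrt_pvalue(logl1, logl0)

    # fold frequencies above 0.5: swap major/minor and reverse the triples
    flip = p_hat > 0.5
    if flip.any():
        maj, mnr = np.where(flip, mnr, maj), np.where(flip, maj, mnr)
        gl[flip] = gl[flip, :, ::-1]
        p_hat = np.where(flip, 1.0 - p_hat, p_hat)

    # third-allele test against the major allele
    tri_counts = totals[idx, thr]
    gl3 = site_genotype_log_likelihoods(sub, maj, thr)
    p3, logl3 = ml_allele_frequency(gl3, usable)
    logl3_null = (gl3[..., 0] * usable).sum(axis=1)
    pval_tri = np.where(tri_counts >= 2,
                        _snp_lrt_pvalue(logl3, logl3_null), 1.0)

    keep = pval < config.snp_pvalue
    table = SiteTable(
        contigs=pileup.contigs, contig_idx=sub.contig_idx[keep],
        pos=sub.pos[keep], major=maj[keep].astype(np.uint8),
        minor=mnr[keep].astype(np.uint8), maf=p_hat[keep],
        pval_snp=pval[keep], pval_tri=pval_tri[keep],
        gl=gl[keep].astype(np.float64), depth=depth[keep].astype(np.int32),
        individuals=list(pileup.individuals),
    )
    return table


def _empty_table(pileup: PileupSet) -> SiteTable:
    N = pileup.n_individuals
    return SiteTable(
        contigs=pileup.contigs, contig_idx=np.empty(0, np.int32),
        pos=np.empty(0, np.int64), major=np.empty(0, np.uint8),
        minor=np.empty(0, np.uint8), maf=np.empty(0), pval_snp=np.empty(0),
        pval_tri=np.empty(0), gl=np.empty((0, N, 3)),
        depth=np.empty((0, N), np.int32), individuals=list(pileup.individuals),
    )


def filter_sites(table: SiteTable, config: FilterConfig | None = None,
                 n_individuals: int | None = None,
                 maf_source: str = "gl") -> SiteTable:
    """Apply the depth / missingness / MAF / biallelic cascade.

    Individuals with site depth outside ``[min_depth, max_depth]`` become
    missing; a site fails when more than ``max_missing`` individuals are
    missing, when its MAF falls below ``min_maf``, or when the triallelic
    test was significant. ``maf_source`` selects the ML frequency from the
    likelihoods (``"gl"``) or the frequency of hard-called genotypes
    (``"calls"``); both conventions exist in common tooling. Idempotent.
    """
    if config is None:
        config = FilterConfig()
    config.validate()
    if n_individuals is None:
        n_individuals = table.n_individuals
    missing = (table.depth < config.min_depth) | (table.depth > config.max_depth)
    fail_missing = missing.sum(axis=1) > config.max_missing
    if maf_source == "gl":
        maf = table.maf
    elif maf_source == "calls":
        dose = hard_call(replace_missing(table, missing))
        with np.errstate(invalid="ignore"):
            called = dose >= 0
            n_chrom = 2.0 * called.sum(axis=1)
            freq = np.where(n_chrom > 0, (dose * called).sum(axis=1) / np.maximum(n_chrom, 1), np.nan)
        maf = np.minimum(freq, 1.0 - freq)
    else:
        raise ValueError("maf_source must be 'gl' or 'calls'")
    fail_maf = ~(maf >= config.min_maf)   # NaN fails
    fail_biallelic = table.pval_tri < config.snp_pvalue
    out = table.subset(np.ones(table.n_sites, dtype=bool))
    out.missing = missing
    out.fail_missing = fail_missing
    out.fail_maf = fail_maf
    out.fail_biallelic = fail_biallelic
    out.filtered = True
    return out


def replace_missing(table: SiteTable, missing: np.ndarray) -> SiteTable:
    out = table.subset(np.ones(table.n_sites, dtype=bool))
    out.missing = missing
    return out


def hard_call(table: SiteTable) -> np.ndarray:
    """(S, N) minor-allele dosage from argmax genotype likelihoods.

    Individuals flagged missing get :data:`MISSING`; an exact tie between
    the best two genotypes is also reported missing (documented tie rule).
    """
    gl = table.gl
    best = gl.argmax(axis=2)
    srt = np.sort(gl, axis=2)
    tie = srt[..., -1] == srt[..., -2]
    dose = best.astype(np.int8)
    dose[tie] = MISSING
    dose[table.missing] = MISSING
    return dose


def thin_snps(table: SiteTable, min_separation: int = 10_000) -> SiteTable:
    """Greedy left-to-right thinning to reduce linkage between kept SNPs.

    The first site of each contig is kept; a later site is kept when it
    lies more than ``min_separation`` bp beyond the last kept site of the
    same contig. Input must be sorted by (contig, position).
    """
    ci, pos = table.contig_idx, table.pos
    if len(pos) and np.any(np.diff(ci) < 0):
        raise ValueError("site table must be sorted by contig; sort before thinning")
    for c in np.unique(ci):
        p = pos[ci == c]
        if np.any(np.diff(p) < 0):
            raise ValueError("positions unsorted within contig; sort before thinning")
    keep = np.zeros(len(pos), dtype=bool)
    last_contig, last_pos = None, None
    for s in range(len(pos)):
        if ci[s] != last_contig or pos[s] - last_pos > min_separation:
            keep[s] = True
            last_contig, last_pos = ci[s], pos[s]
    return table.subset(keep)


# ---------------------------------------------------------------------------
# per-individual calls at every site (consensus input)
# ---------------------------------------------------------------------------

def call_all_sites(pileup: PileupSet):
    """Per-individual diploid calls at every pileup site.

    For each site the two most observed alleles (across individuals) define
    the candidate pair; each individual's genotype is the argmax of its
    likelihood triple. Returns ``(calls, depth)`` where ``calls`` is
    (S, N, 2) allele codes with :data:`MISSING` at zero-depth sites or
    exact ties. This is the input to consensus building, deliberately
    unfiltered by population-level criteria so invariant sites keep their
    called base.
    """
    totals = pileup.counts.sum(axis=1, dtype=np.int64)
    order = np.argsort(-totals, axis=1, kind="stable")
    a1, a2 = order[:, 0], order[:, 1]
    gl = site_genotype_log_likelihoods(pileup, a1, a2)
    best = gl.argmax(axis=2)
    srt = np.sort(gl, axis=2)
    tie = srt[..., -1] == srt[..., -2]
    depth = pileup.depth
    S, N = depth.shape
    calls = np.empty((S, N, 2), dtype=np.int8)
    a1b = np.broadcast_to(a1[:, None], (S, N))
    a2b = np.broadcast_to(a2[:, None], (S, N))
    calls[..., 0] = np.where(best == 2, a2b, a1b)
    calls[..., 1] = np.where(best == 0, a1b, a2b)
    bad = tie | (depth == 0)
    calls[bad] = MISSING
    return calls, depth


# ---------------------------------------------------------------------------
# damage profiling and read filters
# ---------------------------------------------------------------------------

@dataclass
class DamageProfile:
    """Mismatch frequencies by offset from the read ends."""

    offsets: np.ndarray
    ct5: np.ndarray        # C->T frequency at 5' offsets (NaN where undefined)
    ga3: np.ndarray        # G->A frequency at 3' offsets
    ct5_denom: np.ndarray
    ga3_denom: np.ndarray


def estimate_damage_profile(reads: ReadSet, max_offset: int = 24) -> DamageProfile:
    """Empirical deamination profile from reads with aligned references.

    At 5' offset ``i`` the statistic is #(ref C, read T) / #(ref C); the 3'
    profile counts G->A analogously. Zero denominators give NaN, not 0.
    Reads are compared in read orientation, so plus- and minus-strand
    fragments of the same molecule contribute identically.
    """
    K = max_offset + 1
    base_read = np.repeat(np.arange(reads.n_reads), reads.length)
    within = np.arange(len(reads.seq)) - reads.offsets[base_read]
    off3 = reads.length[base_read] - 1 - within
    ct_num = np.zeros(K); ct_den = np.zeros(K)
    ga_num = np.zeros(K); ga_den = np.zeros(K)
    refC = reads.ref == BASE_CODE["C"]
    refG = reads.ref == BASE_CODE["G"]
    m5 = within <= max_offset
    np.add.at(ct_den, within[m5 & refC], 1)
    np.add.at(ct_num, within[m5 & refC & (reads.seq == BASE_CODE["T"])], 1)
    m3 = off3 <= max_offset
    np.add.at(ga_den, off3[m3 & refG], 1)
    np.add.at(ga_num, off3[m3 & refG & (reads.seq == BASE_CODE["A"])], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ct5 = np.where(ct_den > 0, ct_num / ct_den, np.nan)
        ga3 = np.where(ga_den > 0, ga_num / ga_den, np.nan)
    return DamageProfile(np.arange(K), ct5, ga3, ct_den, ga_den)


def shannon_entropy(seq: np.ndarray | str) -> float:
    """Base-composition entropy of a read, in bits."""
    if isinstance(seq, str):
        seq = np.array([BASE_CODE[c] for c in seq], dtype=np.uint8)
    counts = np.bincount(seq, minlength=4)
    freq = counts[counts > 0] / counts.sum()
    return float(-(freq * np.log2(freq)).sum())


def filter_low_complexity(reads: ReadSet, threshold: float = 1.0):
    """Drop reads whose base-composition entropy is strictly below ``threshold``.

    Returns ``(kept_reads, n_removed)``. The boundary is kept: a perfect
    two-base repeat (1.0 bits) passes the default threshold.
    """
    base_read = np.repeat(np.arange(reads.n_reads), reads.length)
    counts = np.zeros((reads.n_reads, 4))
    np.add.at(counts, (base_read, reads.seq), 1)
    tot = counts.sum(axis=1, keepdims=True)
    freq = counts / np.maximum(tot, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(freq > 0, freq * np.log2(freq), 0.0).sum(axis=1)
    keep = ent >= threshold
    return reads.subset(keep), int((~keep).sum())
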