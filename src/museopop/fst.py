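"""Weir-Cockerham Fst: per-site variance components, 50-kb windows, outliers.

The per-site estimator decomposes allele-frequency variance into an
among-population component ``a``, an among-individual-within-population
component ``b`` and a within-individual component ``c`` (computed from the
observed heterozygosity), with ``Fst = a / (a + b + c)``. Windows report
both the mean of per-site ratios ("mean Fst") and the ratio of summed
components ("weighted Fst"); the Z-transform and outlier calls use the mean
of ratios by default, with the alternative one flag away. Negative per-site
values are retained, matching the common windowed-Fst tooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .likelihoods import MISSING


@dataclass
class FstSiteComponents:
    contig_idx: np.ndarray
    pos: np.ndarray
    a: np.ndarray              # among-population
    b: np.ndarray              # among-individual within population
    c: np.ndarray              # within-individual
    defined: np.ndarray        # bool: denominator > 0 and >= 2 diploids/pop
    contigs: list[str]

    @property
    def fst(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = self.a + self.b + self.c
            return np.where(self.defined & (denom != 0), self.a / denom, np.nan)


def wc_fst_site(counts1: Sequence[int], counts2: Sequence[int]):
    """Single-site components from genotype counts ``(n_AA, n_Aa, n_aa)``.

    Returns ``(a, b, c, fst)`` with ``fst = NaN`` when the denominator
    vanishes (site monomorphic across both populations) or either
    population has fewer than two genotyped diploids.
    """
    n1, n2 = sum(counts1), sum(counts2)
    if n1 < 2 or n2 < 2:
        return np.nan, np.nan, np.nan, np.nan
    p1 = (counts1[1] + 2 * counts1[2]) / (2 * n1)
    p2 = (counts2[1] + 2 * counts2[2]) / (2 * n2)
    h1 = counts1[1] / n1
    h2 = counts2[1] / n2
    a, b, c = _wc_components(np.array([n1]), np.array([n2]),
                             np.array([p1]), np.array([p2]),
                             np.array([h1]), np.array([h2]))
    denom = a[0] + b[0] + c[0]
    fst = a[0] / denom if denom != 0 else np.nan
    return float(a[0]), float(b[0]), float(c[0]), float(fst)


def _wc_components(n1, n2, p1, p2, h1, h2):
    """Vectorised two-population diploid Weir-Cockerham components."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
                       / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
    c = hbar / 2.0
    return a, b, c


def wc_fst_components(dosage: np.ndarray, pop1: Sequence[int],
                      pop2: Sequence[int], contig_idx: np.ndarray,
                      pos: np.ndarray, contigs: Sequence[str]) -> FstSiteComponents:
    """Per-site components for all sites of a dosage matrix (missing = -1)."""
    d1 = dosage[:, list(pop1)]
    d2 = dosage[:, list(pop2)]
    called1 = d1 != MISSING
    called2 = d2 != MISSING
    n1 = called1.sum(axis=1).astype(np.float64)
    n2 = called2.sum(axis=1).astype(np.float64)
    enough = (n1 >= 2) & (n2 >= 2)
    n1s, n2s = np.maximum(n1, 2), np.maximum(n2, 2)   # guard; masked later
    p1 = np.where(called1, d1, 0).sum(axis=1) / (2 * n1s)
    p2 = np.where(called2, d2, 0).sum(axis=1) / (2 * n2s)
    h1 = np.where(called1, d1 == 1, 0).sum(axis=1) / n1s
    h2 = np.where(called2, d2 == 1, 0).sum(axis=1) / n2s
    a, b, c = _wc_components(n1s, n2s, p1, p2, h1, h2)
    denom = a + b + c
    defined = enough & (denom != 0)
    a = np.where(enough, a, np.nan)
    b = np.where(enough, b, np.nan)
    c = np.where(enough, c, np.nan)
    return FstSiteComponents(
        contig_idx=np.asarray(contig_idx), pos=np.asarray(pos),
        a=a, b=b, c=c, defined=defined, contigs=list(contigs),
    )


# ---------------------------------------------------------------------------
# windows and outliers
# ---------------------------------------------------------------------------

@dataclass
class FstWindowTrack:
    contigs: list[str]
    contig_idx: np.ndarray
    start: np.ndarray            # 0-based half-open
    end: np.ndarray
    fst_mean: np.ndarray         # mean of per-site ratios
    fst_weighted: np.ndarray     # ratio of summed components
    n_sites: np.ndarray
    z: np.ndarray = None
    outlier: np.ndarray = None

    @property
    def n_windows(self) -> int:
        return len(self.start)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "contig": [self.contigs[i] for i in self.contig_idx],
            "start": self.start, "end": self.end,
            "fst_mean": self.fst_mean, "fst_weighted": self.fst_weighted,
            "n_sites": self.n_sites,
            "z": self.z if self.z is not None else np.nan,
            "outlier": self.outlier if self.outlier is not None else False,
        })


def fst_windows(components: FstSiteComponents,
                contig_lengths: Mapping[str, int],
                window: int = 50_000) -> FstWindowTrack:
    """Nonoverlapping windows tiled from offset 0 of each contig.

    The terminal remainder of a contig forms a short final window. Window
    summaries are invariant to site order within the window.
    """
    ci_l, st_l, en_l, fm_l, fw_l, ns_l = [], [], [], [], [], []
    fst_site = components.fst
    for c, name in enumerate(components.contigs):
        clen = contig_lengths[name]
        in_c = components.contig_idx == c
        pos0 = components.pos[in_c] - 1       # to 0-based
        for start in range(0, max(clen, 1), window):
            end = min(start + window, clen)
            m = in_c.copy()
            m[in_c] = (pos0 >= start) & (pos0 < end)
            defined = m & components.defined
            nd = int(defined.sum())
            if nd:
                fmean = float(np.nanmean(fst_site[defined]))
                A = components.a[defined].sum()
                denom = (components.a[defined] + components.b[defined]
                         + components.c[defined]).sum()
                fweight = float(A / denom) if denom != 0 else np.nan
            else:
                fmean = fweight = np.nan
            ci_l.append(c); st_l.append(start); en_l.append(end)
            fm_l.append(fmean); fw_l.append(fweight); ns_l.append(nd)
    return FstWindowTrack(
        contigs=list(components.contigs),
        contig_idx=np.array(ci_l, dtype=np.int32),
        start=np.array(st_l, dtype=np.int64), end=np.array(en_l, dtype=np.int64),
        fst_mean=np.array(fm_l), fst_weighted=np.array(fw_l),
        n_sites=np.array(ns_l, dtype=np.int64),
    )


def zscore_outliers(track: FstWindowTrack, z_cutoff: float = 1.15,
                    top_fraction: float = 0.05, min_sites: int = 5,
                    statistic: str = "mean"):
    """Z-transform window Fst and call outliers.

    Only windows with at least ``min_sites`` defined sites enter the Z
    calculation. Outliers are windows with ``Z > z_cutoff``; the empirical
    top-``top_fraction`` set is reported alongside, with a flag saying
    whether the two coincide. Returns the annotated track plus a dict of
    the outlier bookkeeping. A zero standard deviation yields no outliers
    (with a warning).
    """
    import warnings

    values = track.fst_mean if statistic == "mean" else track.fst_weighted
    eligible = (track.n_sites >= min_sites) & np.isfinite(values)
    n_eligible = int(eligible.sum())
    if n_eligible < 20:
        raise ValueError(f"only {n_eligible} eligible windows (< 20)")
    mu = values[eligible].mean()
    sd = values[eligible].std(ddof=1)
    z = np.full(track.n_windows, np.nan)
    outlier = np.zeros(track.n_windows, dtype=bool)
    if sd == 0:
        warnings.warn("all eligible windows identical; no outliers callable")
    else:
        z[eligible] = (values[eligible] - mu) / sd
        outlier = np.where(np.isfinite(z), z > z_cutoff, False)
    cutoff_rank = np.quantile(values[eligible], 1.0 - top_fraction)
    top_set = eligible & (values >= cutoff_rank)
    track.z = z
    track.outlier = outlier
    info = {
        "n_eligible": n_eligible,
        "n_outliers_z": int(outlier.sum()),
        "n_outliers_top": int(top_set.sum()),
        "top_set": top_set,
        "sets_coincide": bool(np.array_equal(outlier, top_set)),
    }
    return track, info


# ---------------------------------------------------------------------------
# interval overlap annotation
# ---------------------------------------------------------------------------

def read_intervals(path) -> list[tuple[str, int, int, str]]:
    """Gene intervals from BED (0-based half-open) or GFF (1-based closed).

    Returns ``(contig, start, end, name)`` tuples on 0-based half-open
    coordinates. Malformed lines raise with their line number.
    """
    path = str(path)
    out = []
    is_gff = path.endswith((".gff", ".gff3", ".gtf"))
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if is_gff:
                    contig, start, end = f[0], int(f[3]) - 1, int(f[4])
                    name = _gff_name(f[8]) if len(f) > 8 else f[2]
                else:
                    contig, start, end = f[0], int(f[1]), int(f[2])
                    name = f[3] if len(f) > 3 else f"{contig}:{start}-{end}"
                if end < start:
                    raise ValueError("end < start")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{ln}: malformed interval line ({exc})")
            out.append((contig, start, end, name))
    return out


def _gff_name(attrs: str) -> str:
    for key in ("Name=", "gene_name=", "ID="):
        for part in attrs.split(";"):
            if part.strip().startswith(key):
                return part.strip()[len(key):]
    return attrs.split(";")[0]


def annotate_overlaps(track: FstWindowTrack,
                      intervals: Sequence[tuple[str, int, int, str]]) -> dict[int, list[str]]:
    """Genes overlapping each outlier window by >= 1 bp (half-open).

    Returns ``{window index: [gene names]}`` for windows flagged outlier.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for contig, start, end, name in intervals:
        if end > start:
            trees.setdefault(contig, IntervalTree()).addi(start, end, name)
    if track.outlier is None:
        raise ValueError("call zscore_outliers before annotating")
    out: dict[int, list[str]] = {}
    for w in np.flatnonzero(track.outlier):
        contig = track.contigs[track.contig_idx[w]]
        hits = trees.get(contig, IntervalTree()).overlap(track.start[w], track.end[w])
        out[int(w)] = sorted(h.data for h in hits)
    return out


def write_manhattan_tsv(track: FstWindowTrack, path) -> None:
    """Plot-ready track: contig, window midpoint, Fst and Z per window."""
    with open(path, "w") as fh:
        fh.write("contig\tmidpoint\tfst\tz\n")
        z = track.z if track.z is not None else np.full(track.n_windows, np.nan)
        for w in range(track.n_windows):
            mid = (track.start[w] + track.end[w]) // 2
            fh.write(f"{track.contigs[track.contig_idx[w]]}\t{mid}"
                     f"\t{track.fst_mean[w]:.6f}\t{z[w]:.4f}\n")


def write_outlier_bed(track: FstWindowTrack, path) -> None:
    with open(path, "w") as fh:
        for w in np.flatnonzero(track.outlier if track.outlier is not None else []):
            fh.write(f"{track.contigs[track.contig_idx[w]]}\t{track.start[w]}"
                     f"\t{track.end[w]}\t{track.z[w]:.4f}\n")
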