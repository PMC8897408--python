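"""Patterson's D (ABBA-BABA) with block-jackknife significance.

For a four-taxon tree [((P1,P2),P3),O], an excess of derived alleles shared
between P2 and P3 (ABBA site patterns) over P1-P3 sharing (BABA) indicates
post-speciation gene flow. With population derived-allele frequencies the
per-site pattern weights are

    ABBA = (1-p1) * p2 * p3 * (1-pO)
    BABA = p1 * (1-p2) * p3 * (1-pO)

and D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA). Standard errors come
from a delete-one block jackknife over contiguous genomic blocks (Busing's
delete-m_j formulas); blocks count equally by default — correct when each
block is one linked window — with per-block denominator weighting available
for long physical blocks of many quasi-independent loci. Z = D / SE and
comparisons with |Z| > 3 are flagged significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .likelihoods import MISSING, SiteTable, ml_allele_frequency


@dataclass
class ComparisonSpec:
    p1: tuple[str, ...]
    p2: tuple[str, ...]
    p3: tuple[str, ...]
    outgroup: tuple[str, ...]
    mode: str = "individual"        # "individual" | "population"

    def __post_init__(self):
        sets = [set(self.p1), set(self.p2), set(self.p3), set(self.outgroup)]
        if any(not s for s in sets):
            raise ValueError("each of P1, P2, P3, O needs >= 1 individual")
        for a, b in combinations(sets, 2):
            if a & b:
                raise ValueError(f"taxa overlap: {sorted(a & b)}")


@dataclass
class DStatResult:
    spec: ComparisonSpec
    abba: float
    baba: float
    d: float
    se: float                 # NaN when undefined (degenerate variance)
    z: float
    n_sites: int
    n_blocks: int

    @property
    def significant(self) -> bool:
        return np.isfinite(self.z) and abs(self.z) > 3.0


# ---------------------------------------------------------------------------
# frequencies and polarization
# ---------------------------------------------------------------------------

def pop_allele_freqs(dosage: np.ndarray, individuals: Sequence[int]) -> np.ndarray:
    """Per-site minor-allele frequency from hard-called dosages.

    Missing individuals leave the denominator; sites where every member is
    missing return NaN (dropped from comparisons downstream).
    """
    sub = dosage[:, list(individuals)]
    called = sub != MISSING
    n_chrom = 2.0 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_chrom > 0,
                        np.where(called, sub, 0).sum(axis=1) / n_chrom,
                        np.nan)


def gl_pop_allele_freqs(table: SiteTable, individuals: Sequence[int]) -> np.ndarray:
    """Per-site ML minor-allele frequency within one population, from GLs."""
    idx = list(individuals)
    gl = table.gl[:, idx, :]
    usable = ~table.missing[:, idx]
    p, _ = ml_allele_frequency(gl, usable)
    p = np.where(usable.any(axis=1), p, np.nan)
    return p


def polarize(freqs: dict[str, np.ndarray], outgroup_key: str,
             max_outgroup_polymorphism: float = 0.2) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Convert minor-allele frequencies to derived-allele frequencies.

    The ancestral allele is the outgroup's major allele: wherever the
    outgroup frequency exceeds 0.5 the site flips (p -> 1-p) in every
    taxon. Sites where the outgroup remains polymorphic above
    ``max_outgroup_polymorphism`` after polarization are dropped (ancestral
    state too uncertain).
    """
    po = freqs[outgroup_key]
    flip = po > 0.5
    out = {k: np.where(flip, 1.0 - v, v) for k, v in freqs.items()}
    keep = out[outgroup_key] <= max_outgroup_polymorphism
    return out, keep


# ---------------------------------------------------------------------------
# the statistic
# ---------------------------------------------------------------------------

def site_pattern_weights(p1, p2, p3, po):
    """Per-site (ABBA, BABA) weights; NaN frequencies produce NaN weights."""
    abba = (1.0 - p1) * p2 * p3 * (1.0 - po)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - po)
    return abba, baba


def d_statistic(p1, p2, p3, po, spec: ComparisonSpec | None = None,
                block_ids: np.ndarray | None = None,
                min_blocks: int = 10, weights: str = "equal") -> DStatResult:
    """Patterson's D from per-site frequencies, with optional jackknife.

    Sites with an undefined frequency in any taxon are skipped. With
    ``block_ids`` a delete-one block jackknife yields SE and Z (see
    :func:`block_jackknife` for the ``weights`` choice); without them only
    the point estimate is filled in.
    """
    p1, p2, p3, po = (np.asarray(x, dtype=np.float64) for x in (p1, p2, p3, po))
    ok = np.isfinite(p1) & np.isfinite(p2) & np.isfinite(p3) & np.isfinite(po)
    abba, baba = site_pattern_weights(p1[ok], p2[ok], p3[ok], po[ok])
    A, B = float(abba.sum()), float(baba.sum())
    denom = A + B
    informative = int(((abba + baba) > 0).sum())
    d = (A - B) / denom if denom > 0 else np.nan
    se = z = np.nan
    n_blocks = 0
    if block_ids is not None and denom > 0:
        se, z, n_blocks = block_jackknife(abba, baba,
                                          np.asarray(block_ids)[ok],
                                          min_blocks=min_blocks,
                                          weights=weights)
    return DStatResult(
        spec=spec, abba=A, baba=B, d=d, se=se, z=z,
        n_sites=informative, n_blocks=n_blocks,
    )


def block_jackknife(abba_site: np.ndarray, baba_site: np.ndarray,
                    block_ids: np.ndarray, min_blocks: int = 10,
                    weights: str = "equal"):
    """Delete-one-block jackknife SE and Z for D (Busing's delete-m_j form).

    ``weights`` sets the per-block information weight ``m_j``:

    * ``"equal"`` — every block counts once. Correct when each block is a
      single linked unit, e.g. one non-recombining simulated window whose
      sites all share a genealogy: a block's information does not grow with
      its site count. (Equal weights reduce Busing's formulas to the plain
      delete-one jackknife.)
    * ``"denominator"`` — ``m_j`` is the block's ABBA+BABA sum. Appropriate
      for long physical blocks holding many quasi-independent loci, where
      informative-site counts vary between blocks.

    Empty blocks are ignored; fewer than ``min_blocks`` non-empty blocks
    raises (use smaller blocks). Zero jackknife variance (all blocks
    identical) gives ``(0, NaN, g)`` — Z undefined, flagged downstream.
    """
    uniq, inv = np.unique(block_ids, return_inverse=True)
    A_j = np.bincount(inv, weights=abba_site, minlength=len(uniq))
    B_j = np.bincount(inv, weights=baba_site, minlength=len(uniq))
    d_j = A_j + B_j
    keep = d_j > 0
    A_j, B_j, d_j = A_j[keep], B_j[keep], d_j[keep]
    g = len(d_j)
    if g < min_blocks:
        raise ValueError(
            f"only {g} non-empty jackknife blocks (< {min_blocks}); use smaller blocks"
        )
    if weights == "equal":
        m_j = np.ones(g)
    elif weights == "denominator":
        m_j = d_j
    else:
        raise ValueError("weights must be 'equal' or 'denominator'")
    A, B = A_j.sum(), B_j.sum()
    n = m_j.sum()
    theta = (A - B) / (A + B)
    theta_del = ((A - A_j) - (B - B_j)) / ((A - A_j) + (B - B_j))
    h = n / m_j
    theta_J = g * theta - ((1.0 - m_j / n) * theta_del).sum()
    tau = h * theta - (h - 1.0) * theta_del
    var = ((tau - theta_J) ** 2 / (h - 1.0)).sum() / g
    se = float(np.sqrt(max(var, 0.0)))
    z = theta / se if se > 0 else np.nan
    return se, float(z), g


# ---------------------------------------------------------------------------
# comparison enumeration
# ---------------------------------------------------------------------------

def enumerate_individual_comparisons(pop_map: Mapping[str, str],
                                     outgroup_taxon: str) -> list[ComparisonSpec]:
    """All (P1, P2, P3) individual triples with P1, P2 conspecific.

    P1 and P2 are an unordered pair from one taxon; P3 is any individual of
    a different non-outgroup taxon; the outgroup individuals are fixed.
    """
    taxa: dict[str, list[str]] = {}
    for ind, tax in pop_map.items():
        taxa.setdefault(tax, []).append(ind)
    if outgroup_taxon not in taxa:
        raise ValueError(f"outgroup taxon {outgroup_taxon!r} has no individuals")
    out = []
    o = tuple(taxa[outgroup_taxon])
    ingroup = [t for t in taxa if t != outgroup_taxon]
    for t in ingroup:
        for a, b in combinations(taxa[t], 2):
            for t3 in ingroup:
                if t3 == t:
                    continue
                for c in taxa[t3]:
                    out.append(ComparisonSpec((a,), (b,), (c,), o))
    return out


def population_comparison(pop_map: Mapping[str, str], p1: str, p2: str, p3: str,
                          outgroup_taxon: str) -> ComparisonSpec:
    taxa: dict[str, list[str]] = {}
    for ind, tax in pop_map.items():
        taxa.setdefault(tax, []).append(ind)
    return ComparisonSpec(
        tuple(taxa[p1]), tuple(taxa[p2]), tuple(taxa[p3]),
        tuple(taxa[outgroup_taxon]), mode="population",
    )


def abba_baba_scan(dosage: np.ndarray, individuals: Sequence[str],
                   pop_map: Mapping[str, str], outgroup_taxon: str,
                   block_ids: np.ndarray, mode: str = "individual",
                   population_triple: tuple[str, str, str] | None = None,
                   min_blocks: int = 10) -> list[DStatResult]:
    """Run D for every enumerated comparison on a dosage matrix.

    ``mode="individual"`` enumerates conspecific (P1, P2) pairs against
    each foreign P3; ``mode="population"`` runs the single comparison named
    by ``population_triple`` with every individual per taxon. Taxa present
    in ``pop_map`` but absent from ``individuals`` are skipped with a
    warning.
    """
    import warnings

    index = {name: i for i, name in enumerate(individuals)}
    present = {k: v for k, v in pop_map.items() if k in index}
    skipped = {v for k, v in pop_map.items() if k not in index}
    if skipped - set(present.values()):
        warnings.warn(f"taxa with no individuals in the data: "
                      f"{sorted(skipped - set(present.values()))}")
    if mode == "individual":
        specs = enumerate_individual_comparisons(present, outgroup_taxon)
    elif mode == "population":
        if population_triple is None:
            raise ValueError("population mode needs population_triple=(P1,P2,P3)")
        specs = [population_comparison(present, *population_triple, outgroup_taxon)]
    else:
        raise ValueError("mode must be 'individual' or 'population'")

    results = []
    for spec in specs:
        freqs = {}
        for key, names in (("p1", spec.p1), ("p2", spec.p2),
                           ("p3", spec.p3), ("o", spec.outgroup)):
            freqs[key] = pop_allele_freqs(dosage, [index[n] for n in names])
        pol, keep = polarize(freqs, "o")
        args = (pol["p1"][keep], pol["p2"][keep], pol["p3"][keep],
                pol["o"][keep])
        try:
            res = d_statistic(*args, spec=spec,
                              block_ids=np.asarray(block_ids)[keep],
                              min_blocks=min_blocks)
        except ValueError as exc:   # too few non-empty blocks
            warnings.warn(f"comparison {spec.p1}/{spec.p2}/{spec.p3}: {exc}; "
                          "reporting the point estimate without a Z-score")
            res = d_statistic(*args, spec=spec)
        results.append(res)
    return results


def results_to_dataframe(results: Sequence[DStatResult]):
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "P1": "+".join(r.spec.p1) if r.spec else "",
            "P2": "+".join(r.spec.p2) if r.spec else "",
            "P3": "+".join(r.spec.p3) if r.spec else "",
            "O": "+".join(r.spec.outgroup) if r.spec else "",
            "D": r.d, "SE": r.se, "Z": r.z,
            "nSites": r.n_sites, "nBlocks": r.n_blocks,
            "significant": r.significant,
        })
    return pd.DataFrame(rows)
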