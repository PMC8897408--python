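# Methods

`museopop` reimplements, as one tested library, the analysis chain used for
population genomics of degraded museum-specimen resequencing data: a
coalescent simulator with post-mortem damage as the data source, and on top
of it genotype-likelihood SNP calling, consensus-window divergence dating,
per-window trees with topology weighting, ABBA–BABA introgression tests,
windowed Weir–Cockerham F<sub>ST</sub> scans, and genotype-likelihood
population-structure inference. This note records the models, the defaults
and why they hold, the numerical choices, and what the synthetic data do
and do not establish about real specimens.

## Synthetic data generator

**Demography.** Each genomic window is simulated independently under a
discrete-event structured coalescent: within a population of (diploid)
effective size *N*, *k* lineages coalesce at rate *k(k−1)/(4N)* per
generation; population merges and admixture pulses are scheduled events
(pulses move each lineage of the target into the source with probability
*f*, acting before a merge at the same time). There is no recombination
within a window — the downstream analyses sample distant 10-kb windows
precisely to approximate independent loci, so the generator produces
exactly that idealisation. An external coalescent simulator (msprime) is
used in the test suite only, as an independent oracle for pairwise
divergence under matched demography.

**Defaults** mirror the museum study system: five taxa
(((MEL,TRA),ROB),(ARD,NIG)) with splits at 127k / 224k generations in the
continental clade, an island split at 150k and a root at 500k generations;
sampling 6+5+3+1+1 diploids; mutation rate μ = 4.6×10⁻⁹ per site per
generation (the collared-flycatcher pedigree rate used to calibrate
passerine divergence); 10-kb windows. Effective sizes default to 10⁵
diploids — a typical songbird magnitude which reproduces the
high-incomplete-lineage-sorting regime of a rapid radiation (the split
interval 127k–224k generations is ~0.5×2N, so gene trees disagree often,
as the topology-weighting analyses expect).

**Mutations** follow an infinite-sites approximation (Poisson per branch,
uniform positions, duplicate positions keep the first mutation) with
i.i.d. uniform ancestral bases and Jukes–Cantor choice of the derived
base. Two haplotypes with TMRCA *T* therefore differ at 2μ*TL* sites in
expectation, which is what the divergence-dating recovery tests check.

**Fragments and damage.** Fragment lengths are log-normal (mean 70 bp,
sd 30 bp — plausible for historical toepad extracts; the real
distributions are specimen-specific and not matched), truncated to
[20 bp, window length]. Deamination converts C→T with probability
d₅·λ^i at 5′ offset *i* and G→A with d₃·λ^i from the 3′ end, in read
orientation; the geometric decay is the standard post-mortem deamination
shape. Damage is a real base change — base qualities are untouched.
Sequencing error is applied at the pileup stage: depth is
Poisson(mean), each read drawn from one of the two haplotypes, and each
sequenced base is replaced by a uniform wrong base at rate 10^(−Q/10)
(constant Q = 30 by default).

**Seeding.** One global seed expands into per-stage, per-window
substreams via numpy `SeedSequence` with a fixed spawn key
(stage id, window index); stage ids are frozen in
`museopop.simulate.STAGE_IDS`. Identical seed + config gives bit-identical
output at every stage.

**What the generator does not emulate:** read alignment and mapping error,
indels, within-window recombination, selection, contamination,
GC-biased base composition, and specimen-to-specimen variation in depth,
fragment length and damage intensity. Passing recovery tests therefore
demonstrates the *estimators* are correct and calibrated under the model's
idealisations, not that real museum data meet those idealisations.

## Genotype likelihoods and SNP calling

Per read, P(base | allele) = 1−ε if they match, ε/3 otherwise, with
ε = 10^(−Q/10); a diploid genotype is an equal mixture of its two alleles
and the site likelihood is the product over reads (bases below quality 20
are discarded first). Triples are stored on a natural-log scale,
normalised so the maximum is 0; an empty read set yields a flat triple —
a missing-data marker, never a silent 0.

Site discovery: the two highest-count alleles define major/minor; the ML
minor-allele frequency is fitted by EM under Hardy–Weinberg (start 0.25,
stop at |Δp| < 10⁻⁸ or 100 iterations) and tested against frequency zero
by a likelihood-ratio test. Because the null pins the frequency to the
boundary of its space, the null distribution is the mixture
½δ₀ + ½χ²(1); sites with p < 10⁻⁶ are retained. An analogous LRT of the
third-most-common allele flags triallelic sites at the same threshold.
Sites whose minor allele appears on fewer than 2 reads overall are not
tested (they cannot reach genome-wide significance at these depths).

The filter cascade sets individuals with depth outside [10, 100] missing,
fails sites with more than one missing individual, MAF < 0.12, or a
significant third allele. The MAF used for filtering is the GL-based ML
frequency by default; a hard-call-count frequency is one flag away
(`maf_source="calls"`), since both conventions exist in common tooling and
it is not generally knowable which a given pipeline applied. Filtering is
idempotent and the stored MAF is not re-estimated after depth masking.

Hard calls are the argmax of the likelihood triple; exact ties are
reported missing. SNP thinning is greedy left-to-right per contig, keeping
a site only when it lies **more than** the minimum separation beyond the
last kept site (boundary rule pinned by test).

Low-complexity reads are removed when their base-composition Shannon
entropy falls strictly below 1.0 bits — a perfect two-base repeat (exactly
1.0 bits) survives. Damage profiling counts ref-C→read-T frequencies by
5′ offset (and G→A by 3′ offset) in read orientation, reporting NaN (not
0) where an offset has no eligible sites.

## Consensus windows and divergence dating

Per-individual consensus sequences come from per-individual genotype
calls at every site (deliberately *not* population-filtered, so invariant
sites keep their called base): hets become IUPAC codes; sites with depth
< 10 (inclusive boundary — exactly 10 is kept) or above 3× the
individual's mean depth become N. Windows of 10 kb are tiled every 100 kb
on contigs strictly longer than 100 kb and kept when ≥50% of columns have
data in ≥50% of individuals.

p-distances use pairwise deletion and an IUPAC-aware score: identical
codes 0; otherwise the expected mismatch between one random allele from
each genotype (het vs compatible hom ½, het vs incompatible hom 1, two
hets sharing one allele ¾). Divergence time is T = p/(2μ): two lineages
accumulate mutations independently, so pairwise distance grows at 2μ per
generation. The two-lineage convention is isolated in one function; years
are generations × 3.7 (the BirdLife estimate for orioles). This clock
cannot see past ancestral polymorphism — it overestimates splits by about
2N<sub>anc</sub> generations — so the recovery study uses a small ancestral
size (10³) to keep that bias an order of magnitude below its 10%
tolerance; with the default 10⁵ the bias would dominate, which is a
property of p-distance dating, not of the implementation.

## Window trees and topology weighting

Per-window trees are neighbour joining on the window p-distance matrix.
NJ rather than per-window maximum likelihood is a deliberate substitution:
the downstream quantity is the distribution of *topologies* across
windows, for which NJ is consistent and orders of magnitude cheaper; it is
not suitable for branch-length inference and none is attempted. Joins
resolve Q-criterion ties to the lowest index pair, negative branch lengths
clamp to zero, and the implementation is cross-checked against an
independent NJ implementation (scikit-bio) in the tests. Bootstrap support
resamples alignment columns, re-infers distance + NJ, and reports the
fraction of replicates containing each bipartition of the point tree.

Topology weighting iterates over combinations of one tip per group, reads
the induced group topology off the tree's edge bipartitions (rooted on the
outgroup tip), and normalises counts to weights. Enumeration is exhaustive
up to 10,000 combinations, then switches to 1,000 uniform draws — the
subsampling thresholds of the original topology-weighting tool are not
published, so these are documented package choices. Topology labels are
canonical sorted nested parentheses over group names.

## ABBA–BABA

Derived-allele frequencies are polarised by the outgroup major allele;
sites where the outgroup stays polymorphic above 0.2 after polarisation
are dropped (ancestral state too uncertain — the cutoff is a documented
package choice). Site weights are ABBA = (1−p₁)p₂p₃(1−p_O),
BABA = p₁(1−p₂)p₃(1−p_O); D is the normalised difference of their sums,
antisymmetric in P1↔P2 by construction.

Standard errors come from a delete-one block jackknife in Busing's
delete-m_j form, with a choice of block weights that matters:

* **equal** (default): every block counts once. This is the correct
  weighting when each block is a single linked unit — exactly the
  simulator's regime, where a block is one non-recombining window whose
  sites share a genealogy, so a block's information does not grow with its
  site count. Calibration measured over coalescent replicates: null Z
  standard deviation 1.02.
* **denominator**: blocks weighted by their ABBA+BABA sum, appropriate for
  long physical blocks containing many quasi-independent loci (the
  real-data regime of megabase blocks). Under the simulator's single-
  genealogy blocks this weighting understated the SE (null Z sd ≈ 1.6),
  which is why it is not the default here; it is itself calibration-tested
  on an i.i.d.-site fixture.

Z = D/SE and |Z| > 3 flags significance, matching the field convention.
Individual-level scans enumerate all conspecific (P1,P2) pairs against
each foreign P3 with the outgroup fixed; the population-level comparison
pools all individuals per taxon. Comparisons left with fewer than 10
non-empty blocks report the point estimate without a Z rather than
aborting the scan.

## Windowed F<sub>ST</sub>

Per-site Weir–Cockerham variance components a (among populations),
b (among individuals within) and c (within individuals, from observed
heterozygosity) use the two-population diploid estimator; sites need at
least two genotyped diploids per population. Windows (non-overlapping
50 kb, tiled from offset 0, terminal remainder kept) report both the mean
of per-site ratios ("mean F<sub>ST</sub>") and the ratio of summed
components ("weighted F<sub>ST</sub>"). The Z-transform and outliers
(Z > 1.15, alongside the empirical top-5% set and whether the two
coincide) use the mean of ratios, mirroring the "mean F<sub>ST</sub>"
convention, with the alternative one flag away; negative per-site values
are retained, matching common windowed-F<sub>ST</sub> tooling. Windows
need ≥5 defined sites to enter the Z calculation. The implementation is
pinned to an independently derived nested-ANOVA oracle (pops /
individuals / allele copies) to 10⁻¹² in the tests. Outlier windows are
annotated by ≥1-bp overlap with user-supplied BED/GFF gene intervals
(half-open semantics) — sequence-similarity search against a reference
annotation is out of scope.

## Population structure

Expected dosages are single-pass posterior means: likelihood triple ×
Hardy–Weinberg prior at the site frequency, missing individuals imputed at
2f. This deliberately simplifies iterative individual-allele-frequency
PCA methods; it preserves the clustering structure that the PCA is used to
display, which is all the package claims for it. Sites are standardised by
√(2f(1−f)); the individual covariance is eigendecomposed and coordinates
scaled by √λ.

Admixture maximises Σ log Σ_g GL·Binomial(g; 2, h), h = QFᵀ, by EM.
The update is algebraically factorised into rank-K matrix products (no
S×N×K temporaries), which is exact and keeps the K = 1..10 × 15-replicate
grid tractable. Initialisation seeds each cluster's frequencies from a
randomly chosen individual's posterior dosages shrunk 30% toward the site
frequency (plus small jitter), with Dirichlet(1) rows for Q; each run
advances four such starts for 40 burn-in iterations and continues the best
to convergence — admixture likelihoods at intermediate K have local optima
that inflate the replicate scatter and destabilise ΔK, and multi-start is
the standard guard. Frequencies are clipped to [10⁻⁹, 1−10⁻⁹]; the
log-likelihood is monotone along the continued run (asserted in tests) and
EM stops at a gain below 10⁻⁶ (module default) or 2000 iterations. Replicate runs record every seed for bit-reproducibility;
label switching is resolved only for display, by greedy column matching.
Evanno ΔK = |L″(K)|/sd(L(K)) over replicate log-likelihoods, defined on
interior K; K values with exactly zero replicate scatter are excluded from
the argmax with a warning.

## Study designs behind the reported numbers

`museopop.experiments` fixes one study design per claim; the test suite
and `scripts/acceptance.py` both call these, so every reported number is
recomputed at run time. Problem sizes were chosen as the package's own
desk-scale designs:

* **D calibration/power:** 4 taxa (4+4+4+2 diploids), splits
  100k/200k/600k generations, N = 10⁵, 800 independent 10-kb windows per
  replicate (≈8,000 informative sites; blocks = windows), 100 replicates
  per arm; the pulse arm injects f = 0.2 from P3 into P2 at 50k
  generations.
* **Divergence recovery:** split 50k generations, N = 10³, 4+4 diploids,
  100 windows at depth 30, run through the full pileup→calling→consensus
  chain.
* **Topology regimes:** deep splits with N = 5×10³ (60 windows) for the
  clean regime; splits 1 generation apart with N = 10⁵ (300 windows) for
  the radiation regime; an entropy grid over split intervals checks that
  weight entropy falls as the interval grows.
* **Structure recovery:** the five-taxon default demography with N reduced
  to 5×10⁴ and the island split shallowed to 20k generations so the
  islands form one cluster (the four-cluster configuration), 60 windows at
  depth 30, K = 1..10 × 15 replicates, EM capped at 400 iterations with
  tolerance 10⁻⁵ for the grid.
* **Damage recovery:** d₅ = d₃ = 0.3, λ = 0.5, ~10⁵ fragments.

## Known limitations

* Hard calls are argmax-GL genotypes; no haplotype-aware joint model is
  attempted. The filter cascade downstream is identical, which is the
  basis on which the two calling routes are treated as interchangeable.
* No damage-aware rescaling of genotype likelihoods: damage is simulated
  and profiled, and the MAF filter absorbs most of its effect on calls,
  but likelihoods themselves assume clean bases.
* p-distance dating inherits ancestral-polymorphism bias (see above) and
  the p/(2μ) convention; with shallow splits and large N it overestimates.
* The PCA is a one-pass approximation; admixture models assume unlinked
  sites and Hardy–Weinberg within clusters.
* F<sub>ST</sub> components implement the two-population diploid case
  only.
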