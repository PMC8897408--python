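"""Genotype likelihoods, SNP calling, the filter cascade, damage profiling."""

import numpy as np
import pytest

import museopop as mp
from museopop.likelihoods import (
    FilterConfig,
    MISSING,
    call_all_sites,
    call_snps,
    filter_low_complexity,
    filter_sites,
    genotype_likelihood,
    hard_call,
    min_minor_allele_chromosomes,
    ml_allele_frequency,
    shannon_entropy,
    thin_snps,
)
from museopop.simulate import BASE_CODE

from conftest import counts_from_bases, make_pileup


class TestGenotypeLikelihood:
    def test_single_read_formula_values(self):
        """One read, base A, Q=20, alleles (A,C): the three per-read terms."""
        gl = np.exp(genotype_likelihood(["A"], [20], "A", "C",
                                        normalize=False))
        assert gl == pytest.approx([0.99, 0.496667, 0.003333], abs=1e-6)

    def test_infinite_quality_limit(self):
        gl = genotype_likelihood(["A"] * 8, [1000] * 8, "A", "C",
                                 normalize=False)
        lik = np.exp(gl)
        assert lik[0] == pytest.approx(1.0, abs=1e-6)
        assert lik[2] == pytest.approx(0.0, abs=1e-12)

    def test_balanced_reads_favor_het(self):
        gl = genotype_likelihood(list("AAAAACCCCC"), [30] * 10, "A", "C")
        assert gl.argmax() == 1

    def test_empty_reads_missing_marker_not_exception(self):
        gl = genotype_likelihood([], [], "A", "C")
        np.testing.assert_array_equal(gl, np.zeros(3))

    def test_normalized_triple_max_zero(self):
        gl = genotype_likelihood(list("AAC"), [20, 25, 30], "A", "C")
        assert gl.max() == 0.0


class TestAlleleFrequencyEM:
    def test_converges_to_sample_frequency_with_depth(self):
        """ML MAF approaches the (sample) frequency as depth grows; the
        same genotype draws are re-sequenced at each depth so only read
        noise differs."""
        rng = np.random.default_rng(0)
        n, sites, true_f = 24, 200, 0.3
        geno = rng.binomial(2, true_f, size=(sites, n))   # minor dosage
        sample_f = geno.sum(axis=1) / (2 * n)
        errs = {}
        for depth in (10, 100):
            gl = np.zeros((sites, n, 3))
            for s in range(sites):
                for i in range(n):
                    reads = rng.binomial(depth, [1.0, 0.5, 0.0][geno[s, i]])
                    bases = ["A"] * reads + ["C"] * (depth - reads)
                    gl[s, i] = genotype_likelihood(bases, [30] * depth, "A", "C")
            p, _ = ml_allele_frequency(gl)
            errs[depth] = np.abs(p - sample_f).mean()
        assert errs[100] < errs[10]
        assert errs[100] < 0.01


class TestCallSnps:
    def test_monomorphic_input_empty_table(self):
        counts = np.zeros((5, 4, 4), dtype=np.uint16)
        counts[:, :, BASE_CODE["A"]] = 30
        table = call_snps(make_pileup(counts))
        assert table.n_sites == 0

    def test_fixed_difference_called_with_half_maf(self):
        """16 diploids, 8 vs 8 fixed difference, depth 30, Q30."""
        counts = np.zeros((1, 16, 4), dtype=np.uint16)
        counts[0, :8, BASE_CODE["A"]] = 30
        counts[0, 8:, BASE_CODE["G"]] = 30
        table = call_snps(make_pileup(counts))
        assert table.n_sites == 1
        assert table.maf[0] == pytest.approx(0.5, abs=0.01)
        assert table.pval_snp[0] < 1e-6

    def test_true_triallelic_site_flagged(self):
        counts = np.zeros((1, 10, 4), dtype=np.uint16)
        counts[0, :4, BASE_CODE["A"]] = 30
        counts[0, 4:8, BASE_CODE["C"]] = 30
        counts[0, 8:, BASE_CODE["G"]] = 30
        table = filter_sites(call_snps(make_pileup(counts)))
        assert table.n_sites == 1
        assert table.fail_biallelic[0]
        assert not table.passed[0]

    def test_individual_order_permutation_same_sites(self, two_pop_panel):
        pile = mp.generate_pileups(
            two_pop_panel, mean_depth=25, phred=30, seed=3,
            positions={w: p for w, p in
                       enumerate(two_pop_panel.site_positions)})
        t1 = call_snps(pile)
        perm = np.arange(pile.n_individuals)[::-1]
        pile2 = mp.PileupSet(pile.contigs, pile.contig_idx, pile.pos,
                             pile.counts[:, perm, :],
                             [pile.individuals[i] for i in perm],
                             qual=pile.qual)
        t2 = call_snps(pile2)
        np.testing.assert_array_equal(t1.pos, t2.pos)
        np.testing.assert_array_equal(t1.contig_idx, t2.contig_idx)
        np.testing.assert_array_equal(t1.major, t2.major)


class TestFilterCascade:
    def test_min_minor_allele_chromosomes_16_diploids(self):
        assert min_minor_allele_chromosomes(16, 0.12) == 4

    def test_one_missing_individual_passes_two_fail(self):
        counts = np.zeros((2, 6, 4), dtype=np.uint16)
        counts[:, :, BASE_CODE["A"]] = 30
        counts[:, 1:4, BASE_CODE["C"]] = 15
        counts[:, 1:4, BASE_CODE["A"]] = 15
        counts[0, 0] = 0                             # site 0: one missing
        counts[1, 0] = 0
        counts[1, 5, BASE_CODE["A"]] = 101           # site 1: depth 101 -> missing
        table = call_snps(make_pileup(counts))
        table = filter_sites(table)
        assert table.n_sites == 2
        assert not table.fail_missing[0]
        assert table.fail_missing[1]

    def test_depth_bounds_set_individuals_missing(self):
        counts = np.zeros((1, 6, 4), dtype=np.uint16)
        counts[0, :, BASE_CODE["A"]] = 30
        counts[0, 2:4, BASE_CODE["C"]] = 15
        counts[0, 2:4, BASE_CODE["A"]] = 15
        counts[0, 0, BASE_CODE["A"]] = 9             # below 10
        counts[0, 1, BASE_CODE["A"]] = 101           # above 100
        table = filter_sites(call_snps(make_pileup(counts)))
        assert table.missing[0, 0] and table.missing[0, 1]
        assert table.fail_missing[0]                 # 2 missing -> fail

    def test_maf_filter_and_idempotence(self):
        counts = np.zeros((1, 16, 4), dtype=np.uint16)
        counts[0, :, BASE_CODE["A"]] = 30
        counts[0, 0, BASE_CODE["C"]] = 15            # single het: MAF 1/32
        counts[0, 0, BASE_CODE["A"]] = 15
        t = filter_sites(call_snps(make_pileup(counts)))
        assert t.n_sites == 1 and t.fail_maf[0]
        t2 = filter_sites(t)
        np.testing.assert_array_equal(t.missing, t2.missing)
        np.testing.assert_array_equal(t.fail_missing, t2.fail_missing)
        np.testing.assert_array_equal(t.fail_maf, t2.fail_maf)
        np.testing.assert_array_equal(t.passed, t2.passed)

    def test_gl_and_call_based_maf_agree_at_depth(self):
        counts = np.zeros((1, 10, 4), dtype=np.uint16)
        counts[0, :3, BASE_CODE["C"]] = 40           # 3 hom-minor
        counts[0, 3:, BASE_CODE["A"]] = 40
        t_gl = filter_sites(call_snps(make_pileup(counts)), maf_source="gl")
        t_hc = filter_sites(call_snps(make_pileup(counts)), maf_source="calls")
        assert t_gl.maf[0] == pytest.approx(0.3, abs=0.02)
        assert t_gl.passed[0] and t_hc.passed[0]


class TestHardCall:
    def test_argmax_dosage(self):
        gl = np.log(10.0) * np.array([[[0.0, -30.0, -60.0],
                                       [-60.0, -30.0, 0.0],
                                       [-5.0, 0.0, -5.0]]])
        table = mp.SiteTable(
            contigs=["c"], contig_idx=np.zeros(1, np.int32),
            pos=np.array([1]), major=np.array([0], np.uint8),
            minor=np.array([1], np.uint8), maf=np.array([0.3]),
            pval_snp=np.array([0.0]), pval_tri=np.array([1.0]),
            gl=gl, depth=np.full((1, 3), 30, np.int32),
            individuals=["a", "b", "c"])
        dose = hard_call(table)
        np.testing.assert_array_equal(dose[0], [0, 2, 1])

    def test_low_depth_missing_regardless_of_gl(self):
        counts = np.zeros((1, 4, 4), dtype=np.uint16)
        counts[0, :, BASE_CODE["A"]] = 30
        counts[0, 1, BASE_CODE["C"]] = 30
        counts[0, 1, BASE_CODE["A"]] = 0
        counts[0, 2, BASE_CODE["A"]] = 5            # depth 5 -> missing
        table = filter_sites(call_snps(make_pileup(counts)))
        dose = hard_call(table)
        assert dose[0, 2] == MISSING

    def test_exact_tie_reported_missing(self):
        gl = np.zeros((1, 2, 3))
        gl[0, 0] = [0.0, 0.0, -9.0]                 # hom/het tie
        gl[0, 1] = [0.0, -3.0, -9.0]
        table = mp.SiteTable(
            contigs=["c"], contig_idx=np.zeros(1, np.int32),
            pos=np.array([1]), major=np.array([0], np.uint8),
            minor=np.array([1], np.uint8), maf=np.array([0.3]),
            pval_snp=np.array([0.0]), pval_tri=np.array([1.0]),
            gl=gl, depth=np.full((1, 2), 30, np.int32),
            individuals=["a", "b"])
        dose = hard_call(table)
        assert dose[0, 0] == MISSING and dose[0, 1] == 0


class TestThinning:
    def _table(self, contig_idx, pos):
        S = len(pos)
        return mp.SiteTable(
            contigs=[f"c{i}" for i in range(max(contig_idx) + 1)],
            contig_idx=np.asarray(contig_idx, np.int32),
            pos=np.asarray(pos, np.int64),
            major=np.zeros(S, np.uint8), minor=np.ones(S, np.uint8),
            maf=np.full(S, 0.3), pval_snp=np.zeros(S), pval_tri=np.ones(S),
            gl=np.zeros((S, 2, 3)), depth=np.full((S, 2), 30, np.int32),
            individuals=["a", "b"])

    @pytest.mark.parametrize("contig_idx,pos,kept", [
        ([0, 0, 0], [1, 5000, 12000], [1, 12000]),
        ([0, 1, 2], [1, 2, 3], [1, 2, 3]),
        ([0] * 21, list(range(1, 20002, 1000)), [1, 11001]),
    ])
    def test_greedy_rule(self, contig_idx, pos, kept):
        out = thin_snps(self._table(contig_idx, pos))
        assert list(out.pos) == kept

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sort"):
            thin_snps(self._table([0, 0], [500, 100]))


class TestDamageProfileAndComplexity:
    def test_damage_free_reads_zero_frequencies(self, two_pop_panel):
        reads = mp.fragment_and_damage(
            two_pop_panel, mp.DamageModel(d5=0.0, d3=0.0), mean_depth=2,
            seed=1)
        prof = mp.estimate_damage_profile(reads)
        assert np.nansum(prof.ct5) == 0.0
        assert np.nansum(prof.ga3) == 0.0

    def test_zero_denominator_is_nan_not_zero(self, two_pop_panel):
        reads = mp.fragment_and_damage(
            two_pop_panel, mp.DamageModel(d5=0.0, d3=0.0), mean_depth=0.001,
            seed=1)
        few = reads.subset(np.arange(reads.n_reads) < 1)
        prof = mp.estimate_damage_profile(few, max_offset=24)
        # offsets beyond the single read's span have no denominator
        assert np.isnan(prof.ct5[prof.ct5_denom == 0]).all()

    def test_strand_symmetry_of_profile(self, two_pop_panel):
        reads = mp.fragment_and_damage(
            two_pop_panel, mp.DamageModel(d5=0.25, d3=0.25), mean_depth=4,
            seed=2)
        plus = reads.subset(reads.strand == 0)
        minus = reads.subset(reads.strand == 1)
        p1 = mp.estimate_damage_profile(plus)
        p2 = mp.estimate_damage_profile(minus)
        # both strands see the same injected curve
        np.testing.assert_allclose(p1.ct5[:4], p2.ct5[:4], atol=0.03)

    @pytest.mark.parametrize("seq,entropy", [
        ("AAAAAAAA", 0.0),
        ("ACGTACGT", 2.0),
        ("ACACACAC", 1.0),
    ])
    def test_shannon_entropy_values(self, seq, entropy):
        assert shannon_entropy(seq) == pytest.approx(entropy)

    def test_low_complexity_filter_boundary(self, two_pop_panel):
        reads = mp.fragment_and_damage(two_pop_panel, mp.DamageModel(),
                                       mean_depth=1, seed=3)
        kept, removed = filter_low_complexity(reads, threshold=1.0)
        assert kept.n_reads + removed == reads.n_reads
        # the boundary is kept: entropy exactly 1.0 survives
        for i in range(min(kept.n_reads, 100)):
            assert shannon_entropy(kept.read_seq(i)) >= 1.0


class TestRecoveryProperties:
    def test_hard_call_error_rate_below_one_percent(self, two_pop_sim,
                                                    two_pop_panel):
        """Depth 30, Q30: hard-called genotypes at passing sites are >99%
        correct against the simulated truth."""
        pile = mp.generate_pileups(
            two_pop_panel, mean_depth=30, phred=30, seed=5,
            positions={w: p for w, p in
                       enumerate(two_pop_panel.site_positions)})
        table = filter_sites(call_snps(pile)).passing()
        dose = hard_call(table)
        n = wrong = 0
        for w in range(len(two_pop_sim.windows)):
            m = table.contig_idx == w
            if not m.any():
                continue
            win = two_pop_sim.windows[w]
            truth = two_pop_sim.true_genotypes(w)
            pos_map = {p + 1: i for i, p in enumerate(win.positions)}
            for s in np.flatnonzero(m):
                if table.pos[s] not in pos_map:
                    continue
                t = truth[pos_map[table.pos[s]]]
                # dosage of the *minor* allele: match on derived or flipped
                d = dose[s]
                ok = d != MISSING
                err = min(np.sum(d[ok] != t[ok]), np.sum(d[ok] != 2 - t[ok]))
                wrong += err
                n += ok.sum()
        assert n > 200
        assert wrong / n < 0.01

    def test_dosage_expectation_within_bounds(self, two_pop_panel):
        from museopop.structure import expected_genotypes

        pile = mp.generate_pileups(
            two_pop_panel, mean_depth=20, phred=30, seed=6,
            positions={w: p for w, p in
                       enumerate(two_pop_panel.site_positions)})
        table = call_snps(pile)
        dose = expected_genotypes(table.gl, table.maf, table.missing)
        assert dose.min() >= 0.0 and dose.max() <= 2.0


def test_call_all_sites_matches_truth_on_invariant_sites(two_pop_sim,
                                                         two_pop_panel):
    pile = mp.generate_pileups(two_pop_panel, mean_depth=30, phred=30, seed=7)
    calls, depth = call_all_sites(pile)
    w = 0
    m = pile.contig_idx == w
    seg = set(two_pop_sim.windows[w].positions + 1)
    invariant = [s for s in np.flatnonzero(m) if pile.pos[s] not in seg]
    anc = two_pop_panel.ancestral[w]
    agree = [calls[s, 0, 0] == anc[pile.pos[s] - 1]
             for s in invariant[:2000] if calls[s, 0, 0] != MISSING]
    assert np.mean(agree) > 0.999
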