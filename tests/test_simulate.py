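"""Simulator: demography validation, coalescent behaviour, damage model."""

import numpy as np
import pytest

import museopop as mp
from museopop.simulate import (
    BASE_CODE,
    COMPLEMENT,
    ConfigurationError,
    generate_pileups,
    stage_rng,
)


class TestConfigValidation:
    def test_inconsistent_split_times_name_the_pair(self):
        cfg = mp.SpeciesTreeConfig(
            labels=("A", "B", "C"),
            merges=(mp.PopulationMerge(10_000.0, "B", "A"),
                    mp.PopulationMerge(5_000.0, "C", "B")),  # B already merged
            samples={"A": 1, "B": 1, "C": 1},
        )
        # time-sorted replay merges C->B first, then B->A is fine; reverse order fails
        cfg2 = mp.SpeciesTreeConfig(
            labels=("A", "B", "C"),
            merges=(mp.PopulationMerge(5_000.0, "B", "A"),
                    mp.PopulationMerge(10_000.0, "C", "B")),
            samples={"A": 1, "B": 1, "C": 1},
        )
        cfg.validate()  # consistent despite declaration order
        with pytest.raises(ConfigurationError, match="'C' -> 'B'"):
            cfg2.validate()

    def test_bad_fraction_and_mu(self):
        with pytest.raises(ConfigurationError):
            mp.SpeciesTreeConfig(mu=0.0).validate()
        cfg = mp.SpeciesTreeConfig(
            pulses=(mp.AdmixturePulse(1000.0, "TRA", "ROB", 1.5),))
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_config_plain_text_round_trip(self, tmp_path):
        cfg = mp.SpeciesTreeConfig(
            pulses=(mp.AdmixturePulse(50_000.0, "ROB", "TRA", 0.2),),
            n_windows=7, seed=42)
        path = tmp_path / "sim.config.txt"
        cfg.save(path)
        back = mp.SpeciesTreeConfig.load(path)
        assert back.n_windows == 7 and back.seed == 42
        assert back.pulses[0].fraction == 0.2
        assert [m.time for m in back.merges] == [m.time for m in cfg.merges]


class TestGenealogies:
    def test_single_population_all_coalesce_internally(self):
        cfg = mp.SpeciesTreeConfig(labels=("A",), merges=(), ne=1_000.0,
                                   samples={"A": 2}, n_windows=5, seed=1)
        sim = mp.simulate_genealogies(cfg)
        for win in sim.windows:
            assert len(win.parent) == 2 * win.n_leaves - 1
            assert win.tmrca > 0
            assert win.pulse_migrants == ()

    def test_zero_divergence_split_makes_groups_exchangeable(self):
        """With the split at (almost) time zero, between-group distance
        matches within-group distance."""
        cfg = mp.SpeciesTreeConfig(
            labels=("A", "B"), merges=(mp.PopulationMerge(1e-9, "B", "A"),),
            ne=10_000.0, samples={"A": 3, "B": 3}, n_windows=150, seed=7)
        sim = mp.simulate_genealogies(cfg)
        within, between = [], []
        for w, win in enumerate(sim.windows):
            d = win.derived.astype(np.int32)
            if not len(d):
                continue
            diff = lambda i, j: np.mean(d[:, i] != d[:, j]) * len(d)
            within.append(diff(0, 1))
            between.append(diff(0, 6))   # A-hap vs B-hap
        assert np.mean(between) == pytest.approx(np.mean(within), rel=0.15)

    def test_pulse_migration_fraction_recovered(self):
        """About f of target-population lineages trace into the source at
        the pulse, over many replicate windows."""
        f = 0.2
        cfg = mp.SpeciesTreeConfig(
            labels=("P1", "P2", "P3", "O"),
            merges=(mp.PopulationMerge(100_000.0, "P2", "P1"),
                    mp.PopulationMerge(200_000.0, "P3", "P1"),
                    mp.PopulationMerge(600_000.0, "O", "P1")),
            ne=50_000.0, samples={"P1": 1, "P2": 2, "P3": 1, "O": 1},
            pulses=(mp.AdmixturePulse(50_000.0, "P3", "P2", f),),
            n_windows=1000, seed=13)
        sim = mp.simulate_genealogies(cfg)
        tot = moved = 0
        for win in sim.windows:
            k, m = win.pulse_migrants[0]
            tot += k
            moved += m
        est = moved / tot
        se = np.sqrt(f * (1 - f) / tot)
        assert abs(est - f) < 4 * se

    def test_determinism_same_seed_identical(self, two_pop_config):
        a = mp.simulate_genealogies(two_pop_config, seed=5)
        b = mp.simulate_genealogies(two_pop_config, seed=5)
        for wa, wb in zip(a.windows, b.windows):
            np.testing.assert_array_equal(wa.derived, wb.derived)
            np.testing.assert_array_equal(wa.positions, wb.positions)
            np.testing.assert_array_equal(wa.node_time, wb.node_time)

    def test_msprime_cross_check_pairwise_divergence(self):
        """Mean between-population divergence matches msprime under the
        identical two-population demography."""
        import msprime

        T, ne, mu, L, reps = 60_000.0, 5_000.0, 4.6e-9, 10_000, 150
        cfg = mp.SpeciesTreeConfig(
            labels=("A", "B"), merges=(mp.PopulationMerge(T, "B", "A"),),
            ne=ne, samples={"A": 1, "B": 1}, n_windows=reps, seed=17)
        sim = mp.simulate_genealogies(cfg)
        mine = np.mean([len(w.positions) and
                        np.mean(w.derived[:, 0] != w.derived[:, 2]) * len(w.positions)
                        for w in sim.windows])

        demography = msprime.Demography()
        demography.add_population(name="A", initial_size=ne)
        demography.add_population(name="B", initial_size=ne)
        demography.add_population(name="anc", initial_size=ne)
        demography.add_population_split(time=T, derived=["A", "B"], ancestral="anc")
        other = []
        for i in range(reps):
            ts = msprime.sim_ancestry(
                samples={"A": 1, "B": 1}, demography=demography,
                sequence_length=L, random_seed=1000 + i)
            mts = msprime.sim_mutations(ts, rate=mu, random_seed=2000 + i)
            g = mts.genotype_matrix()
            other.append(np.sum(g[:, 0] != g[:, 2]))
        theory = 2 * mu * (T + 2 * ne) * L
        assert np.mean(mine) == pytest.approx(theory, rel=0.1)
        assert np.mean(mine) == pytest.approx(np.mean(other), rel=0.15)


class TestMutateSequences:
    def test_zero_rate_gives_identical_haplotypes(self):
        cfg = mp.SpeciesTreeConfig(labels=("A",), merges=(), ne=1_000.0,
                                   samples={"A": 3}, mu=1e-300,
                                   n_windows=3, seed=2)
        sim = mp.simulate_genealogies(cfg)
        panel = mp.mutate_sequences(sim)
        for seq in panel.seqs:
            assert (seq == seq[0]).all()

    def test_expected_pairwise_differences_two_mu_t_l(self):
        """Two haplotypes with TMRCA T differ at ~2 mu T L sites."""
        T, mu, L, reps = 1e5, 4.6e-9, 10_000, 220
        cfg = mp.SpeciesTreeConfig(
            labels=("A", "B"), merges=(mp.PopulationMerge(T, "B", "A"),),
            ne=1e-6,   # negligible coalescent depth: TMRCA ~ split time
            samples={"A": 1, "B": 1}, mu=mu, n_windows=reps, seed=3)
        sim = mp.simulate_genealogies(cfg)
        panel = mp.mutate_sequences(sim)
        diffs = [np.sum(seq[0] != seq[2]) for seq in panel.seqs]
        expected = 2 * mu * T * L    # = 9.2 per 10-kb window
        se = np.sqrt(expected / reps)
        assert np.mean(diffs) == pytest.approx(expected, abs=4 * se)

    def test_same_seed_reproducible(self, two_pop_sim):
        p1 = mp.mutate_sequences(two_pop_sim, seed=9)
        p2 = mp.mutate_sequences(two_pop_sim, seed=9)
        for a, b in zip(p1.seqs, p2.seqs):
            np.testing.assert_array_equal(a, b)


class TestFragmentsAndDamage:
    def test_no_damage_fragments_are_exact_substrings(self, two_pop_panel):
        dmg = mp.DamageModel(d5=0.0, d3=0.0)
        reads = mp.fragment_and_damage(two_pop_panel, dmg, mean_depth=2,
                                       seed=4)
        for i in range(min(reads.n_reads, 200)):
            np.testing.assert_array_equal(reads.read_seq(i), reads.read_ref(i))
            w, s, ln = reads.window[i], reads.start[i], reads.length[i]
            src = two_pop_panel.seqs[w][2 * reads.ind[i] + reads.hap[i], s:s + ln]
            if reads.strand[i] == 1:
                src = COMPLEMENT[src[::-1]]
            np.testing.assert_array_equal(reads.read_ref(i), src)

    def test_geometric_decay_formula(self):
        dmg = mp.DamageModel(d5=0.3, decay=0.5)
        rates = [dmg.d5 * dmg.decay ** i for i in range(3)]
        assert rates == pytest.approx([0.30, 0.15, 0.075])

    def test_injected_curve_recovered_from_fragments(self):
        from museopop.experiments import damage_recovery

        prof, inj5, inj3 = damage_recovery(seed=21, d5=0.3, decay=0.5,
                                           n_fragments=100_000)
        for off in range(6):
            assert prof.ct5[off] == pytest.approx(inj5[off], abs=0.01)
            assert prof.ga3[off] == pytest.approx(inj3[off], abs=0.01)

    def test_fragment_length_bounds(self, two_pop_panel):
        reads = mp.fragment_and_damage(two_pop_panel, mp.DamageModel(),
                                       mean_depth=1, seed=5)
        assert reads.length.min() >= 20
        assert reads.length.max() <= two_pop_panel.window_length


class TestPileups:
    def test_error_free_hom_site_all_reads_match(self):
        cfg = mp.SpeciesTreeConfig(labels=("A",), merges=(), ne=100.0,
                                   samples={"A": 1}, mu=1e-300,
                                   window_length=500, n_windows=1, seed=6)
        sim = mp.simulate_genealogies(cfg)
        panel = mp.mutate_sequences(sim)
        pile = generate_pileups(panel, mean_depth=30, phred=1000, seed=6)
        hit = pile.counts.astype(int)
        # every site: all observed bases equal the single true allele
        for s in range(pile.n_sites):
            true = panel.seqs[0][0, s]
            assert hit[s, 0].sum() == hit[s, 0, true]

    def test_het_site_allele_balance_near_half(self, two_pop_panel):
        pile = generate_pileups(two_pop_panel, mean_depth=60, phred=1000,
                                seed=7)
        sim_windows = {w: set(p) for w, p in
                       enumerate(two_pop_panel.site_positions)}
        ratios = []
        for s in range(pile.n_sites):
            w = pile.contig_idx[s]
            pos = pile.pos[s] - 1
            if pos not in sim_windows[w]:
                continue
            for i in range(pile.n_individuals):
                h1 = two_pop_panel.seqs[w][2 * i, pos]
                h2 = two_pop_panel.seqs[w][2 * i + 1, pos]
                if h1 == h2:
                    continue
                tot = pile.counts[s, i].sum()
                if tot:
                    ratios.append(pile.counts[s, i, h1] / tot)
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.02)

    def test_phred_error_rate_matches_definition(self):
        """Q=20 on hom sites -> ~1% non-true bases over many observations."""
        cfg = mp.SpeciesTreeConfig(labels=("A",), merges=(), ne=100.0,
                                   samples={"A": 1}, mu=1e-300,
                                   window_length=10_000, n_windows=4, seed=8)
        sim = mp.simulate_genealogies(cfg)
        panel = mp.mutate_sequences(sim)
        pile = generate_pileups(panel, mean_depth=30, phred=20, seed=8)
        wrong = total = 0
        for w in range(4):
            m = pile.contig_idx == w
            true = panel.seqs[w][0, pile.pos[m] - 1]
            c = pile.counts[m, 0].astype(np.int64)
            total += c.sum()
            wrong += c.sum() - c[np.arange(m.sum()), true].sum()
        rate = wrong / total
        se = np.sqrt(0.01 * 0.99 / total)
        assert rate == pytest.approx(0.01, abs=4 * se)

    def test_pileup_tsv_round_trip(self, two_pop_panel):
        pos = {w: p[:3] for w, p in enumerate(two_pop_panel.site_positions[:2])}
        pile = generate_pileups(two_pop_panel, mean_depth=8, phred=30, seed=9,
                                positions={0: pos[0], 1: pos[1]})
        keep = pile.contig_idx < 2
        import museopop.simulate as sm

        small = sm.PileupSet(pile.contigs, pile.contig_idx[keep],
                             pile.pos[keep], pile.counts[keep],
                             pile.individuals, qual=pile.qual)
        path = "scratch_pileup.tsv"
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            p = os.path.join(d, "pile.tsv")
            small.to_tsv(p)
            back = sm.PileupSet.from_tsv(p)
            assert back.counts.sum() == small.counts.sum()
            np.testing.assert_array_equal(
                np.sort(back.pos), np.sort(small.pos))


def test_stage_rng_streams_are_independent_and_stable():
    a = stage_rng(1, "genealogy", 0).integers(0, 1 << 30, 4)
    b = stage_rng(1, "genealogy", 0).integers(0, 1 << 30, 4)
    c = stage_rng(1, "mutate", 0).integers(0, 1 << 30, 4)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)
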