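"""Weir-Cockerham Fst against an independent ANOVA oracle; windows; outliers."""

import numpy as np
import pytest

from museopop import fst as fs
from museopop.likelihoods import MISSING


def anova_wc_oracle(genotypes_by_pop):
    """Independent brute-force Weir-Cockerham components.

    Computed from the nested ANOVA on individual allele copies (pops /
    individuals / copies) rather than the closed-form frequency formulas:
    a = (MSP - MSI) / (2 n_c), b = (MSI - MSG) / 2, c = MSG.
    ``genotypes_by_pop`` is a list of per-population dosage lists (0/1/2).
    """
    r = len(genotypes_by_pop)
    ns = [len(g) for g in genotypes_by_pop]
    n = sum(ns)
    pbars = []
    ss_g = 0.0
    ss_i = 0.0
    for g in genotypes_by_pop:
        p_i = sum(g) / (2 * len(g))
        pbars.append(p_i)
        for x in g:
            ybar = x / 2.0
            # within-individual SS over the two allele copies
            for y in ([0, 0], [0, 1], [1, 1])[x]:
                ss_g += (y - ybar) ** 2
            ss_i += 2.0 * (ybar - p_i) ** 2
    pbar = sum(2 * len(g) * p / (2 * n) for g, p in zip(genotypes_by_pop, pbars))
    ss_p = sum(2 * ni * (p - pbar) ** 2 for ni, p in zip(ns, pbars))
    msg = ss_g / n
    msi = ss_i / (n - r)
    msp = ss_p / (r - 1)
    nc = (n - sum(ni * ni for ni in ns) / n) / (r - 1)
    a = (msp - msi) / (2 * nc)
    b = (msi - msg) / 2.0
    c = msg
    return a, b, c


def counts_to_genotypes(counts):
    n_aa, n_ab, n_bb = counts
    return [0] * n_aa + [1] * n_ab + [2] * n_bb


class TestPerSite:
    def test_fixed_difference_is_exactly_one(self):
        a, b, c, fst = fs.wc_fst_site((5, 0, 0), (0, 0, 5))
        assert fst == 1.0
        assert (a, b, c) == (0.5, 0.0, 0.0)

    def test_no_differentiation_nonpositive(self):
        _, _, _, fst = fs.wc_fst_site((3, 4, 3), (3, 4, 3))
        assert fst <= 0.0

    def test_hand_computed_table(self):
        """Counts (4 AA, 4 Aa, 2 aa) vs (1 AA, 3 Aa, 6 aa): value frozen
        from the independently scripted component oracle."""
        a, b, c, fst = fs.wc_fst_site((4, 4, 2), (1, 3, 6))
        assert a == pytest.approx(0.0472222222222, abs=1e-10)
        assert b == pytest.approx(0.0527777777778, abs=1e-10)
        assert c == pytest.approx(0.175, abs=1e-12)
        assert fst == pytest.approx(0.171717171717, abs=1e-10)

    def test_symmetric_in_population_order(self):
        f1 = fs.wc_fst_site((4, 4, 2), (1, 3, 6))[3]
        f2 = fs.wc_fst_site((1, 3, 6), (4, 4, 2))[3]
        assert f1 == pytest.approx(f2, abs=1e-14)

    def test_monomorphic_undefined(self):
        a, b, c, fst = fs.wc_fst_site((5, 0, 0), (5, 0, 0))
        assert np.isnan(fst)

    def test_fewer_than_two_diploids_undefined(self):
        assert np.isnan(fs.wc_fst_site((1, 0, 0), (0, 0, 5))[3])

    def test_matches_anova_oracle_on_100_random_tables(self):
        """Implementation equals the independent ANOVA-route oracle to
        1e-12 on random genotype-count tables."""
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 100:
            c1 = tuple(rng.integers(0, 8, 3))
            c2 = tuple(rng.integers(0, 8, 3))
            if sum(c1) < 2 or sum(c2) < 2:
                continue
            a, b, c, fst = fs.wc_fst_site(c1, c2)
            ao, bo, co = anova_wc_oracle(
                [counts_to_genotypes(c1), counts_to_genotypes(c2)])
            if not (sum(c1[1:]) or sum(c2[1:])) and not (c1[0] or c2[0]):
                continue
            assert a == pytest.approx(ao, abs=1e-12)
            assert b == pytest.approx(bo, abs=1e-12)
            assert c == pytest.approx(co, abs=1e-12)
            checked += 1

    def test_vectorised_matches_scalar_with_missing(self):
        rng = np.random.default_rng(1)
        dose = rng.integers(0, 3, size=(40, 10)).astype(np.int8)
        dose[rng.random(dose.shape) < 0.1] = MISSING
        comp = fs.wc_fst_components(dose, list(range(5)), list(range(5, 10)),
                                    np.zeros(40, np.int32),
                                    np.arange(1, 41), ["c"])
        for s in range(40):
            def cnt(cols):
                vals = dose[s, cols]
                vals = vals[vals != MISSING]
                return (int((vals == 0).sum()), int((vals == 1).sum()),
                        int((vals == 2).sum()))
            a, b, c, fst = fs.wc_fst_site(cnt(range(5)), cnt(range(5, 10)))
            if np.isnan(fst):
                assert not comp.defined[s] or np.isnan(comp.fst[s])
            else:
                assert comp.fst[s] == pytest.approx(fst, abs=1e-12)


class TestWindows:
    def _components(self, pos, fst_values, contig_len=200_000):
        # build components with a = fst, b+c = 1-fst so per-site ratio = fst
        S = len(pos)
        a = np.asarray(fst_values, dtype=float)
        return fs.FstSiteComponents(
            contig_idx=np.zeros(S, np.int32), pos=np.asarray(pos),
            a=a, b=np.zeros(S), c=1.0 - a, defined=np.ones(S, bool),
            contigs=["c"])

    def test_single_site_window_both_summaries_equal(self):
        comp = self._components([5], [0.42])
        track = fs.fst_windows(comp, {"c": 50_000})
        assert track.fst_mean[0] == pytest.approx(0.42)
        assert track.fst_weighted[0] == pytest.approx(0.42)

    def test_mean_of_ratios_halves(self):
        comp = self._components([5, 10], [0.0, 1.0])
        track = fs.fst_windows(comp, {"c": 50_000})
        assert track.fst_mean[0] == pytest.approx(0.5)

    def test_site_order_invariance(self):
        rng = np.random.default_rng(2)
        pos = rng.permutation(np.arange(1, 41))
        vals = rng.random(40)
        t1 = fs.fst_windows(self._components(pos, vals), {"c": 100_000})
        order = np.argsort(pos)
        t2 = fs.fst_windows(self._components(pos[order], vals[order]),
                            {"c": 100_000})
        np.testing.assert_allclose(t1.fst_mean, t2.fst_mean)

    def test_windows_tile_with_terminal_remainder(self):
        comp = self._components([1], [0.5], contig_len=120_000)
        track = fs.fst_windows(comp, {"c": 120_000})
        assert list(track.start) == [0, 50_000, 100_000]
        assert list(track.end) == [50_000, 100_000, 120_000]

    def test_window_mean_matches_coalescent_expectation(self):
        """Two populations split T generations ago: genome-wide window Fst
        near the closed-form expectation 1 - exp(-T / 2N) ... computed via
        the Hudson-style expectation for the configured demography."""
        import museopop as mp
        from museopop.likelihoods import MISSING as M

        T, ne = 100_000.0, 100_000.0
        cfg = mp.SpeciesTreeConfig(
            labels=("A", "B"), merges=(mp.PopulationMerge(T, "B", "A"),),
            ne=ne, samples={"A": 8, "B": 8}, n_windows=300, seed=51)
        sim = mp.simulate_genealogies(cfg)
        A = B = C = 0.0
        for w in range(cfg.n_windows):
            dose = sim.true_genotypes(w)
            if not len(dose):
                continue
            comp = fs.wc_fst_components(
                dose.astype(np.int8), list(range(8)), list(range(8, 16)),
                np.zeros(len(dose), np.int32), np.arange(1, len(dose) + 1),
                ["c"])
            d = comp.defined
            A += comp.a[d].sum()
            B += comp.b[d].sum()
            C += comp.c[d].sum()
        weighted = A / (A + B + C)    # ratio-of-sums: consistent for theta
        expectation = 1.0 - np.exp(-T / (2 * ne))
        assert weighted == pytest.approx(expectation, rel=0.2)


class TestOutliers:
    def _track(self, values, n_sites=10):
        S = len(values)
        return fs.FstWindowTrack(
            contigs=["c"], contig_idx=np.zeros(S, np.int32),
            start=np.arange(S) * 50_000, end=(np.arange(S) + 1) * 50_000,
            fst_mean=np.asarray(values, float),
            fst_weighted=np.asarray(values, float),
            n_sites=np.full(S, n_sites))

    def test_single_extreme_window_flagged(self):
        track, info = fs.zscore_outliers(self._track([0.1] * 19 + [0.9]))
        assert track.outlier.sum() == 1 and track.outlier[-1]

    def test_all_equal_no_outliers_with_warning(self):
        with pytest.warns(UserWarning, match="identical"):
            track, info = fs.zscore_outliers(self._track([0.3] * 25))
        assert track.outlier.sum() == 0

    def test_too_few_windows_raises(self):
        with pytest.raises(ValueError, match="eligible"):
            fs.zscore_outliers(self._track([0.1] * 5))

    def test_gaussian_z_cutoff_fraction(self):
        """Z > 1.645 flags ~5% of Gaussian windows; the 1.15 cutoff flags
        more — the two outlier definitions genuinely differ."""
        rng = np.random.default_rng(3)
        vals = rng.normal(0.2, 0.05, size=4000)
        track, info = fs.zscore_outliers(self._track(vals), z_cutoff=1.645)
        assert info["n_outliers_z"] / info["n_eligible"] == pytest.approx(
            0.05, abs=0.01)
        track2, info2 = fs.zscore_outliers(self._track(vals), z_cutoff=1.15)
        assert info2["n_outliers_z"] > info["n_outliers_z"]

    def test_min_sites_excluded_from_z(self):
        track = self._track([0.1] * 24 + [0.9])
        track.n_sites[-1] = 1
        track, info = fs.zscore_outliers(track, min_sites=5)
        assert info["n_eligible"] == 24
        assert not track.outlier[-1]


class TestAnnotation:
    def _outlier_track(self):
        track = fs.FstWindowTrack(
            contigs=["c1", "c2"], contig_idx=np.array([0, 0, 1], np.int32),
            start=np.array([0, 50_000, 0]), end=np.array([50_000, 100_000,
                                                          50_000]),
            fst_mean=np.array([0.9, 0.1, 0.8]),
            fst_weighted=np.array([0.9, 0.1, 0.8]),
            n_sites=np.full(3, 10))
        track.outlier = np.array([True, False, True])
        track.z = np.array([2.0, -0.5, 1.5])
        return track

    def test_half_open_overlap_semantics(self):
        track = self._outlier_track()
        genes = [("c1", 10, 20, "gA"),          # inside window 0
                 ("c1", 50_000, 50_010, "gB"),  # outside [0, 50000)
                 ("c2", 49_999, 60_000, "gC")]  # 1-bp overlap with window 2
        hits = fs.annotate_overlaps(track, genes)
        assert hits[0] == ["gA"]
        assert hits[2] == ["gC"]

    def test_three_genes_two_windows_exact_mapping(self):
        track = self._outlier_track()
        genes = [("c1", 100, 200, "g1"), ("c1", 40_000, 60_000, "g2"),
                 ("c2", 0, 10, "g3")]
        hits = fs.annotate_overlaps(track, genes)
        assert hits == {0: ["g1", "g2"], 2: ["g3"]}

    def test_manhattan_track_file(self, tmp_path):
        track = self._outlier_track()
        path = tmp_path / "manhattan.tsv"
        fs.write_manhattan_tsv(track, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "contig\tmidpoint\tfst\tz"
        assert lines[1].split("\t") == ["c1", "25000", "0.900000", "2.0000"]

    def test_bed_and_gff_round_trip(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("c1\t10\t20\tgA\nc2\t5\t30\tgB\n")
        assert fs.read_intervals(bed) == [("c1", 10, 20, "gA"),
                                          ("c2", 5, 30, "gB")]
        gff = tmp_path / "genes.gff"
        gff.write_text("c1\tsrc\tgene\t11\t20\t.\t+\t.\tID=gA;Name=gA\n")
        assert fs.read_intervals(gff) == [("c1", 10, 20, "gA")]
        bad = tmp_path / "bad.bed"
        bad.write_text("c1\t10\n")
        with pytest.raises(ValueError, match="bad.bed:1"):
            fs.read_intervals(bad)
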