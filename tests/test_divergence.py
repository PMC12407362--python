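"""Tests for the F_ST / pi scan and GDR calling."""

import itertools

import numpy as np
import pandas as pd
import pytest

import invscan.divergence as div
import invscan.simulate as sim
from invscan.matrix import MISSING, GenotypeMatrix


def textbook_theta(n_list, j_list):
    """Independent transcription of the general r-population Weir-Cockerham
    estimator in its allele-count form, coded with plain Python floats."""
    r = len(n_list)
    p = [j / n for n, j in zip(n_list, j_list)]
    nbar = sum(n_list) / r
    nsum = sum(n_list)
    nc = (nsum - sum(n * n for n in n_list) / nsum) / (r - 1)
    pbar = sum(n * pi for n, pi in zip(n_list, p)) / nsum
    s2 = sum(n * (pi - pbar) ** 2 for n, pi in zip(n_list, p)) / ((r - 1) * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r)
    return a, a + b


def make_matrix(dosages, positions=None, chrom="chr1"):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, s = dosages.shape
    if positions is None:
        positions = np.arange(s)
    return GenotypeMatrix(
        dosages=dosages,
        chroms=np.full(s, chrom, dtype=object),
        positions=np.asarray(positions),
        samples=[f"s{i}" for i in range(n)],
    )


class TestFilterVariants:
    def test_maf_boundaries(self):
        # 25 samples (50 alleles): one het -> MAF 0.02, removed;
        # one hom-alt -> MAF 0.04, kept
        d = np.zeros((25, 2), dtype=np.int8)
        d[0, 0] = 1
        d[0, 1] = 2
        gm = make_matrix(d)
        out = div.filter_variants(gm, maf_min=0.03, missing_max=0.1)
        assert list(out.positions) == [1]

    def test_maf_exactly_at_threshold_retained(self):
        # 100 alleles, 3 alt -> MAF exactly 0.03
        d = np.zeros((50, 1), dtype=np.int8)
        d[0] = 2
        d[1] = 1
        out = div.filter_variants(make_matrix(d), maf_min=0.03)
        assert out.n_sites == 1

    def test_missing_rate_threshold(self):
        d = np.tile([0, 1, 2, 1, 0] * 5, (2, 1)).T.astype(np.int8)  # 25 x 2
        d = d.copy()
        d[:3, 0] = MISSING   # 3/25 = 0.12 missing -> removed
        d[:2, 1] = MISSING   # 2/25 = 0.08 -> kept
        out = div.filter_variants(make_matrix(d), maf_min=0.0, missing_max=0.1)
        assert list(out.positions) == [1]

    def test_empty_input(self):
        gm = make_matrix(np.empty((3, 0), dtype=np.int8))
        assert div.filter_variants(gm).n_sites == 0


class TestAlleleCounts:
    def test_direct_count(self):
        gm = make_matrix(np.array([[0], [1], [2]]))
        df = div.allele_counts_by_group(gm, ["g1", "g1", "g1"] [:2] + ["g2"])
        assert df.n1[0] == 4 and df.j1[0] == 1
        assert df.n2[0] == 2 and df.j2[0] == 2

    def test_all_missing_group_flagged_undefined(self):
        d = np.array([[0], [1], [MISSING]], dtype=np.int8)
        df = div.allele_counts_by_group(make_matrix(d), ["g1", "g1", "g2"])
        assert not df.defined[0]

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(3)
        d = rng.integers(-1, 3, size=(20, 50)).astype(np.int8)
        labels = ["g1"] * 12 + ["g2"] * 8
        df = div.allele_counts_by_group(make_matrix(d), labels)
        for s in range(50):
            for gi, g in enumerate(["g1", "g2"], start=1):
                calls = [
                    d[i, s] for i in range(20) if labels[i] == g and d[i, s] != MISSING
                ]
                assert df[f"n{gi}"][s] == 2 * len(calls)
                assert df[f"j{gi}"][s] == sum(calls)


class TestFstSite:
    def test_fixed_difference_theta_one(self):
        a, d, theta = div.fst_site(20, 0, 20, 20)
        assert theta == pytest.approx(1.0)

    def test_equal_frequencies_nonpositive(self):
        a, d, theta = div.fst_site(20, 10, 20, 10)
        assert theta <= 0.0

    def test_monomorphic_undefined(self):
        a, d, theta = div.fst_site(20, 0, 20, 0)
        assert np.isnan(a) and np.isnan(d)

    def test_against_independent_textbook_implementation(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n1, n2 = rng.integers(4, 60, size=2)
            j1 = rng.integers(0, n1 + 1)
            j2 = rng.integers(0, n2 + 1)
            if (j1 + j2) in (0, n1 + n2):
                continue
            a, d, theta = div.fst_site(n1, j1, n2, j2)
            a_ref, d_ref = textbook_theta([n1, n2], [j1, j2])
            assert a == pytest.approx(a_ref, abs=1e-12)
            assert d == pytest.approx(d_ref, abs=1e-12)

    def test_group_label_swap_invariance(self):
        _, _, t1 = div.fst_site(30, 7, 44, 21)
        _, _, t2 = div.fst_site(44, 21, 30, 7)
        assert t1 == pytest.approx(t2, abs=1e-14)


class TestPiSite:
    def test_monomorphic_zero(self):
        assert div.pi_site(np.array([10]), np.array([0]))[0] == 0.0
        assert div.pi_site(np.array([10]), np.array([10]))[0] == 0.0

    def test_small_case(self):
        assert div.pi_site(np.array([4]), np.array([2]))[0] == pytest.approx(2 / 3)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(2, 30))
            j = int(rng.integers(0, n + 1))
            alleles = [1] * j + [0] * (n - j)
            pairs = list(itertools.combinations(alleles, 2))
            oracle = sum(x != y for x, y in pairs) / len(pairs)
            assert div.pi_site(np.array([n]), np.array([j]))[0] == pytest.approx(oracle)

    def test_undefined_below_two(self):
        assert np.isnan(div.pi_site(np.array([1]), np.array([1]))[0])


class TestWindowedScan:
    @pytest.fixture
    def stats(self, small_panel):
        _, gm, labels, _ = small_panel
        return div.site_stats(div.filter_variants(gm), labels)

    def test_window_count_default_geometry(self):
        pos = np.arange(0, 300_000, 1_000)
        stats = pd.DataFrame(
            {
                "chrom": "c", "pos": pos,
                "a": 0.1, "d": 0.5, "theta": 0.2, "pi1": 0.1, "pi2": 0.1,
            }
        )
        windows = div.windowed_scan(stats, {"c": 300_000})
        assert len(windows) == 21  # floor((300000-100000)/10000)+1

    def test_empty_window_undefined_fst_zero_pi(self):
        stats = pd.DataFrame(
            {
                "chrom": ["c"], "pos": [250_000],
                "a": [0.1], "d": [0.5], "theta": [0.2], "pi1": [0.2], "pi2": [0.0],
            }
        )
        windows = div.windowed_scan(
            stats, {"c": 300_000}, div.ScanConfig(window=100_000, step=100_000)
        )
        first = windows.iloc[0]
        assert np.isnan(first.fst_weighted) and first.pi1 == 0.0

    def test_weighted_value_matches_resummation(self, stats, small_panel):
        spec = small_panel[0]
        cfg = div.ScanConfig(window=50_000, step=10_000)
        windows = div.windowed_scan(stats, {spec.chrom: spec.chrom_length}, cfg)
        for _, w in windows.sample(10, random_state=0).iterrows():
            inside = stats[(stats.pos >= w.start) & (stats.pos < w.end)]
            ok = inside[~inside.d.isna()]
            if len(ok) and ok.d.sum() != 0:
                assert w.fst_weighted == pytest.approx(ok.a.sum() / ok.d.sum())
            else:
                assert np.isnan(w.fst_weighted)
            assert w.pi1 == pytest.approx(ok.pi1.sum() / (w.end - w.start))

    def test_site_order_invariance(self, stats, small_panel):
        spec = small_panel[0]
        shuffled = stats.sample(frac=1.0, random_state=1).reset_index(drop=True)
        w1 = div.windowed_scan(stats, {spec.chrom: spec.chrom_length})
        w2 = div.windowed_scan(shuffled, {spec.chrom: spec.chrom_length})
        pd.testing.assert_frame_equal(w1, w2)

    def test_step_exceeding_window_rejected(self):
        with pytest.raises(ValueError):
            div.ScanConfig(window=10_000, step=20_000)


class TestGdrCalling:
    def window_frame(self, values, window=10_000):
        starts = np.arange(len(values)) * window
        return pd.DataFrame(
            {
                "chrom": "c", "start": starts, "end": starts + window,
                "n_sites": 10, "n_defined": 10,
                "fst_weighted": values, "fst_mean": values,
                "pi1": 0.0, "pi2": 0.0,
            }
        )

    def test_constant_track_yields_no_gdrs(self):
        gdrs = div.call_gdrs(self.window_frame(np.full(50, 0.3)))
        assert len(gdrs) == 0

    def test_contiguous_top_windows_merge_to_one_region(self):
        values = np.linspace(0.0, 0.4, 100)
        values[40:45] = [0.9, 0.92, 0.94, 0.96, 0.98]
        gdrs = div.call_gdrs(self.window_frame(values))
        assert len(gdrs) == 1
        assert gdrs.start[0] == 400_000 and gdrs.end[0] == 450_000
        assert gdrs.mean_fst[0] == pytest.approx(np.mean([0.9, 0.92, 0.94, 0.96, 0.98]))

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="windows"):
            div.call_gdrs(self.window_frame(np.linspace(0, 1, 10)))

    def test_planted_block_recovered_across_seeds(self):
        """The called GDRs cover >= 90% of the planted divergence block and
        <= 10% of the background, across seeds."""
        cfg = div.ScanConfig(window=50_000, step=50_000)
        block = (900_000, 1_000_000)
        block_cov, bg_cov = [], []
        for seed in range(20):
            spec = sim.PopulationSpec(
                n_sites=10_000, chrom_length=2_000_000,
                f_background=0.05, f_block=0.6, block=block, seed=seed,
            )
            gm, labels, _ = sim.simulate_population(spec)
            stats = div.site_stats(div.filter_variants(gm), labels)
            windows = div.windowed_scan(stats, {spec.chrom: 2_000_000}, cfg)
            gdrs = div.call_gdrs(windows, cfg)
            cov = sum(
                max(0, min(e, block[1]) - max(s, block[0]))
                for s, e in zip(gdrs.start, gdrs.end)
            )
            outside = sum(e - s for s, e in zip(gdrs.start, gdrs.end)) - cov
            block_cov.append(cov / (block[1] - block[0]))
            bg_cov.append(outside / (2_000_000 - (block[1] - block[0])))
        assert np.mean(block_cov) >= 0.9
        assert np.mean(bg_cov) <= 0.1

    def test_block_f_monotonicity(self):
        """Raising the planted F of the block never decreases the block's
        mean windowed F_ST (averaged over seeds)."""
        cfg = div.ScanConfig(window=50_000, step=50_000)
        block = (900_000, 1_000_000)
        means = []
        for f_block in (0.1, 0.3, 0.6):
            vals = []
            for seed in range(20):
                spec = sim.PopulationSpec(
                    n_sites=4_000, chrom_length=2_000_000,
                    f_background=0.05, f_block=f_block, block=block, seed=seed,
                )
                gm, labels, _ = sim.simulate_population(spec)
                stats = div.site_stats(gm, labels)
                windows = div.windowed_scan(stats, {spec.chrom: 2_000_000}, cfg)
                in_block = windows[(windows.start >= block[0]) & (windows.end <= block[1])]
                vals.append(in_block.fst_weighted.mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
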