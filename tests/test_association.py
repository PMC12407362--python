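"""Tests for PCA, the GLM scan, haplotype grouping and phenotype formulas."""

import numpy as np
import pytest
from scipy import stats as sps

import invscan.association as assoc
import invscan.divergence as div
import invscan.simulate as sim
from invscan.matrix import MISSING, GenotypeMatrix


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


class TestPca:
    def test_two_clusters_separate_on_pc1(self):
        d = np.vstack([np.tile([0, 0, 2, 0, 2], (5, 1)),
                       np.tile([2, 2, 0, 2, 0], (5, 1))])
        pca = assoc.genotype_pca(make_matrix(d), 2)
        pc1 = pca.coordinates[:, 0]
        assert np.std(pc1[:5]) == pytest.approx(0.0, abs=1e-9)
        assert np.std(pc1[5:]) == pytest.approx(0.0, abs=1e-9)
        assert np.sign(pc1[:5]).min() != np.sign(pc1[5:]).max()

    def test_demes_linearly_separable_across_seeds(self):
        ok = 0
        for seed in range(20):
            spec = sim.PopulationSpec(
                n_sites=1_000, f_background=0.3, f_block=0.3, block=None, seed=seed
            )
            gm, labels, _ = sim.simulate_population(spec)
            pca = assoc.genotype_pca(gm, 2)
            pc1 = pca.coordinates[:, 0]
            ai = pc1[np.array(labels) == "AI"]
            ac = pc1[np.array(labels) == "AC"]
            ok += ai.max() < ac.min() or ac.max() < ai.min()
        assert ok >= 19

    def test_duplicating_samples_keeps_directions(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(12, 80)).astype(np.int8)
        p1 = assoc.genotype_pca(make_matrix(d), 2)
        p2 = assoc.genotype_pca(make_matrix(np.vstack([d, d])), 2)
        # duplicated set: each sample keeps its coordinate up to sign/scale
        for c in range(2):
            x = p1.coordinates[:, c]
            y = p2.coordinates[:12, c]
            corr = abs(np.corrcoef(x, y)[0, 1])
            assert corr > 0.999

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            assoc.genotype_pca(make_matrix(np.zeros((4, 5), dtype=np.int8)))


class TestGlmScan:
    def test_null_pvalues_uniform(self):
        """Permuted (null) phenotypes give uniform p-values (KS test below
        the 1% critical value)."""
        rng = np.random.default_rng(2)
        spec = sim.PopulationSpec(
            n_sites=2_000, f_background=0.1, f_block=0.1, block=None, seed=3
        )
        gm, labels, _ = sim.simulate_population(spec)
        y = rng.normal(size=gm.n_samples)  # independent of genotype
        pca = assoc.genotype_pca(gm, 2)
        res = assoc.glm_scan(y, gm, pca)
        stat = sps.kstest(res.table.p, "uniform").statistic
        crit_1pct = 1.628 / np.sqrt(len(res.table))
        assert stat < crit_1pct

    def test_type_i_error_calibrated(self):
        """Empirical rejection rate at nominal alpha=0.05 stays in
        [0.04, 0.06] over many null sites."""
        rejections = total = 0
        for seed in range(20):
            spec = sim.PopulationSpec(
                n_sites=2_000, f_background=0.0, f_block=0.0, block=None, seed=seed
            )
            gm, _, _ = sim.simulate_population(spec)
            y = np.random.default_rng(seed + 100).normal(size=gm.n_samples)
            res = assoc.glm_scan(y, gm, covariates=None)
            rejections += (res.table.p < 0.05).sum()
            total += len(res.table)
        assert 0.04 <= rejections / total <= 0.06

    def test_matches_bruteforce_regression_and_finds_causal_site(self):
        rng = np.random.default_rng(4)
        spec = sim.PopulationSpec(
            n_sites=300, f_background=0.1, f_block=0.1, block=None, seed=5
        )
        gm, _, _ = sim.simulate_population(spec)
        causal = 123
        y = 2.0 * gm.dosages[:, causal] + rng.normal(0, 0.5, gm.n_samples)
        pca = assoc.genotype_pca(gm, 2)
        res = assoc.glm_scan(y, gm, pca)
        tab = res.table.set_index("pos")
        assert tab.p.idxmin() == gm.positions[causal]
        # independent site-by-site least squares oracle
        cov = pca.coordinates[:, :2]
        for s in rng.choice(gm.n_sites, 15, replace=False):
            x = gm.dosages[:, s].astype(float)
            if np.std(x) == 0:
                assert gm.positions[s] not in tab.index
                continue
            X = np.column_stack([np.ones_like(y), x, cov])
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            dof = len(y) - X.shape[1]
            sigma2 = resid @ resid / dof
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            t = beta[1] / se
            p = 2 * sps.t.sf(abs(t), dof)
            row = tab.loc[gm.positions[s]]
            assert row.beta == pytest.approx(beta[1], abs=1e-10)
            assert row.p == pytest.approx(p, abs=1e-10)

    def test_affine_invariance(self):
        spec = sim.PopulationSpec(n_sites=200, block=None, seed=6)
        gm, _, _ = sim.simulate_population(spec)
        y = np.random.default_rng(7).normal(size=gm.n_samples)
        pca = assoc.genotype_pca(gm, 2)
        p1 = assoc.glm_scan(y, gm, pca).table.p
        p2 = assoc.glm_scan(5.0 * y - 3.0, gm, pca).table.p
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_monomorphic_sites_absent(self):
        d = np.array([[0, 1], [0, 2], [0, 0], [0, 1]], dtype=np.int8)
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = assoc.glm_scan(y, make_matrix(d))
        assert list(res.table.pos) == [1]

    def test_too_many_covariates_rejected(self):
        d = np.array([[0, 1], [1, 2], [2, 0], [0, 1]], dtype=np.int8)
        with pytest.raises(ValueError):
            assoc.glm_scan(np.ones(4), make_matrix(d), np.ones((4, 3)))


class TestSignificanceThreshold:
    def test_direct_division(self):
        p_star, _ = assoc.significance_threshold(2_918_655)
        assert p_star == pytest.approx(1.71e-8, rel=0.01)

    def test_effective_count_log_threshold(self):
        p_star, neg_log = assoc.significance_threshold(
            2_918_655, alpha=0.05, n_eff=2_873_563
        )
        assert p_star == pytest.approx(1.74e-8, rel=0.001)
        assert neg_log == 7.76

    def test_single_site(self):
        assert assoc.significance_threshold(1) == (0.05, 1.3)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            assoc.significance_threshold(0)


class TestHaplotypes:
    def test_single_pattern_single_group(self):
        d = np.tile([0, 2, 0, 2], (5, 1)).astype(np.int8)
        haps = assoc.assign_haplotypes(make_matrix(d), [("chr1", i) for i in range(4)])
        assert set(haps.groups.values()) == {"A"}

    def test_two_patterns_two_groups_ordered_by_phenotype(self):
        d = np.vstack([np.zeros((3, 4)), np.full((6, 4), 2)]).astype(np.int8)
        gm = make_matrix(d)
        pheno = {s: (90.0 if i < 3 else 2.0) for i, s in enumerate(gm.samples)}
        haps = assoc.assign_haplotypes(gm, [("chr1", i) for i in range(4)], pheno)
        # smaller group has the higher mean phenotype -> labelled A
        assert haps.groups["s0"] == "A" and haps.groups["s5"] == "B"

    def test_missing_call_unassigned(self):
        d = np.zeros((3, 2), dtype=np.int8)
        d[1, 0] = MISSING
        haps = assoc.assign_haplotypes(make_matrix(d), [("chr1", 0), ("chr1", 1)])
        assert haps.groups["s1"] == assoc.UNASSIGNED

    def test_sample_reordering_invariance(self):
        rng = np.random.default_rng(8)
        d = rng.choice([0, 2], size=(10, 3)).astype(np.int8)
        gm = make_matrix(d)
        sites = [("chr1", i) for i in range(3)]
        h1 = assoc.assign_haplotypes(gm, sites)
        perm = rng.permutation(10)
        gm2 = GenotypeMatrix(
            dosages=d[perm], chroms=gm.chroms, positions=gm.positions,
            samples=[gm.samples[i] for i in perm],
        )
        h2 = assoc.assign_haplotypes(gm2, sites)
        assert {s: h1.patterns[s] for s in gm.samples} == {
            s: h2.patterns[s] for s in gm.samples
        }

    def test_unknown_site_rejected(self):
        with pytest.raises(ValueError):
            assoc.assign_haplotypes(make_matrix(np.zeros((2, 2), dtype=np.int8)),
                                    [("chrX", 99)])


class TestCompareGroups:
    def test_closed_form_pooled_t(self):
        t, p = assoc.compare_groups([1, 2, 3], [7, 8, 9])
        assert t == pytest.approx(-7.348, abs=0.001)
        assert p == pytest.approx(0.0018, abs=0.0002)

    def test_identical_groups(self):
        assert assoc.compare_groups([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_zero_variance_different_means(self):
        t, p = assoc.compare_groups([5, 5], [1, 1])
        assert np.isinf(t) and p == 0.0

    def test_default_effect_sizes_highly_significant(self):
        groups = {f"t{i}": "tolerant" for i in range(8)}
        groups.update({f"s{i}": "sensitive" for i in range(8)})
        df = sim.simulate_phenotypes(groups, seed=1)
        t, p = assoc.compare_groups(
            df[df.group == "tolerant"].survival, df[df.group == "sensitive"].survival
        )
        assert p < 0.001

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            assoc.compare_groups([1.0], [2.0, 3.0])


class TestPhenotypeFormulas:
    def test_relative_conductivity_as_printed(self):
        assert assoc.relative_conductivity(1, 3, 5) == pytest.approx(2.0)
        assert assoc.relative_conductivity(1, 3, 1) == pytest.approx(0.0)

    def test_relative_conductivity_conventional_switch(self):
        assert assoc.relative_conductivity(1, 3, 5, conventional=True) == pytest.approx(0.5)

    def test_degenerate_conductivities(self):
        with pytest.raises(ValueError):
            assoc.relative_conductivity(2, 2, 5)

    def test_anthocyanin_content(self):
        assert assoc.anthocyanin_content(0.5, 0.25) == pytest.approx(2.0)
        assert assoc.anthocyanin_content(0.0, 1.0) == 0.0
        with pytest.raises(ValueError):
            assoc.anthocyanin_content(0.5, 0.0)
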