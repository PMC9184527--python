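"""QC, imputation, kinship, diversity, PCA and LD pruning."""

import numpy as np
import pytest
from scipy import stats

import breedscan as bs
from conftest import make_genotypes


class TestQC:
    def test_maf_threshold_is_strict(self):
        # 50 hybrids: MAF exactly 0.05 retained, 0.04 removed
        n = 50
        c_low = np.zeros(n)
        c_low[:4] = 1.0  # freq 4/100 = 0.04
        c_edge = np.zeros(n)
        c_edge[:5] = 1.0  # freq 0.05
        c_fixed = np.full(n, 2.0)  # monomorphic, MAF 0
        G = make_genotypes(np.column_stack([c_low, c_edge, c_fixed]))
        G2, rep = bs.qc_and_impute(G)
        assert list(G2.snp_ids) == ["s1"]  # only the MAF-0.05 SNP survives
        assert rep.n_removed_maf == 2  # 0.04 SNP and the monomorphic SNP

    def test_missingness_threshold_is_strict(self):
        n = 20
        base = np.tile([0.0, 1.0, 2.0, 1.0], 5)
        c_25 = base.copy()
        c_25[:5] = np.nan  # 25% missing -> removed
        c_20 = base.copy()
        c_20[:4] = np.nan  # exactly 20% -> retained
        G = make_genotypes(np.column_stack([c_25, c_20]))
        G2, rep = bs.qc_and_impute(G)
        assert rep.n_removed_missing == 1
        assert list(G2.snp_ids) == ["s1"]

    def test_identity_on_clean_matrix(self):
        rng = np.random.default_rng(0)
        G = make_genotypes(rng.binomial(1, 0.5, (30, 10)) + rng.binomial(1, 0.5, (30, 10)))
        G2, rep = bs.qc_and_impute(G)
        np.testing.assert_array_equal(G.counts, G2.counts)
        assert rep.n_imputed == 0

    def test_modal_imputation(self):
        col = np.array([0.0, 0.0, 0.0, 1.0, 2.0, 2.0, np.nan, np.nan, 1.0, 1.0] * 2)
        G = make_genotypes(col[:, None])
        G2, rep = bs.qc_and_impute(G, max_missing=0.5)
        assert rep.n_imputed == 4
        assert (G2.counts[np.isnan(col)] == 0.0).all()  # modal genotype, ties -> smaller

    def test_idempotent(self, qc_panel):
        G2, *_ = qc_panel
        G3, rep = bs.qc_and_impute(G2)
        np.testing.assert_array_equal(G2.counts, G3.counts)
        assert rep.n_retained == G2.n_snps

    def test_all_removed_raises_with_tallies(self):
        G = make_genotypes(np.zeros((10, 3)))
        with pytest.raises(ValueError, match="MAF filter removed 3"):
            bs.qc_and_impute(G)


class TestGRM:
    def test_hand_case(self):
        # 3 hybrids x 2 SNPs; p = (0.5, 0.5); denom = 2*0.25*2 = 1
        G = make_genotypes([[0, 2], [2, 0], [1, 1]])
        K = bs.grm(G)
        Z = np.array([[-1.0, 1.0], [1.0, -1.0], [0.0, 0.0]])
        expected = Z @ Z.T / 1.0
        np.testing.assert_allclose(K.values, expected, atol=1e-12)

    def test_duplicate_hybrids_equal_rows(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 3, (5, 40)).astype(float)
        counts[3] = counts[0]
        K = bs.grm(make_genotypes(counts))
        np.testing.assert_allclose(K.values[0], K.values[3])
        assert K.values[0, 0] == pytest.approx(K.values[3, 3])

    def test_psd_and_monomorphic_warning(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 3, (30, 100)).astype(float)
        counts[:, 0] = 2.0  # monomorphic
        with pytest.warns(UserWarning, match="monomorphic"):
            K = bs.grm(make_genotypes(counts))
        assert np.linalg.eigvalsh(K.values).min() >= -1e-8

    def test_requires_complete(self):
        counts = np.array([[0.0, np.nan], [2.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="complete"):
            bs.grm(make_genotypes(counts))

    def test_hybrid_order_equivariance(self, qc_panel):
        G2, *_ = qc_panel
        K = bs.grm(G2)
        perm = np.random.default_rng(3).permutation(G2.n_hybrids)
        K2 = bs.grm(G2.take_hybrids(perm))
        np.testing.assert_allclose(K2.values, K.values[np.ix_(perm, perm)], atol=1e-12)


class TestIBS:
    def test_trivial_values(self):
        G = make_genotypes([[0, 0, 0], [2, 2, 2], [0, 0, 0]])
        M = bs.ibs_matrix(G).values
        assert M[0, 2] == 1.0  # identical rows
        assert M[0, 1] == 0.0  # opposite homozygotes everywhere
        assert np.allclose(np.diag(M), 1.0)

    def test_hand_case_3x3(self):
        G = make_genotypes([[0, 1, 2], [1, 1, 0], [2, 0, 1]])
        M = bs.ibs_matrix(G).values
        # |diffs| h0-h1: 1,0,2 -> mean (2-d)/2 = (0.5+1+0)/3
        assert M[0, 1] == pytest.approx((0.5 + 1.0 + 0.0) / 3)
        assert M[0, 2] == pytest.approx((0.0 + 0.5 + 0.5) / 3)
        assert M[1, 2] == pytest.approx((0.5 + 0.5 + 0.5) / 3)


class TestNei:
    def test_fixed_group_zero(self):
        G = make_genotypes([[0, 2], [0, 2], [2, 0], [2, 0]])
        he = bs.nei_diversity(G, np.array(["a", "a", "b", "b"], dtype=object))
        assert he["a"] == 0.0 and he["b"] == 0.0

    def test_half_frequency_limit(self):
        n = 2000
        col = np.concatenate([np.zeros(n // 2), np.full(n // 2, 2.0)])
        he = bs.nei_diversity(make_genotypes(col[:, None]), np.array(["g"] * n, dtype=object))
        assert he["g"] == pytest.approx(0.5, abs=1e-3)

    def test_stable_across_year_terciles(self):
        # stationary panel (no structure drift, no selection)
        cfg = bs.SimConfig(
            n_hybrids=120, n_snps=4000, n_selected_loci=0, structure_tau=np.inf,
            missing_rate=0.0, seed=21,
        )
        G, meta, _ = bs.simulate_panel(cfg)
        he = bs.nei_diversity(G, meta.terciles())
        vals = list(he.values())
        assert max(vals) - min(vals) < 0.01


class TestPCA:
    def test_separated_cohorts(self):
        # two year cohorts fixed for disjoint alleles
        n, m = 40, 60
        counts = np.zeros((n, m))
        counts[: n // 2, : m // 2] = 2.0
        counts[n // 2 :, m // 2 :] = 2.0
        years = np.concatenate([np.full(n // 2, 1950.0), np.full(n // 2, 2015.0)])
        res = bs.pca_year(make_genotypes(counts), years)
        assert res.r2_pc1_year > 0.9
        # sign convention: PC1 positively correlated with year
        assert np.corrcoef(res.scores[:, 0], years)[0, 1] > 0

    def test_year_independent_structure_below_null(self):
        rng = np.random.default_rng(5)
        counts = rng.binomial(2, 0.4, (50, 300)).astype(float)
        years = np.arange(50, dtype=float)
        res = bs.pca_year(make_genotypes(counts), years)
        null = []
        for _ in range(200):
            null.append(bs.pca_year(make_genotypes(counts), rng.permutation(years)).r2_pc1_year)
        assert res.r2_pc1_year <= np.quantile(null, 0.95)

    def test_duplicated_hybrids_identical_scores(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 3, (12, 50)).astype(float)
        counts[5] = counts[2]
        res = bs.pca_year(make_genotypes(counts), np.arange(12, dtype=float))
        np.testing.assert_allclose(res.scores[2], res.scores[5], atol=1e-8)

    def test_explained_variance_sums_to_total(self, qc_panel):
        G2, meta, *_ = qc_panel
        res = bs.pca_year(G2, meta.years)
        X = G2.counts - G2.counts.mean(axis=0)
        total = (X**2).sum() / (G2.n_hybrids - 1)
        assert res.explained_variance.sum() == pytest.approx(total, rel=1e-10)

    def test_too_few_hybrids(self):
        with pytest.raises(ValueError, match="3 hybrids"):
            bs.pca_year(make_genotypes([[0, 1], [1, 0]]), np.array([1.0, 2.0]))


class TestLDPrune:
    def test_duplicate_column_pruned(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 3, (40, 10)).astype(float)
        counts[:, 4] = counts[:, 2]
        kept = bs.ld_prune(make_genotypes(counts))
        assert (2 in kept) != (4 in kept)

    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(8)
        counts = rng.binomial(2, 0.5, (500, 20)).astype(float)
        kept = bs.ld_prune(make_genotypes(counts), r2_max=0.2)
        assert len(kept) == 20

    def test_posthoc_r2_bound(self, qc_panel):
        G2, *_ = qc_panel
        kept = bs.ld_prune(G2, window_snps=30, step=5, r2_max=0.3)
        # verify within a window of the retained set
        for ch in set(G2.chrom.astype(str)):
            idx = [j for j in kept if str(G2.chrom[j]) == ch][:30]
            if len(idx) < 2:
                continue
            r = np.corrcoef(G2.counts[:, idx], rowvar=False)
            np.fill_diagonal(r, 0.0)
            assert np.nanmax(r**2) <= 0.3 + 1e-9

    def test_target_n_subsample_seeded(self, qc_panel):
        G2, *_ = qc_panel
        a = bs.ld_prune(G2, target_n=100, seed=1)
        b = bs.ld_prune(G2, target_n=100, seed=1)
        c = bs.ld_prune(G2, target_n=100, seed=2)
        assert len(a) == 100 and (a == b).all() and not (a == c).all()
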