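"""F_ST among gene pools and the cyto-nuclear / habitat test battery."""

import numpy as np
import pytest
from scipy import stats

import finekin as fk
from tests.conftest import make_hwe_genotypes

AFRICAN_SP = [0.0341, 0.0124, 0.0273]
NEOTROPICAL_SP = [0.0166, 0.0003, 0.0090, 0.0074]
AFRICAN_EIG = [0.272, 0.111, 0.154]
NEOTROPICAL_EIG = [0.029, 0.057, 0.038, 0.073]


class TestFst:
    def test_fixed_disjoint_alleles_give_theta_one(self):
        calls_a = [[("1", "1")] for _ in range(10)]
        calls_b = [[("2", "2")] for _ in range(10)]
        g = fk.GenotypeMatrix(
            [f"i{j}" for j in range(20)], ["L1"], calls_a + calls_b
        )
        labels = ["A"] * 10 + ["B"] * 10
        assert fk.weir_cockerham_fst(g, labels) == pytest.approx(1.0, abs=1e-9)

    def test_random_labels_p_roughly_uniform(self, rng):
        ps = []
        for rep in range(60):
            g = make_hwe_genotypes(rng, 24, n_loci=2)
            labels = list(rng.permutation(["A"] * 12 + ["B"] * 12))
            ps.append(
                fk.fst_among_pools(g, labels, n_perm=99, seed=rep).p
            )
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_purging_admixed_individuals_raises_differentiation(self, two_deme_dataset):
        d = two_deme_dataset
        res = fk.run_admixture(d.genotypes, 2, burnin=800, iters=3000, seed=21)[0]
        lab50, _ = fk.assign_gene_pools(res, 0.5)
        lab87, _ = fk.assign_gene_pools(res, 0.875)
        f50 = fk.fst_among_pools(d.genotypes, lab50, n_perm=99, seed=1)
        f87 = fk.fst_among_pools(d.genotypes, lab87, n_perm=99, seed=1)
        assert f87.fst > f50.fst
        assert f50.p <= 0.05

    def test_single_group_undefined(self, rng):
        g = make_hwe_genotypes(rng, 10)
        with pytest.raises(ValueError):
            fk.fst_among_pools(g, ["A"] * 10)


class TestAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        x = rng.normal(size=20)
        groups = np.array(["a"] * 10 + ["b"] * 10)
        res = fk.anova_scores(x, groups)
        t, p = stats.ttest_ind(x[:10], x[10:], equal_var=True)
        assert res.statistic == pytest.approx(t**2, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)

    def test_null_p_uniform(self, rng):
        ps = []
        for _ in range(500):
            x = rng.normal(size=24)
            groups = np.repeat(["a", "b", "c"], 8)
            ps.append(fk.anova_scores(x, groups).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_partitioned_scores_highly_significant(self, rng):
        x = np.concatenate([rng.normal(0, 0.2, 15), rng.normal(3, 0.2, 15)])
        res = fk.anova_scores(x, ["H19"] * 15 + ["H24"] * 15)
        assert res.p <= 0.001
        assert set(res.group_means) == {"H19", "H24"}


class TestFisher:
    def test_diagonal_2x2_exact_value(self):
        res = fk.fisher_association(np.array([[10, 0], [0, 10]]))
        assert res.p == pytest.approx(2 / 184756, rel=1e-9)
        assert res.null_type == "exact"

    def test_monte_carlo_agrees_with_exact_on_2x2(self):
        # run the rxc Monte-Carlo machinery on a 2x2 by embedding it
        from finekin.heterogeneity import _log_table_prob

        table = np.array([[10, 3], [2, 8]])
        exact = stats.fisher_exact(table)[1]
        rng = np.random.default_rng(1)
        rows, cols = table.sum(1), table.sum(0)
        row_lab = np.repeat([0, 1], rows)
        col_lab = np.repeat([0, 1], cols)
        obs = _log_table_prob(table)
        n_mc = 100_000
        le = 0
        for _ in range(n_mc):
            t = np.zeros_like(table)
            np.add.at(t, (row_lab, rng.permutation(col_lab)), 1)
            le += _log_table_prob(t) <= obs + 1e-9
        assert (le + 1) / (n_mc + 1) == pytest.approx(exact, abs=0.002)

    def test_perfect_coupling_highly_significant(self):
        # GP1 with H19, GP2 with H24 in every individual
        res = fk.fisher_association(np.array([[20, 0, 0], [0, 15, 2], [1, 0, 12]]),
                                    n_mc=2000, seed=3)
        assert res.p < 0.001

    def test_independent_margins_p_uniform(self, rng):
        ps = []
        for rep in range(150):
            a = rng.integers(0, 3, 40)
            b = rng.integers(0, 3, 40)
            table = np.zeros((3, 3), dtype=int)
            np.add.at(table, (a, b), 1)
            try:
                ps.append(fk.fisher_association(table, n_mc=199, seed=rep).p)
            except ValueError:
                continue
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            fk.fisher_association(np.array([[5, 5], [0, 0]]))


class TestMantel:
    def _sim_matrix(self, labels):
        lab = np.asarray(labels)
        return (lab[:, None] == lab[None, :]).astype(float)

    def test_identical_matrices_give_r_one(self, rng):
        m = self._sim_matrix(rng.integers(0, 3, 20))
        ctrl = rng.random((20, 20))
        ctrl = (ctrl + ctrl.T) / 2
        np.fill_diagonal(ctrl, 0)
        res = fk.partial_mantel(m, m, ctrl, n_perm=99, seed=1)
        assert res.statistic == pytest.approx(1.0, abs=1e-9)

    def test_constant_control_equals_simple_mantel(self, rng):
        a = self._sim_matrix(rng.integers(0, 2, 15))
        b = self._sim_matrix(rng.integers(0, 2, 15))
        ctrl = np.ones((15, 15))
        np.fill_diagonal(ctrl, 0)
        r1 = fk.partial_mantel(a, b, ctrl * 0 + 5 - 5 * np.eye(15), n_perm=99, seed=2)
        r2 = fk.mantel(a, b, n_perm=99, seed=2)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.p == r2.p

    def test_independent_matrices_p_uniform(self, rng):
        ps = []
        for rep in range(150):
            a = self._sim_matrix(rng.integers(0, 2, 15))
            b = self._sim_matrix(rng.integers(0, 2, 15))
            c = rng.random((15, 15))
            c = (c + c.T) / 2
            np.fill_diagonal(c, 0)
            try:
                ps.append(fk.partial_mantel(a, b, c, n_perm=99, seed=rep).p)
            except ValueError:
                continue
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_spatial_control_attenuates_cline_driven_association(self, rng):
        # haplotype and pool labels coupled only through a shared cline:
        # the simple Mantel fires, the partial Mantel is attenuated
        n = 40
        x = np.sort(rng.random(n)) * 1000
        hap = (x + rng.normal(0, 150, n)) > 500
        pool = (x + rng.normal(0, 150, n)) > 500
        a = self._sim_matrix(hap.astype(int))
        b = self._sim_matrix(pool.astype(int))
        dist = np.abs(x[:, None] - x[None, :])
        simple = fk.mantel(a, b, n_perm=199, seed=9)
        partial = fk.partial_mantel(a, b, dist, n_perm=199, seed=9)
        assert simple.statistic > partial.statistic
        assert simple.p <= 0.05

    def test_constant_matrix_undefined(self):
        m = np.ones((10, 10))
        with pytest.raises(ValueError):
            fk.partial_mantel(m, m, m)


class TestContinentalTtest:
    def test_published_sp_contrast(self):
        res = fk.continental_ttest(AFRICAN_SP, NEOTROPICAL_SP)
        assert res.p == pytest.approx(0.029, abs=1e-3)
        assert res.extra["df"] == 5

    def test_published_eig_contrast(self):
        res = fk.continental_ttest(AFRICAN_EIG, NEOTROPICAL_EIG)
        assert res.p == pytest.approx(0.014, abs=1e-3)

    def test_identical_groups(self):
        res = fk.continental_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fk.continental_ttest([1.0, 1.0], [1.0, 1.0])


class TestSpearmanExact:
    def test_perfect_concordance_n7(self):
        x = np.arange(7.0)
        res = fk.spearman_exact(x, x * 2 + 1)
        assert res.statistic == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 5040, rel=1e-9)

    def test_published_altitude_correlation(self):
        eig = [0.029, 0.057, 0.038, 0.073, 0.272, 0.111, 0.154]
        alt_range = [47, 42, 29, 72, 1225, 365, 444]
        res = fk.spearman_exact(eig, alt_range)
        assert res.statistic == pytest.approx(0.89, abs=5e-3)
        assert res.p == pytest.approx(31 / 5040, rel=1e-9)

    def test_matches_scipy_on_large_n(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = fk.spearman_exact(x, y)
        rho, p = stats.spearmanr(x, y, alternative="greater")
        assert res.statistic == pytest.approx(rho, abs=1e-12)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            fk.spearman_exact([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_category_relabelling_invariance_of_fisher(self, rng):
        table = np.array([[12, 3, 1], [2, 9, 4]])
        r1 = fk.fisher_association(table, n_mc=999, seed=4)
        r2 = fk.fisher_association(table[::-1, ::-1], n_mc=999, seed=4)
        assert r1.p == pytest.approx(r2.p, abs=0.05)
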