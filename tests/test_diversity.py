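"""Diversity, inbreeding, null-allele and clonality statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats

import finekin as fk
from finekin.diversity import _rarefy
from tests.conftest import make_hwe_genotypes


def enumeration_richness(counts, g):
    """Exhaustive oracle: average number of distinct alleles over every
    possible subsample of g gene copies."""
    pool = [a for a, c in enumerate(counts) for _ in range(c)]
    vals = [len(set(sub)) for sub in itertools.combinations(pool, g)]
    return float(np.mean(vals))


class TestAllelicRichness:
    def test_monomorphic_is_one(self):
        assert _rarefy(np.array([10]), 2) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "counts,g",
        [([5, 5], 2), ([8, 1, 1], 2), ([4, 3, 2, 1], 3), ([6, 2], 5)],
    )
    def test_matches_exhaustive_enumeration(self, counts, g):
        assert _rarefy(np.array(counts), g) == pytest.approx(
            enumeration_richness(counts, g), abs=1e-12
        )

    def test_five_five_closed_form(self):
        assert _rarefy(np.array([5, 5]), 2) == pytest.approx(14 / 9, abs=1e-12)

    def test_random_instances_match_enumeration(self, rng):
        for _ in range(10):
            k = rng.integers(2, 5)
            counts = rng.integers(1, 7, size=k)
            g = int(rng.integers(2, min(5, counts.sum())))
            assert _rarefy(counts, g) == pytest.approx(
                enumeration_richness(list(counts), g), abs=1e-10
            )

    def test_standard_size_too_large_names_locus(self):
        g = fk.GenotypeMatrix(
            ["a", "b"], ["Sg99"], [[("1", "2")], [None]]
        )
        with pytest.raises(ValueError, match="Sg99"):
            fk.rarefied_allelic_richness(g, 5)


class TestHeterozygosity:
    def test_biallelic_even_frequencies(self):
        # 0.5/0.5 with 10 gene copies: 10/9 * 0.5 = 0.5556
        g = fk.GenotypeMatrix(
            [f"i{j}" for j in range(5)],
            ["L1"],
            [[("a", "b")], [("a", "b")], [("a", "b")], [("a", "a")], [("b", "b")]],
        )
        he, mean, se = fk.expected_heterozygosity(g)
        assert mean == pytest.approx(0.5556, abs=1e-4)
        assert np.isnan(se)  # single locus: jackknife undefined

    def test_monomorphic_zero(self):
        g = fk.GenotypeMatrix(["a", "b"], ["L1"], [[("1", "1")], [("1", "1")]])
        _, mean, _ = fk.expected_heterozygosity(g)
        assert mean == 0.0

    def test_haplotype_diversity_matches_published_bci_value(self):
        # 10 individuals carrying 2 haplotypes at counts 8/2 give h = 0.356
        h = fk.HaplotypeSet([f"i{j}" for j in range(10)], ["A"] * 8 + ["B"] * 2)
        assert fk.unbiased_haplotype_diversity(h) == pytest.approx(0.356, abs=5e-4)

    def test_relabelling_invariance_and_nonnegative_se(self, rng):
        g = make_hwe_genotypes(rng, 30, n_loci=4)
        _, m1, se1 = fk.expected_heterozygosity(g)
        relabel = fk.GenotypeMatrix(
            g.individual_ids,
            g.locus_ids,
            [
                [tuple(sorted(f"x{a}" for a in c)) for c in row]
                for row in g.calls
            ],
        )
        _, m2, se2 = fk.expected_heterozygosity(relabel)
        assert m1 == pytest.approx(m2, abs=1e-12)
        assert se1 >= 0


class TestFixationIndex:
    def test_total_homozygote_excess(self):
        calls = [[("A", "A")]] * 50 + [[("a", "a")]] * 50
        g = fk.GenotypeMatrix([f"i{j}" for j in range(100)], ["L1"], calls)
        r = fk.fixation_index(g, n_perm=200, seed=1)
        assert r.multilocus == pytest.approx(1.0, abs=1e-9)
        assert r.p_high <= 1 / 201 + 1e-12

    def test_hardy_weinberg_proportions_near_zero(self):
        calls = [[("A", "A")]] * 25 + [[("A", "a")]] * 50 + [[("a", "a")]] * 25
        g = fk.GenotypeMatrix([f"i{j}" for j in range(100)], ["L1"], calls)
        r = fk.fixation_index(g, n_perm=200, seed=1)
        assert abs(r.multilocus) < 0.02
        assert r.p_high > 0.05

    def test_all_monomorphic_undefined(self):
        g = fk.GenotypeMatrix(["a", "b"], ["L1"], [[("1", "1")], [("1", "1")]])
        with pytest.raises(ValueError, match="monomorphic"):
            fk.fixation_index(g, n_perm=10)

    def test_selfing_equilibrium_recovers_s_over_2_minus_s(self):
        # partial selfing at s=0.5 gives F = s/(2-s) = 1/3 at equilibrium
        vals = []
        for seed in range(10):
            cfg = fk.SimulationConfig(
                scenario="panmixia",
                width=200.0,
                height=200.0,
                cell_size=20.0,
                density=0.01,
                sigma_seed=200.0,
                sigma_pollen=200.0,
                generations=30,
                selfing=0.5,
                seed=seed,
            )
            d = fk.simulate(cfg)
            vals.append(fk.fixation_index(d.genotypes, n_perm=0).multilocus)
        assert np.mean(vals) == pytest.approx(1 / 3, abs=0.05)

    def test_p_uniform_under_hwe_null(self, rng):
        ps = []
        for rep in range(100):
            g = make_hwe_genotypes(rng, 30, n_loci=2)
            try:
                ps.append(fk.fixation_index(g, n_perm=99, seed=rep).p_high)
            except ValueError:
                pass
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestNullAlleles:
    def test_no_deficit_gives_zero_and_identity(self):
        # heterozygote excess: nulls cannot explain anything, r = 0
        calls = [[("A", "a")]] * 60 + [[("A", "A")]] * 20 + [[("a", "a")]] * 20
        g = fk.GenotypeMatrix([f"i{j}" for j in range(100)], ["L1"], calls)
        fis = fk.fixation_index(g, n_perm=0).multilocus
        res = fk.null_allele_correction(g)
        assert res.null_freq["L1"] == 0.0
        assert res.fis_star == pytest.approx(fis, abs=1e-12)

    def test_masking_recovery_within_band(self):
        errs = []
        for seed in range(10):
            cfg = fk.SimulationConfig(
                scenario="panmixia",
                width=200.0,
                height=200.0,
                cell_size=20.0,
                density=0.01,
                sigma_seed=200.0,
                sigma_pollen=200.0,
                generations=3,
                null_rates=(0.2,),
                n_loci=3,
                seed=seed,
            )
            d = fk.simulate(cfg)
            res = fk.null_allele_correction(d.genotypes)
            errs.append(res.null_freq["L1"] - d.truth["realized_null_freq"][0])
        assert abs(np.mean(errs)) < 0.05

    def test_wahlund_signal_not_absorbed(self, rng):
        # two merged demes, no nulls: F_IS* stays clearly positive
        f1 = [rng.dirichlet(np.ones(4) * 0.3) for _ in range(4)]
        f2 = [rng.dirichlet(np.ones(4) * 0.3) for _ in range(4)]
        g1 = make_hwe_genotypes(rng, 40, n_loci=4, freqs=f1)
        g2 = make_hwe_genotypes(rng, 40, n_loci=4, freqs=f2)
        merged = fk.GenotypeMatrix(
            [f"a{j}" for j in range(40)] + [f"b{j}" for j in range(40)],
            g1.locus_ids,
            g1.calls + g2.calls,
        )
        fis = fk.fixation_index(merged, n_perm=0).multilocus
        res = fk.null_allele_correction(merged, n_sim=200, seed=3)
        assert fis > 0.05
        # the estimator absorbs part of the deficit, but the corrected
        # index stays positive and significant (no blanks back the nulls)
        assert res.fis_star > 0
        assert res.p_high < 0.05


class TestClonality:
    def test_monomorphic_probabilities_are_one(self):
        g = fk.GenotypeMatrix(
            ["a", "b", "c"], ["L1"], [[("1", "1")]] * 3
        )
        res = fk.clonality(g)
        assert res.genets[0]["p_gen"] == pytest.approx(1.0)
        assert res.genets[0]["psex"] == pytest.approx(1.0)

    def test_psex_matches_binomial_tail_oracle(self):
        # duplicated genotype heterozygous at 5 loci, all freqs 0.1:
        # P_gen = (2 * 0.1 * 0.1)^5; psex = sum_{i>=1} C(N-1,i) p^i (1-p)^(N-1-i)
        from finekin.diversity import _p_gen
        from scipy.special import comb

        geno = tuple(("1", "2") for _ in range(5))
        freqs = [{"1": 0.1, "2": 0.1, "3": 0.8} for _ in range(5)]
        pg = _p_gen(geno, freqs)
        assert pg == pytest.approx((2 * 0.01) ** 5, rel=1e-12)
        N = 85
        oracle = sum(
            comb(N - 1, i) * pg**i * (1 - pg) ** (N - 1 - i)
            for i in range(1, N)
        )
        from scipy.stats import binom

        assert float(binom.sf(0, N - 1, pg)) == pytest.approx(oracle, rel=1e-9)

    def test_rare_duplicate_in_large_sample_flagged_clone(self, rng):
        g = make_hwe_genotypes(rng, 84, n_loci=5, n_alleles=12)
        dup = fk.GenotypeMatrix(
            g.individual_ids + ["dup"],
            g.locus_ids,
            g.calls + [list(g.calls[0])],
        )
        res = fk.clonality(dup)
        target = [x for x in res.genets if "dup" in x["ramet_ids"]][0]
        assert target["psex"] < 1e-4 and target["is_clone"]

    def test_psex_monotone_in_sample_size_and_genotype_probability(self):
        from scipy.stats import binom

        pg = 1e-4
        vals = [float(binom.sf(0, N - 1, pg)) for N in (10, 50, 200)]
        # more chances to draw the genotype: psex grows with N at fixed P_gen
        assert vals == sorted(vals)
        # and shrinks as the genotype gets rarer at fixed N
        rare = [float(binom.sf(0, 99, p)) for p in (1e-2, 1e-4, 1e-6)]
        assert rare == sorted(rare, reverse=True)

    def test_missing_locus_excluded_with_record(self):
        g = fk.GenotypeMatrix(
            ["a", "b", "c"],
            ["L1", "L2"],
            [[("1", "2"), None], [("1", "2"), ("3", "3")], [("1", "2"), ("3", "3")]],
        )
        res = fk.clonality(g)
        assert res.excluded == ["a"]
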