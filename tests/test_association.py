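"""Association-stage checks: burden statistic, ACAT, testing ladder,
permutation calibration, clumping, chi-square heuristic."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from txtwas.association import (
    acat,
    align_alleles,
    burden_test,
    effective_n_heuristic,
    impute_and_test_individual,
    ld_clump,
    permutation_test,
    shaffer_confirm,
    stepwise_test,
)
from txtwas.containers import GwasSummary, LDMatrix
from txtwas.simulate import SimConfig, TraitConfig, simulate_locus, simulate_trait


def _gwas(snps, z, a1=None, a2=None, n=1000):
    k = len(snps)
    return GwasSummary(
        table=pd.DataFrame(
            {
                "snp": snps,
                "a1": a1 or ["A"] * k,
                "a2": a2 or ["G"] * k,
                "z": z,
                "n": n,
            }
        )
    )


class TestAlignAlleles:
    MODEL = pd.DataFrame(
        {"snp": ["rs1", "rs2", "rs3"], "a1": ["A", "C", "A"], "a2": ["G", "T", "T"]}
    )

    def test_identical_alleles_unchanged(self):
        gwas = _gwas(["rs1", "rs2", "rs3"], [1.0, 2.0, 3.0],
                     a1=["A", "C", "A"], a2=["G", "T", "T"])
        z, mask = align_alleles(self.MODEL, gwas, keep_ambiguous=True)
        np.testing.assert_array_equal(z, [1.0, 2.0, 3.0])
        assert mask.all()

    def test_swapped_alleles_flip_sign(self):
        gwas = _gwas(["rs1", "rs2"], [1.0, 2.0], a1=["G", "T"], a2=["A", "C"])
        z, mask = align_alleles(self.MODEL.iloc[:2], gwas)
        np.testing.assert_array_equal(z, [-1.0, -2.0])

    def test_ambiguous_snp_policy(self):
        gwas = _gwas(["rs1", "rs3"], [1.0, 3.0], a1=["A", "A"], a2=["G", "T"])
        z, mask = align_alleles(self.MODEL, gwas)  # default drops A/T
        np.testing.assert_array_equal(z, [1.0])
        z2, mask2 = align_alleles(self.MODEL, gwas, keep_ambiguous=True)
        np.testing.assert_array_equal(z2, [1.0, 3.0])

    def test_no_overlap_raises(self):
        gwas = _gwas(["rsX"], [1.0])
        with pytest.raises(ValueError, match="overlap"):
            align_alleles(self.MODEL, gwas)


class TestBurden:
    def test_single_snp_passthrough(self):
        Z, p = burden_test(np.array([1.0]), np.array([3.0]), np.array([[1.0]]))
        assert Z == pytest.approx(3.0)
        assert p == pytest.approx(2 * stats.norm.sf(3.0))

    def test_cancellation(self):
        Z, _ = burden_test(np.array([1.0, 1.0]), np.array([1.0, -1.0]), np.eye(2))
        assert Z == pytest.approx(0.0)

    def test_hand_arithmetic_with_ld(self):
        w = np.array([0.5, 0.5])
        V = np.array([[1.0, 0.5], [0.5, 1.0]])
        z = np.array([2.0, 2.0])
        Z, _ = burden_test(w, z, V)
        assert Z == pytest.approx(2.0 / math.sqrt(0.75))

    def test_zero_weights_flagged(self):
        Z, p = burden_test(np.zeros(3), np.ones(3), np.eye(3))
        assert np.isnan(Z) and np.isnan(p)

    def test_agrees_with_individual_level_regression(self):
        """Summary-level burden Z equals the individual-level regression z
        when V is the in-sample LD of the GWAS panel (tolerance O(1/n))."""
        cfg = SimConfig(n_train=200, p_snps=40, m_isoforms=2, p_causal=0.1,
                        h_g2=0.3, seed=31)
        locus = simulate_locus(cfg)
        tcfg = TraitConfig(scenario="one_isoform", h_t2=0.1, seed=1)
        n_g = 3000
        y, gwas, Xg = simulate_trait(locus, tcfg, n_gwas=n_g, return_panel=True)
        V = Xg.T @ Xg / n_g
        rng = np.random.default_rng(0)
        w = rng.standard_normal(40)
        z_ind, _ = impute_and_test_individual(Xg, w, y)
        Z_sum, _ = burden_test(w, gwas.z, V)
        assert Z_sum == pytest.approx(z_ind, abs=30.0 / n_g * abs(z_ind) + 0.05)

    def test_perfect_phenotype_saturates(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((500, 5))
        w = np.array([1.0, 0, 0, 0, 0])
        y = X @ w
        z, p = impute_and_test_individual(X, w, y)
        assert abs(z) > 100
        assert p <= 1e-300


class TestAcat:
    @pytest.mark.parametrize("p0", [1e-6, 0.01, 0.5, 0.99])
    def test_fixed_point(self, p0):
        assert acat([p0, p0, p0]) == pytest.approx(p0, rel=1e-10)

    def test_two_value_numeric_oracle(self):
        expected = 0.5 - math.atan(math.tan(0.49 * math.pi) / 2.0) / math.pi
        assert acat([0.01, 0.5]) == pytest.approx(expected, rel=1e-12)

    def test_small_p_linearization(self):
        p = [1e-12, 0.3, 0.6]
        # one dominant tiny p: combined within 2x of t * p_min
        assert acat(p) == pytest.approx(3 * 1e-12, rel=1.0)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            acat([])
        with pytest.raises(ValueError):
            acat([0.0, 0.5])
        with pytest.raises(ValueError):
            acat([1.5])

    def test_weights(self):
        assert acat([0.01, 0.5], weights=[1.0, 0.0]) == pytest.approx(0.01, rel=1e-10)


class TestShaffer:
    def test_single_isoform(self):
        assert shaffer_confirm([0.04], alpha=0.05).tolist() == [True]

    def test_two_isoforms_both_at_full_alpha(self):
        # screening guarantees one false null, so both thresholds are alpha/1
        assert shaffer_confirm([0.04, 0.049], alpha=0.05).tolist() == [True, True]

    def test_three_isoforms_sequential_stop(self):
        # thresholds 0.025, 0.025, 0.05; 0.03 > 0.025 stops the sequence
        assert shaffer_confirm([0.01, 0.03, 0.04], alpha=0.05).tolist() == [
            True, False, False,
        ]

    def test_input_order_preserved(self):
        rej = shaffer_confirm([0.03, 0.01, 0.04], alpha=0.05)
        assert rej.tolist() == [False, True, False]


class TestStepwise:
    def test_single_gene_single_isoform_reduces_to_bh(self):
        df = pd.DataFrame({"gene": ["g1"], "isoform": ["i1"], "p": [0.01]})
        genes, isos = stepwise_test(df, alpha=0.05)
        assert genes.loc[0, "acat_p"] == pytest.approx(0.01)
        assert bool(genes.loc[0, "screened"])
        assert bool(isos.loc[0, "stage2_reject"])

    def test_bh_keeps_first_two_of_three(self):
        # BH at alpha 0.05 on acat p {0.001, 0.02, 0.9}: adjusted
        # {0.003, 0.03, 0.9} -> first two screened
        df = pd.DataFrame(
            {
                "gene": ["g1", "g2", "g3"],
                "isoform": ["i1", "i2", "i3"],
                "p": [0.001, 0.02, 0.9],
            }
        )
        genes, _ = stepwise_test(df, alpha=0.05)
        screened = genes.sort_values("gene")["screened"].tolist()
        assert screened == [True, True, False]

    def test_failed_screening_gates_isoforms(self):
        df = pd.DataFrame(
            {
                "gene": ["g1", "g1"],
                "isoform": ["i1", "i2"],
                "p": [0.4, 0.001],
            }
        )
        # the good isoform is diluted; force non-screening with bonferroni
        # over many null genes
        null = pd.DataFrame(
            {
                "gene": [f"n{i}" for i in range(20)],
                "isoform": ["ix"] * 20,
                "p": np.linspace(0.3, 0.95, 20),
            }
        )
        genes, isos = stepwise_test(pd.concat([df, null], ignore_index=True))
        g1 = genes.set_index("gene").loc["g1"]
        if not g1["screened"]:
            assert not isos.loc[isos["gene"] == "g1", "stage2_reject"].any()

    def test_bonferroni_more_conservative_than_bh(self):
        df = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(10)],
                "isoform": ["i"] * 10,
                "p": np.linspace(0.004, 0.05, 10),
            }
        )
        bh_genes, _ = stepwise_test(df, adjust="bh")
        bf_genes, _ = stepwise_test(df, adjust="bonferroni")
        assert bf_genes["screened"].sum() <= bh_genes["screened"].sum()


class TestPermutation:
    def test_single_snp_degenerate(self):
        p = permutation_test(np.array([1.0]), np.array([2.0]), np.array([[1.0]]))
        assert p == 1.0

    def test_zero_statistic_has_p_near_one(self):
        rng = np.random.default_rng(2)
        w = rng.standard_normal(10)
        z = np.zeros(10)
        p = permutation_test(w, z, np.eye(10), n_perm=200, seed=0)
        assert p == 1.0

    def test_never_returns_zero(self):
        w = np.zeros(5)
        w[0] = 1.0
        z = np.array([50.0, 0, 0, 0, 0])
        p = permutation_test(w, z, np.eye(5), n_perm=100, seed=0)
        assert p >= 1.0 / 101

    def test_uniform_under_exchangeable_null(self):
        """With i.i.d. z, V=I and random w the permutation p-value is
        approximately uniform (KS check at reduced n_perm)."""
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(120):
            w = rng.standard_normal(12)
            z = rng.standard_normal(12)
            pvals.append(permutation_test(w, z, np.eye(12), n_perm=150,
                                          seed=int(rng.integers(2**31))))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestClump:
    def test_no_significant_snp(self):
        snps = [f"rs{i}" for i in range(4)]
        gwas = _gwas(snps, [1.0, 2.0, 1.5, 0.5])
        ld = LDMatrix(snp_ids=snps, V=np.eye(4))
        assert ld_clump(gwas, ld) == []

    def test_correlated_pair_yields_one_lead(self):
        snps = ["rs1", "rs2"]
        V = np.array([[1.0, math.sqrt(0.5)], [math.sqrt(0.5), 1.0]])
        gwas = _gwas(snps, [6.0, 5.9])
        leads = ld_clump(gwas, LDMatrix(snp_ids=snps, V=V), r2=0.2)
        assert leads == ["rs1"]

    def test_matches_bruteforce_oracle_on_hand_example(self):
        snps = [f"rs{i}" for i in range(5)]
        z = np.array([6.0, 6.5, 5.8, 7.0, 1.0])
        r = np.array(
            [
                [1.0, 0.6, 0.1, 0.0, 0.0],
                [0.6, 1.0, 0.1, 0.0, 0.0],
                [0.1, 0.1, 1.0, 0.7, 0.0],
                [0.0, 0.0, 0.7, 1.0, 0.0],
                [0.0, 0.0, 0.0, 0.0, 1.0],
            ]
        )
        gwas = _gwas(snps, z)
        ld = LDMatrix(snp_ids=snps, V=r)

        # brute-force greedy oracle
        p = 2 * stats.norm.sf(np.abs(z))
        avail = (p < 5e-8).tolist()
        expected = []
        while any(avail):
            best = min((i for i in range(5) if avail[i]), key=lambda i: p[i])
            expected.append(snps[best])
            for j in range(5):
                if avail[j] and r[best, j] ** 2 >= 0.2:
                    avail[j] = False
        assert ld_clump(gwas, ld, r2=0.2) == expected


class TestEffectiveN:
    def test_identical_vectors_zero_percent(self):
        p = np.array([0.01, 0.001, 0.2])
        assert effective_n_heuristic(p, p) == pytest.approx(0.0)

    def test_doubled_chisq_is_hundred_percent(self):
        pb = np.array([0.05])
        chi_b = stats.chi2.isf(0.05, 1)
        pa = np.array([stats.chi2.sf(2 * chi_b, 1)])
        assert effective_n_heuristic(pa, pb) == pytest.approx(100.0)

    def test_matches_direct_recomputation(self, rng):
        pa = rng.uniform(1e-6, 1, 50)
        pb = rng.uniform(1e-6, 1, 50)
        chi_a = stats.chi2.isf(pa, 1)
        chi_b = stats.chi2.isf(pb, 1)
        m = chi_b > 1
        expected = np.mean(100 * (chi_a[m] - chi_b[m]) / chi_b[m])
        assert effective_n_heuristic(pa, pb) == pytest.approx(expected)

    def test_no_qualifying_pairs_is_nan(self):
        p_all_weak = np.array([0.9, 0.95])
        assert np.isnan(effective_n_heuristic(p_all_weak, p_all_weak))
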