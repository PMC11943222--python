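"""Unit and property tests for the NB differential-expression machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ncrip.de import (CountMatrix, DEThresholds, NormalizationError,
                      bh_adjust, estimate_dispersion, fpkm, nb_wald_test,
                      size_factors)

from conftest import make_counts


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = make_counts(np.array([[10, 10], [20, 20]]),
                         np.array([[10, 10], [20, 20]]))
        assert np.allclose(size_factors(cm), 1.0)

    def test_hand_computed_median_of_ratios(self):
        # genes (10,20),(20,40),(30,60): all ratios to the geometric-mean
        # reference are 1/sqrt(2) and sqrt(2)
        df = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]},
                          index=["a", "b", "c"])
        f = size_factors(df)
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)])

    def test_scaling_law(self, rng):
        base = rng.poisson(100, size=(50, 1))
        df = pd.DataFrame(np.hstack([base, 2 * base]), columns=["i", "j"])
        f = size_factors(df)
        assert f["j"] / f["i"] == pytest.approx(2.0)

    def test_gene_order_invariance(self, rng):
        arr = rng.poisson(50, size=(30, 4)) + 1
        df = pd.DataFrame(arr, columns=list("abcd"))
        perm = rng.permutation(30)
        assert np.allclose(size_factors(df), size_factors(df.iloc[perm]))

    def test_no_all_positive_gene_raises(self):
        df = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(NormalizationError):
            size_factors(df)


class TestDispersion:
    def test_constant_counts_hit_floor(self):
        cm = make_counts(np.full((3, 3), 7), np.full((3, 3), 9))
        f = pd.Series(1.0, index=cm.counts.columns)
        assert np.allclose(estimate_dispersion(cm, f), 1e-8)

    def test_poisson_estimates_near_zero(self, rng):
        wt = rng.poisson(1000, size=(10_000, 3))
        mut = rng.poisson(1000, size=(10_000, 3))
        cm = make_counts(wt, mut)
        f = pd.Series(1.0, index=cm.counts.columns)
        assert np.median(estimate_dispersion(cm, f)) < 0.01

    def test_nb_dispersion_recovered_in_band(self, rng):
        alpha, mu = 0.1, 500.0
        r = 1 / alpha
        wt = rng.negative_binomial(r, r / (r + mu), size=(5000, 3))
        mut = rng.negative_binomial(r, r / (r + mu), size=(5000, 3))
        cm = make_counts(wt, mut)
        f = pd.Series(1.0, index=cm.counts.columns)
        med = np.median(estimate_dispersion(cm, f))
        assert 0.05 <= med <= 0.2


class TestBH:
    def test_stepup_collapse(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_empty(self):
        assert bh_adjust([]).size == 0

    @staticmethod
    def brute_force(p):
        m = len(p)
        order = np.argsort(p)
        out = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            out[i] = running
        return out

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_matches_brute_force_stepup(self, pvals):
        assert np.allclose(bh_adjust(pvals), self.brute_force(pvals))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_padj_dominates_p(self, pvals):
        adj = bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        assert (adj <= 1 + 1e-12).all()


class TestWald:
    def test_duplicated_matrix_gives_exact_zero_lfc(self, rng):
        block = rng.poisson(100, size=(200, 3))
        res = nb_wald_test(make_counts(block, block))
        assert (res.table["log2FC"] == 0).all()
        assert (res.calls == "ns").all()

    def test_strain_swap_negates_lfc_keeps_p(self, rng):
        wt = rng.poisson(100, size=(300, 3))
        mut = rng.poisson(160, size=(300, 3))
        a = nb_wald_test(make_counts(wt, mut))
        b = nb_wald_test(make_counts(mut, wt))
        assert np.allclose(a.table["log2FC"], -b.table["log2FC"])
        assert np.allclose(a.table["pvalue"].dropna(), b.table["pvalue"].dropna())

    def test_all_zero_gene_excluded(self):
        wt = np.array([[0, 0, 0], [10, 12, 9]])
        mut = np.array([[0, 0, 0], [11, 10, 13]])
        res = nb_wald_test(make_counts(wt, mut))
        assert np.isnan(res.table.loc["g0", "pvalue"])
        assert res.table.loc["g0", "call"] == "ns"
        assert np.isfinite(res.table.loc["g1", "pvalue"])

    def test_single_replicate_rejected(self):
        cm = make_counts(np.array([[5], [6]]), np.array([[7, 8], [9, 10]]))
        with pytest.raises(ValueError, match="replicates"):
            nb_wald_test(cm)

    def test_power_on_planted_fourfold_change(self, rng):
        # planted log2FC = +2 among a null background, n = 3 per strain
        G, k = 4000, 200
        mu = 2.0 ** rng.uniform(3, 10, G)
        fold = np.ones(G)
        fold[:k] = 4.0
        r = 1 / 0.05
        wt = rng.negative_binomial(r, r / (r + mu[:, None]), size=(G, 3))
        mut = rng.negative_binomial(r, r / (r + (mu * fold)[:, None]), size=(G, 3))
        res = nb_wald_test(make_counts(wt, mut))
        frac_up = (res.calls.iloc[:k] == "up").mean()
        assert frac_up >= 0.9

    def test_agrees_with_two_proportion_z_oracle(self, rng):
        # Poisson counts, dispersion pinned to the floor: the Wald p should
        # track a classical two-proportion z-test on pooled library totals
        from scipy import stats
        G, n = 500, 4
        mu = np.full(G, 2000.0)
        wt = rng.poisson(mu[:, None] * np.ones(n))
        mut = rng.poisson(mu[:, None] * np.ones(n) * 1.05)
        cm = make_counts(wt, mut)
        f = pd.Series(1.0, index=cm.counts.columns)
        disp = pd.Series(1e-8, index=cm.gene_ids)
        res = nb_wald_test(cm, factors=f, dispersion=disp,
                           moderate_dispersion=False)
        x1, x2 = wt.sum(1), mut.sum(1)
        t1 = t2 = n * mu * 10  # large pseudo-totals; rates are small
        p1, p2 = x1 / t1, x2 / t2
        pp = (x1 + x2) / (t1 + t2)
        z = (p2 - p1) / np.sqrt(pp * (1 - pp) * (1 / t1 + 1 / t2))
        p_oracle = 2 * stats.norm.sf(np.abs(z))
        diff = np.abs(res.table["pvalue"].to_numpy() - p_oracle)
        assert np.mean(diff) < 0.02


class TestFPKM:
    def test_definition(self):
        cm = make_counts(np.array([[100]]), np.array([[100]]),
                         lengths=[500])
        # column total 100, so FPKM = 100*1e9/(500*100) = 2e6; rescale via a
        # constructed big column instead:
        big = make_counts(np.array([[100], [999_900]]),
                          np.array([[100], [999_900]]),
                          lengths=[500, 1000])
        vals = fpkm(big)
        assert vals.iloc[0, 0] == pytest.approx(100 * 1e9 / (500 * 1e6))

    def test_sparsity(self):
        cm = make_counts(np.array([[50], [0], [0]]), np.array([[50], [0], [0]]),
                         lengths=[100, 100, 100])
        vals = fpkm(cm)
        assert (vals.iloc[1:] == 0).all().all()
        assert (vals.iloc[0] > 0).all()

    def test_zero_column_total_raises(self):
        cm = make_counts(np.array([[0]]), np.array([[5]]), lengths=[100])
        with pytest.raises(ValueError, match="zero column total"):
            fpkm(cm)


def test_thresholds_validation():
    with pytest.raises(ValueError):
        DEThresholds(fdr=0.0)
    with pytest.raises(ValueError):
        DEThresholds(lfc_min=-1)


def test_count_matrix_rejects_negative_and_duplicates():
    with pytest.raises(ValueError):
        make_counts(np.array([[-1]]), np.array([[1]]))
    with pytest.raises(ValueError, match="duplicate"):
        make_counts(np.array([[1], [2]]), np.array([[1], [2]]),
                    gene_ids=["a", "a"])
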