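"""Rank-product machinery: exact tails, bound envelopes, mu/MAD, q-values."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scgxe.rankprod import (SubtypeDelta, geometric_mean_p, mu_mad, qvalues,
                            rank_product, rank_product_test, rank_within_library,
                            rp_continuous_bounds, rp_exact, rp_pvalue_bounds,
                            subtype_deltas)


def brute_tail(rp, n, k):
    count = sum(1 for t in itertools.product(range(1, n + 1), repeat=k)
                if math.prod(t) <= rp)
    return count / n ** k


class TestExactTail:
    @pytest.mark.parametrize("rp,n,k,expected", [
        (1, 2, 2, 1 / 4), (2, 2, 2, 3 / 4), (4, 2, 2, 1.0),
        (3, 10, 1, 0.3), (7.5, 10, 1, 0.7),
    ])
    def test_small_cases(self, rp, n, k, expected):
        assert rp_exact(rp, n, k) == pytest.approx(expected, abs=1e-15)

    @given(st.integers(2, 9), st.integers(1, 4), st.floats(0.5, 1.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_enumeration(self, n, k, frac):
        rp = 1 + frac * (n ** k - 1)
        assert rp_exact(rp, n, k) == pytest.approx(brute_tail(rp, n, k), abs=1e-12)

    def test_budget_refusal(self):
        with pytest.raises(ValueError):
            rp_exact(1e18, 10 ** 6, 6, op_budget=1e6)


class TestBounds:
    def test_k1_exact_both_sides(self):
        lo, hi = rp_pvalue_bounds(3, 10, 1)
        assert lo == hi == 0.3

    def test_enumerable_lattice_is_exact(self):
        lo, hi = rp_pvalue_bounds(2, 2, 2)
        assert lo == hi == 0.75

    @given(st.integers(2, 60), st.integers(2, 4), st.floats(0.0, 1.0))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_continuous_envelopes_bracket_exact(self, n, k, frac):
        rp = 1 + frac * (min(n ** k, 10 ** 6) - 1)
        exact = rp_exact(rp, n, k)
        lo, hi = rp_continuous_bounds(rp, n, k)
        assert lo <= exact + 1e-12
        assert exact <= hi + 1e-12

    def test_monotone_in_rp(self):
        for n, k in [(50, 3), (2000, 10)]:
            rps = np.geomspace(1, float(n) ** k, 60)
            ps = [geometric_mean_p(*rp_pvalue_bounds(r, n, k)) for r in rps]
            assert np.all(np.diff(ps) >= -1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            rp_pvalue_bounds(0.5, 10, 2)
        with pytest.raises(ValueError):
            rp_pvalue_bounds(101, 10, 2)

    def test_non_integer_rp_from_ties(self):
        # bounds evaluated at a tied (half-integer) rank product stay valid
        lo, hi = rp_pvalue_bounds(2.5, 2, 2)
        assert lo == hi == rp_exact(2.5, 2, 2) == 0.75


class TestGeometricMean:
    @pytest.mark.parametrize("lo,hi,expected", [
        (0.04, 0.04, 0.04), (0.01, 0.04, 0.02), (1.0, 1.0, 1.0),
    ])
    def test_values(self, lo, hi, expected):
        assert geometric_mean_p(lo, hi) == pytest.approx(expected)

    def test_zero_lower_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            assert geometric_mean_p(0.0, 0.3) == 0.3


class TestMuMad:
    def _delta(self, d):
        d = np.asarray(d, dtype=float)[None, None, :]
        return SubtypeDelta(d=d, genes=["g0"], libraries=["lib0"],
                            subtypes=[f"s{i}" for i in range(d.shape[2])],
                            contrast=("t", ("a", "b")),
                            n_cells=np.full((1, d.shape[2], 2), 10),
                            mask=np.ones((1, d.shape[2]), dtype=bool))

    @pytest.mark.parametrize("d,mu,mad", [
        ((2, 2, 2), 2.0, 0.0),
        ((0, 0, 6), 2.0, 8 / 3),
        ((-1, 1), 0.0, 1.0),
    ])
    def test_formulas(self, d, mu, mad):
        stat = mu_mad(self._delta(d))
        assert stat.mu[0, 0] == pytest.approx(mu)
        assert stat.mad[0, 0] == pytest.approx(mad)


class TestRanks:
    def test_directions_and_ties(self):
        stat = np.array([[3.0], [1.0], [2.0]])
        assert rank_within_library(stat, "up").ravel().tolist() == [1, 3, 2]
        assert rank_within_library(stat, "down").ravel().tolist() == [3, 1, 2]
        tied = np.array([[5.0], [5.0], [1.0]])
        assert rank_within_library(tied, "up").ravel().tolist() == [1.5, 1.5, 3]

    def test_masked_get_least_extreme_rank(self):
        stat = np.array([[3.0], [np.nan], [2.0]])
        assert rank_within_library(stat, "up").ravel().tolist() == [1, 3, 2]
        assert rank_within_library(stat, "down").ravel().tolist() == [2, 3, 1]

    def test_direction_duality_untied(self, rng):
        stat = rng.normal(size=(50, 4))
        up = rank_within_library(stat, "up")
        down = rank_within_library(stat, "down")
        assert np.allclose(up + down, 50 + 1)

    def test_rank_product(self):
        assert rank_product(np.array([[2.0, 3.0]]))[0] == pytest.approx(6.0)
        assert rank_product(np.array([[4.0]]))[0] == pytest.approx(4.0)
        assert rank_product(np.ones((1, 5)))[0] == pytest.approx(1.0)


class TestSubtypeDeltas:
    def _toy(self, shift):
        rng = np.random.default_rng(0)
        cells = []
        meta = []
        values = []
        for lib in range(3):
            for sub in ("sA", "sB"):
                for level in ("WT", "KO"):
                    for i in range(5):
                        cid = f"l{lib}{sub}{level}{i}"
                        cells.append(cid)
                        meta.append({"cell_id": cid, "chip": lib, "state": sub,
                                     "genotype": level})
                        base = 5.0 + (shift if (level == "KO" and sub == "sB") else 0.0)
                        values.append(base)
        expr = pd.DataFrame({"g0": values}, index=cells).T
        meta = pd.DataFrame(meta).set_index("cell_id")
        return expr, meta

    def test_identical_levels_give_zero(self):
        expr, meta = self._toy(0.0)
        delta = subtype_deltas(expr, meta, ("genotype", ("WT", "KO")), "state", min_cells=3)
        assert np.allclose(delta.d, 0.0)

    def test_mean_shift_recovered_exactly_without_noise(self):
        expr, meta = self._toy(2.0)
        delta = subtype_deltas(expr, meta, ("genotype", ("WT", "KO")), "state", min_cells=3)
        assert np.allclose(delta.d[0, :, 0], 0.0)   # subtype sA
        assert np.allclose(delta.d[0, :, 1], 2.0)   # subtype sB

    def test_simulated_effect_within_3se(self, rng):
        # one library, 200 cells per group, effect 1.5 in subtype 2 only
        n = 200
        sd = 1.0
        rows, meta = [], []
        vals = {}
        for sub, eff in (("s1", 0.0), ("s2", 1.5)):
            for level in ("WT", "KO"):
                for i in range(n):
                    cid = f"{sub}{level}{i}"
                    meta.append({"cell_id": cid, "chip": 0, "state": sub,
                                 "genotype": level})
                    vals[cid] = rng.normal(5.0 + (eff if level == "KO" else 0.0), sd)
        expr = pd.DataFrame(vals, index=["g0"])
        meta = pd.DataFrame(meta).set_index("cell_id")
        delta = subtype_deltas(expr, meta, ("genotype", ("WT", "KO")), "state")
        se = sd * math.sqrt(2 / n)
        assert abs(delta.d[0, 0, 0] - 0.0) < 3 * se
        assert abs(delta.d[0, 0, 1] - 1.5) < 3 * se

    def test_low_cell_entries_masked_and_absent_level_excluded(self):
        expr, meta = self._toy(0.0)
        meta2 = meta.copy()
        # library 2 loses all KO cells -> excluded with warning
        drop = meta2.index[(meta2["chip"] == 2) & (meta2["genotype"] == "KO")]
        keep = expr.columns.difference(drop)
        with pytest.warns(UserWarning, match="lacks contrast level"):
            delta = subtype_deltas(expr[keep], meta2.loc[keep],
                                   ("genotype", ("WT", "KO")), "state", min_cells=3)
        assert delta.libraries == [0, 1]


class TestQvalues:
    def test_all_ones(self):
        with pytest.warns(UserWarning):
            assert np.all(qvalues(np.ones(50)) == 1.0)

    def test_bh_oracle_when_pi0_is_one(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(3)
        p = rng.uniform(1e-4, 1, size=80)   # < 100 -> pi0 = 1 (BH)
        with pytest.warns(UserWarning):
            q = qvalues(p)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh)

    def test_uniform_null_rarely_significant(self):
        hits = []
        for seed in range(20):
            p = np.random.default_rng(seed).uniform(size=10_000)
            p = np.clip(p, 1e-12, 1.0)
            hits.append((qvalues(p) <= 0.05).mean())
        assert max(hits) <= 0.01

    def test_rejects_bad_pvalues(self):
        with pytest.raises(ValueError):
            qvalues([0.5, 0.0])


class TestEndToEnd:
    def test_masked_gene_reported_least_significant(self, rng):
        # a gene expressed in too few cells everywhere ranks at the bottom
        genes, libs = 30, 4
        stat = rng.normal(size=(genes, libs))
        stat[5] = np.nan
        ranks = rank_within_library(stat, "up")
        assert np.all(ranks[5] == genes)

    def test_rank_product_test_shapes(self, small_tpm, small_sim):
        frame = np.log2(small_tpm.to_frame() + 1.0)
        meta = small_sim.metadata.assign(state=small_sim.truth.true_state)
        res = rank_product_test(frame, meta, ("genotype", ("WT", "KO")),
                                subtype_col="env")
        n = len(small_tpm.gene_ids)
        assert len(res.summary) == 2 * n
        assert set(res.summary["test"]) == {"mu", "mad"}
        assert res.table["p_lower"].le(res.table["p"] + 1e-12).all()
        assert res.table["p"].le(res.table["p_upper"] + 1e-12).all()
        assert res.summary["p_two_sided"].between(0, 1).all()
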