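"""Partial correlation, rank index, TES and the lncRNA screen."""
import math

import numpy as np
import pandas as pd
import pytest

from lncpath import (SyntheticConfig, generate_cohort, partial_correlation,
                     partial_correlation_pvalue, rank_index, screen_lncrnas)
from lncpath.containers import ExpressionMatrix
from lncpath.screen import (pair_association_matrices, total_enrichment_score)


def residual_partial_corr(x, y, z):
    """Oracle: Pearson correlation of OLS residuals after regressing out z."""
    z1 = np.column_stack([np.ones_like(z), z])
    rx = x - z1 @ np.linalg.lstsq(z1, x, rcond=None)[0]
    ry = y - z1 @ np.linalg.lstsq(z1, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


class TestPartialCorrelation:
    def test_orthogonal_purity_collapses_to_pearson(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        z = rng.normal(size=50)
        z1 = np.column_stack([np.ones(50), x, y])
        z = z - z1 @ np.linalg.lstsq(z1, z, rcond=None)[0]  # exactly uncorrelated
        a = partial_correlation(x, y, z)
        assert a.pcc == pytest.approx(a.r_lnc_m, abs=1e-12)

    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=30)
        z = rng.normal(size=30)
        z1 = np.column_stack([np.ones(30), x])
        z = z - z1 @ np.linalg.lstsq(z1, z, rcond=None)[0]
        assert partial_correlation(x, x.copy(), z).pcc == pytest.approx(1.0, abs=1e-12)

    def test_residual_regression_identity_on_fixed_vectors(self):
        lnc = np.array([1.0, 2, 3, 4, 5])
        m = np.array([2.0, 1, 4, 3, 5])
        p = np.array([0.9, 0.8, 0.7, 0.9, 0.6])
        a = partial_correlation(lnc, m, p)
        assert a.pcc == pytest.approx(residual_partial_corr(lnc, m, p), abs=1e-12)

    def test_residual_regression_identity_randomized(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 40))
            x, y, z = rng.normal(size=(3, n))
            a = partial_correlation(x, y, z)
            assert a.pcc == pytest.approx(residual_partial_corr(x, y, z), abs=1e-10)

    def test_symmetry_in_roles(self, rng):
        x, y, z = rng.normal(size=(3, 25))
        assert partial_correlation(x, y, z).pcc == pytest.approx(
            partial_correlation(y, x, z).pcc, abs=1e-14)

    def test_degenerate_inputs(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError):
            partial_correlation(x, np.ones(10), rng.normal(size=10))
        with pytest.raises(ValueError):
            partial_correlation(x[:3], x[:3] * 2, x[:3])


class TestPvalueAndRankIndex:
    def test_zero_pcc_gives_p_one(self):
        a = partial_correlation(np.r_[1.0, 2, 3, 4, 2], np.r_[2.0, 1, 3, 1, 4],
                                np.r_[0.5, 0.6, 0.4, 0.7, 0.5])
        a = a.__class__(**{**a.__dict__, "pcc": 0.0})
        assert partial_correlation_pvalue(a).p_value == pytest.approx(1.0)

    def test_formula_against_erfc_oracle(self):
        a = partial_correlation(np.arange(5.0), np.r_[2.0, 1, 4, 3, 5],
                                np.r_[0.9, 0.8, 0.7, 0.9, 0.6])
        a = a.__class__(**{**a.__dict__, "pcc": 0.3, "n": 100})
        z = 0.3 * math.sqrt(97 / (1 - 0.09))
        expect = math.erfc(z / math.sqrt(2))  # 2 * Phi(-z)
        assert partial_correlation_pvalue(a).p_value == pytest.approx(expect, abs=1e-10)

    def test_p_decreases_with_n(self):
        a = partial_correlation(np.arange(5.0), np.r_[2.0, 1, 4, 3, 5],
                                np.r_[0.9, 0.8, 0.7, 0.9, 0.6])
        prev = 1.0
        for n in (10, 20, 40, 80):
            b = a.__class__(**{**a.__dict__, "pcc": 0.5, "n": n})
            p = partial_correlation_pvalue(b).p_value
            assert p < prev
            prev = p

    def test_rank_index_boundaries_and_antisymmetry(self):
        base = partial_correlation(np.arange(5.0), np.r_[2.0, 1, 4, 3, 5],
                                   np.r_[0.9, 0.8, 0.7, 0.9, 0.6])
        mk = lambda pcc, p: base.__class__(**{**base.__dict__, "pcc": pcc, "p_value": p})
        assert rank_index(mk(0.5, 1.0)).ri == 0.0
        assert rank_index(mk(-0.5, 1.0)).ri == 0.0
        assert rank_index(mk(0.4, 0.01)).ri == pytest.approx(-math.log(0.01))
        assert rank_index(mk(0.3, 0.2)).ri == pytest.approx(-rank_index(mk(-0.3, 0.2)).ri)
        assert rank_index(mk(-0.9, 0.0)).ri == -745.0  # underflow cap


class TestMatrixPass:
    def test_matches_scalar_operations(self, rng):
        lnc = pd.DataFrame(rng.normal(size=(4, 30)),
                           index=[f"L{i}" for i in range(4)])
        mrna = pd.DataFrame(rng.normal(size=(6, 30)),
                            index=[f"M{i}" for i in range(6)])
        purity = pd.Series(rng.uniform(0.3, 1.0, 30))
        pcc, pval, ri = pair_association_matrices(lnc, mrna, purity)
        for l in lnc.index:
            for m in mrna.index:
                a = partial_correlation(lnc.loc[l], mrna.loc[m], purity)
                a = rank_index(partial_correlation_pvalue(a))
                assert pcc.loc[l, m] == pytest.approx(a.pcc, abs=1e-10)
                assert pval.loc[l, m] == pytest.approx(a.p_value, abs=1e-10)
                assert ri.loc[l, m] == pytest.approx(a.ri, abs=1e-8)


class TestScreen:
    def test_tes_identity_and_sorting(self, small_cohort):
        res = screen_lncrnas(small_cohort.expression, small_cohort.purity,
                             small_cohort.truth.pathway_genes, n_perm=200, seed=0)
        assert np.allclose(res["tes"],
                           total_enrichment_score(res["p_adj"], res["es"]))
        assert res["tes"].abs().is_monotonic_decreasing
        assert ((res["tes"] >= -1) & (res["tes"] <= 1)).all()
        # candidacy gate is exactly the stated conjunction
        expect = (res["tes"].abs() > 0.95) & (res["p_adj"] < 0.05)
        assert (res["is_candidate"] == expect).all()

    def test_gate_monotonicity(self, small_cohort):
        strict = screen_lncrnas(small_cohort.expression, small_cohort.purity,
                                small_cohort.truth.pathway_genes, n_perm=200, seed=0)
        loose = screen_lncrnas(small_cohort.expression, small_cohort.purity,
                               small_cohort.truth.pathway_genes, n_perm=200, seed=0,
                               tes_threshold=0.5, fdr_threshold=0.25)
        assert set(strict.loc[strict.is_candidate, "lnc_id"]) <= \
            set(loose.loc[loose.is_candidate, "lnc_id"])

    def test_constant_lncrna_skipped(self, small_cohort, caplog):
        values = small_cohort.expression.values.copy()
        values.loc["LNC_000"] = 1.0
        expr = ExpressionMatrix(values, small_cohort.expression.partition)
        with caplog.at_level("WARNING"):
            res = screen_lncrnas(expr, small_cohort.purity,
                                 small_cohort.truth.pathway_genes, n_perm=200, seed=0)
        assert "LNC_000" not in set(res["lnc_id"])
        assert len(res) == small_cohort.expression.lncrna.shape[0] - 1

    def test_degenerate_target_sets_rejected(self, small_cohort):
        expr, purity = small_cohort.expression, small_cohort.purity
        with pytest.raises(ValueError):
            screen_lncrnas(expr, purity, [], n_perm=200)
        with pytest.raises(ValueError):
            screen_lncrnas(expr, purity, list(expr.mrna.index), n_perm=200)
        with pytest.raises(ValueError):
            screen_lncrnas(expr, purity, ["NOT_A_GENE"], n_perm=200)

    def test_constant_purity_degrades_to_unadjusted(self, small_cohort, caplog):
        flat = pd.Series(0.5, index=small_cohort.expression.sample_ids)
        with caplog.at_level("WARNING"):
            a = screen_lncrnas(small_cohort.expression, flat,
                               small_cohort.truth.pathway_genes, n_perm=200, seed=0)
        b = screen_lncrnas(small_cohort.expression, None,
                           small_cohort.truth.pathway_genes, n_perm=200, seed=0)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_lncrnas_recovered(self):
        # full-size cohort: the desk-scale fixture is underpowered for the
        # 1 - 2*P_adj > 0.95 gate at modest permutation counts
        c = generate_cohort(SyntheticConfig(seed=0, effect_r=0.6))
        res = screen_lncrnas(c.expression, c.purity, c.truth.pathway_genes,
                             n_perm=1000, seed=3)
        cand = set(res.loc[res.is_candidate, "lnc_id"])
        assert set(c.truth.active_lncrnas) <= cand
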