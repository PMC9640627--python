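"""Risk model and Kaplan-Meier utilities against hand-tabulated oracles."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from lncpath import RiskModel, SyntheticConfig, fit_risk_model, generate_cohort, survival_curves
from lncpath.risk import score_samples


def km_by_hand(time, event):
    """Product-limit estimate via the standard tabulation (oracle)."""
    out = {}
    s = 1.0
    for t in sorted(set(time)):
        d = sum(1 for ti, ei in zip(time, event) if ti == t and ei == 1)
        n = sum(1 for ti in time if ti >= t)
        s *= 1 - d / n
        out[t] = s
    return out


def logrank_by_hand(time, event, group):
    """Two-group log-rank via the O - E / V tabulation (oracle)."""
    o_minus_e, v = 0.0, 0.0
    for t in sorted({ti for ti, ei in zip(time, event) if ei == 1}):
        at1 = sum(1 for ti, g in zip(time, group) if ti >= t and g == 1)
        at = sum(1 for ti in time if ti >= t)
        d = sum(1 for ti, ei in zip(time, event) if ti == t and ei == 1)
        d1 = sum(1 for ti, ei, g in zip(time, event, group) if ti == t and ei == 1 and g == 1)
        o_minus_e += d1 - d * at1 / at
        if at > 1:
            v += d * (at1 / at) * (1 - at1 / at) * (at - d) / (at - 1)
    stat = o_minus_e**2 / v
    return stat, float(chi2.sf(stat, 1))


class TestSurvivalCurves:
    def test_eight_sample_oracle(self):
        surv = pd.DataFrame({
            "time": [1.0, 2.0, 3.0, 5.0, 1.5, 2.5, 4.0, 6.0],
            "event": [1, 1, 0, 1, 1, 1, 1, 0],
        }, index=[f"s{i}" for i in range(8)])
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=surv.index)
        curves, stat, p = survival_curves(surv, labels)
        for g in ("a", "b"):
            sub = surv[labels == g]
            expect = km_by_hand(sub["time"].tolist(), sub["event"].tolist())
            got = dict(zip(curves[g]["time"], curves[g]["survival"]))
            for t, s in expect.items():
                assert got[t] == pytest.approx(s, abs=1e-12)
        grp = (labels == "a").astype(int).tolist()
        stat_o, p_o = logrank_by_hand(surv["time"].tolist(), surv["event"].tolist(), grp)
        assert stat == pytest.approx(stat_o, abs=1e-8)
        assert p == pytest.approx(p_o, abs=1e-8)

    def test_first_step_without_censoring(self):
        surv = pd.DataFrame({"time": [3.0, 1.0, 4.0, 2.0, 5.0, 6.0],
                             "event": 1}, index=[f"s{i}" for i in range(6)])
        curves, _, _ = survival_curves(surv, pd.Series("g", index=surv.index))
        tbl = curves["g"].set_index("time")
        assert tbl.loc[1.0, "survival"] == pytest.approx(5 / 6)
        assert (np.diff(curves["g"]["survival"]) <= 0).all()
        # no censoring: KM equals the empirical survival function
        assert tbl.loc[6.0, "survival"] == pytest.approx(0.0)

    def test_identical_groups_give_null_test(self):
        times = [1.0, 2.0, 3.0, 4.0]
        surv = pd.DataFrame({"time": times * 2, "event": 1},
                            index=[f"s{i}" for i in range(8)])
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=surv.index)
        _, stat, p = survival_curves(surv, labels)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self, rng):
        surv = pd.DataFrame({"time": rng.exponential(5, 30) + 0.1,
                             "event": rng.integers(0, 2, 30)},
                            index=[f"s{i}" for i in range(30)])
        surv.loc[surv.index[:3], "event"] = 1
        labels = pd.Series(["x"] * 15 + ["y"] * 15, index=surv.index)
        _, s1, p1 = survival_curves(surv, labels)
        _, s2, p2 = survival_curves(surv, labels.map({"x": "y", "y": "x"}))
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_single_group_and_small_groups(self, rng):
        surv = pd.DataFrame({"time": rng.exponential(5, 10) + 0.1, "event": 1},
                            index=[f"s{i}" for i in range(10)])
        curves, stat, p = survival_curves(surv, pd.Series("g", index=surv.index))
        assert stat is None and p is None and "g" in curves
        bad = pd.Series(["a"] * 8 + ["b"] * 2, index=surv.index)
        with pytest.raises(ValueError):
            survival_curves(surv, bad)


class TestRiskModel:
    def test_single_driver_recovery(self):
        c = generate_cohort(SyntheticConfig(seed=11, n_active_lnc=1, effect_r=0.8,
                                            hazard_beta=1.0, subtype_shift=0.0))
        driver = c.truth.active_lncrnas[0]
        keys = [driver] + [l for l in c.expression.lncrna.index if l != driver][:4]
        m = fit_risk_model(c.expression.values.loc[keys], c.survival)
        assert m.beta[driver] > 0
        assert m.logrank_p < 0.05
        # high-risk group has more events per unit follow-up
        ev = c.survival.join(m.groups).groupby("group")["event"].mean()
        assert ev["high"] > ev["low"]

    def test_median_split_balance_and_tie_rule(self, rng):
        c = generate_cohort(SyntheticConfig(seed=2, n_samples=101, n_mrna=60,
                                            n_lncrna=10, pathway_set_size=20))
        keys = list(c.expression.lncrna.index[:3])
        m = fit_risk_model(c.expression.values.loc[keys], c.survival)
        counts = m.groups.value_counts()
        assert abs(counts.get("high", 0) - counts.get("low", 0)) <= 1
        at_cut = m.risk_scores == m.cut
        assert (m.groups[at_cut] == "low").all()

    def test_fixed_beta_shift_invariance(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 40)), index=list("abc"),
                            columns=[f"s{i}" for i in range(40)])
        beta = pd.Series({"a": 0.5, "b": -1.0, "c": 0.2})
        base = score_samples(beta, expr)
        shifted = expr.copy()
        shifted.loc["b"] += 7.0
        moved = score_samples(beta, shifted)
        assert np.allclose(moved - base, -7.0)
        assert ((base > base.median()) == (moved > moved.median())).all()

    def test_zero_beta_model_is_degenerate(self, rng):
        expr = pd.DataFrame(rng.normal(size=(2, 30)), index=["a", "b"],
                            columns=[f"s{i}" for i in range(30)])
        model = RiskModel.from_dict({"lnc_ids": ["a", "b"],
                                     "beta": {"a": 0.0, "b": 0.0},
                                     "cut": 0.0}, expr)
        assert (model.risk_scores == 0).all()
        assert (model.groups == "low").all()
        assert model.logrank_p is None  # no survival test without a real split

    def test_collinear_design_rejected(self, rng):
        c = generate_cohort(SyntheticConfig(seed=4, n_samples=60, n_mrna=60,
                                            n_lncrna=10, pathway_set_size=20))
        values = c.expression.values.copy()
        values.loc["LNC_001"] = 2.0 * values.loc["LNC_000"]
        with pytest.raises(ValueError, match="collinear"):
            fit_risk_model(values.loc[["LNC_000", "LNC_001"]], c.survival)

    def test_univariate_mode_matches_individual_fits(self):
        c = generate_cohort(SyntheticConfig(seed=6, n_samples=80, n_mrna=60,
                                            n_lncrna=6, pathway_set_size=20))
        keys = list(c.expression.lncrna.index[:2])
        m = fit_risk_model(c.expression.values.loc[keys], c.survival, mode="univariate")
        from lncpath import fit_univariate_cox
        import math
        for lnc in keys:
            est = fit_univariate_cox(c.expression.values.loc[lnc], c.survival)
            assert m.beta[lnc] == pytest.approx(est.log2_hr * math.log(2), rel=1e-6)

    def test_model_roundtrip(self, tmp_path):
        c = generate_cohort(SyntheticConfig(seed=8, n_samples=60, n_mrna=60,
                                            n_lncrna=8, pathway_set_size=20))
        keys = list(c.expression.lncrna.index[:3])
        m = fit_risk_model(c.expression.values.loc[keys], c.survival)
        applied = RiskModel.from_dict(m.to_dict(), c.expression.values)
        pd.testing.assert_series_equal(applied.risk_scores, m.risk_scores)
        assert (applied.groups == m.groups).all()
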