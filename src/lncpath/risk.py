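"""lncRNA risk score: Cox coefficients, median split, survival comparison.

The risk score of a sample is ``sum_i beta_i * EXP_i`` over the key lncRNAs,
with ``beta_i`` from a Cox proportional-hazards fit (joint fit in
multivariate mode, per-lncRNA fits in univariate mode). Samples are split
into high/low-risk groups at the median score (ties go to the low-risk
group) and compared with a log-rank test. Kaplan-Meier utilities for
arbitrary group labels live here as well.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test

from .containers import ExpressionMatrix, check_survival

logger = logging.getLogger(__name__)


@dataclass
class RiskModel:
    """Fitted lncRNA risk model and the induced sample stratification."""

    lnc_ids: list[str]
    beta: pd.Series                 # per-lncRNA Cox coefficient
    risk_scores: pd.Series          # per-sample sum(beta_i * expression_i)
    cut: float                      # median risk score
    groups: pd.Series               # "high" (> cut) / "low" (<= cut)
    logrank_stat: float | None      # None when the split is degenerate
    logrank_p: float | None
    degenerate: bool = False
    flagged: bool = False           # convergence warning during the Cox fit
    mode: str = "multivariate"

    def to_dict(self) -> dict:
        return {
            "lnc_ids": list(self.lnc_ids),
            "beta": {k: float(v) for k, v in self.beta.items()},
            "cut": float(self.cut),
            "mode": self.mode,
        }

    @classmethod
    def from_dict(cls, d: dict, expr: ExpressionMatrix | pd.DataFrame) -> "RiskModel":
        """Apply a saved model (coefficients + cut) to new expression data."""
        beta = pd.Series(d["beta"], dtype=float)
        values = expr.values if isinstance(expr, ExpressionMatrix) else expr
        scores = score_samples(beta, values)
        groups = _median_groups(scores, float(d["cut"]))
        return cls(lnc_ids=list(d["lnc_ids"]), beta=beta, risk_scores=scores,
                   cut=float(d["cut"]), groups=groups, logrank_stat=None,
                   logrank_p=None, mode=d.get("mode", "multivariate"))


def score_samples(beta: pd.Series, values: pd.DataFrame) -> pd.Series:
    """Risk score per sample: linear combination of lncRNA expression rows."""
    missing = set(beta.index) - set(values.index)
    if missing:
        raise ValueError(f"expression lacks model lncRNAs: {sorted(missing)[:5]}")
    X = values.loc[beta.index]
    return X.mul(beta, axis=0).sum(axis=0).rename("risk_score")


def _median_groups(scores: pd.Series, cut: float) -> pd.Series:
    return pd.Series(np.where(scores > cut, "high", "low"),
                     index=scores.index, name="group")


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(float)
    A = A - A.mean(axis=0)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name the features involved via near-zero R diagonal of a pivoted QR
        _, r = np.linalg.qr(A)
        diag = np.abs(np.diag(r))
        tol = max(A.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
        bad = [X.columns[i] for i in range(len(diag)) if diag[i] <= tol]
        raise ValueError(f"collinear lncRNA expression (rank {rank} < {A.shape[1]}); "
                         f"implicated features: {bad or list(X.columns)}")


def fit_risk_model(expr: ExpressionMatrix | pd.DataFrame, surv: pd.DataFrame,
                   mode: str = "multivariate") -> RiskModel:
    """Fit the risk model on the key-lncRNA expression rows of *expr*.

    Requires >= 20 samples and >= 10 events; multivariate mode additionally
    requires full column rank of the key-lncRNA design. An all-zero score
    vector (degenerate median split) is flagged and returned without a
    log-rank test.
    """
    if mode not in ("multivariate", "univariate"):
        raise ValueError("mode must be 'multivariate' or 'univariate'")
    values = expr.lncrna if isinstance(expr, ExpressionMatrix) else expr
    surv = check_survival(surv)
    common = values.columns.intersection(surv.index)
    if len(common) < 20:
        raise ValueError("need at least 20 aligned samples")
    surv = surv.loc[common]
    if int(surv["event"].sum()) < 10:
        raise ValueError("need at least 10 events")
    X = values[common].T  # samples x lncRNAs
    lnc_ids = list(X.columns)

    flagged = False
    if mode == "multivariate":
        _check_rank(X)
        df = pd.concat([X, surv], axis=1)
        cph = CoxPHFitter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            cph.fit(df, duration_col="time", event_col="event")
            flagged = any(issubclass(w.category, ConvergenceWarning) for w in caught)
        beta = cph.params_.reindex(lnc_ids).astype(float)
    else:
        coefs = {}
        for lnc in lnc_ids:
            df = pd.DataFrame({"time": surv["time"], "event": surv["event"], "x": X[lnc]})
            cph = CoxPHFitter()
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                cph.fit(df, duration_col="time", event_col="event")
                flagged |= any(issubclass(w.category, ConvergenceWarning) for w in caught)
            coefs[lnc] = float(cph.params_["x"])
        beta = pd.Series(coefs).reindex(lnc_ids)
    if flagged:
        logger.warning("risk-model Cox fit raised a convergence warning")

    scores = score_samples(beta, values[common])
    cut = float(scores.median())
    groups = _median_groups(scores, cut)
    if scores.nunique() == 1:
        logger.warning("degenerate risk scores (all equal); no survival test run")
        return RiskModel(lnc_ids=lnc_ids, beta=beta, risk_scores=scores, cut=cut,
                         groups=groups, logrank_stat=None, logrank_p=None,
                         degenerate=True, flagged=flagged, mode=mode)
    res = multivariate_logrank_test(surv["time"], groups, surv["event"])
    return RiskModel(lnc_ids=lnc_ids, beta=beta, risk_scores=scores, cut=cut,
                     groups=groups, logrank_stat=float(res.test_statistic),
                     logrank_p=float(res.p_value), flagged=flagged, mode=mode)


def survival_curves(surv: pd.DataFrame, labels: pd.Series):
    """Kaplan-Meier estimate per group plus a k-group log-rank test.

    Returns ``(curves, stat, p)`` where *curves* maps each group label to a
    DataFrame with columns ``time, survival, at_risk, censored`` (one row
    per observed time). With a single group the test is skipped
    (``stat = p = None``); groups with fewer than 3 samples are rejected.
    """
    surv = check_survival(surv)
    labels = pd.Series(labels).reindex(surv.index)
    if labels.isna().any():
        raise ValueError("labels must cover every survival sample")
    counts = labels.value_counts()
    if (counts < 3).any():
        raise ValueError(f"groups with fewer than 3 samples: "
                         f"{sorted(counts.index[counts < 3].tolist())}")
    curves = {}
    for g in sorted(counts.index):
        sub = surv[labels == g]
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"])
        tbl = km.event_table.iloc[1:] if 0 in km.event_table.index and \
            (km.event_table.loc[0, ["observed", "censored"]] == 0).all() else km.event_table
        curves[g] = pd.DataFrame({
            "time": tbl.index.to_numpy(float),
            "survival": km.survival_function_at_times(tbl.index).to_numpy(float),
            "at_risk": tbl["at_risk"].to_numpy(int),
            "censored": tbl["censored"].to_numpy(int),
        }).reset_index(drop=True)
    if len(counts) < 2:
        return curves, None, None
    res = multivariate_logrank_test(surv["time"], labels, surv["event"])
    return curves, float(res.test_statistic), float(res.p_value)


def plot_survival_curves(curves: dict, path) -> None:
    """Write a simple KM step plot (PNG) for the given curve tables."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, tbl in curves.items():
        ax.step(np.r_[0, tbl["time"]], np.r_[1.0, tbl["survival"]],
                where="post", label=str(g))
        cens = tbl[tbl["censored"] > 0]
        ax.plot(cens["time"], cens["survival"], "|", color=ax.lines[-1].get_color())
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
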