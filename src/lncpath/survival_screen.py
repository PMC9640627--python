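"""Univariate Cox screening of pathway scores against overall survival.

Each pathway's per-sample score is fit as the single covariate of a Cox
proportional-hazards model; the coefficient is reported on the base-2 log
scale (log2 HR per unit score), so log2(HR) > 0 marks a risk factor and
log2(HR) < 0 a protective factor.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceWarning

from .containers import check_survival

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)


@dataclass(frozen=True)
class HazardEstimate:
    """Single-covariate Cox fit summary (base-2 log hazard ratio)."""

    feature_id: str
    log2_hr: float
    p_value: float
    n_events: int
    flagged: bool = False  # convergence / separation warning raised during the fit


def fit_univariate_cox(scores: pd.Series, surv: pd.DataFrame) -> HazardEstimate:
    """Fit a one-covariate Cox PH model of *scores* on overall survival.

    Requires >= 10 samples with >= 3 events and a non-constant covariate.
    Monotone-likelihood (separation-like) fits are returned with
    ``flagged=True`` rather than discarded.
    """
    surv = check_survival(surv)
    common = scores.index.intersection(surv.index)
    if len(common) < 10:
        raise ValueError("need at least 10 aligned samples")
    df = pd.DataFrame({
        "time": surv.loc[common, "time"],
        "event": surv.loc[common, "event"],
        "x": scores.loc[common].astype(float),
    })
    if int(df["event"].sum()) < 3:
        raise ValueError("need at least 3 events")
    if df["x"].std() == 0:
        raise ValueError(f"covariate {scores.name!r} has zero variance")

    cph = CoxPHFitter()
    flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        cph.fit(df, duration_col="time", event_col="event")
        flagged = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if flagged:
        logger.warning("covariate %r: Cox fit raised a convergence warning "
                       "(possible monotone likelihood)", scores.name)
    beta = float(cph.params_["x"])
    p = float(cph.summary.loc["x", "p"])
    return HazardEstimate(feature_id=str(scores.name), log2_hr=beta / LN2,
                          p_value=p, n_events=int(df["event"].sum()), flagged=flagged)


def screen_pathways(scores: pd.DataFrame, surv: pd.DataFrame,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Univariate Cox screen of every pathway score row.

    Returns one row per successfully fitted pathway with columns
    ``pathway, log2_hr, p_value, n_events, significant, direction, flagged``;
    per-pathway failures (e.g. constant scores) are logged and excluded.
    """
    rows = []
    for pathway in scores.index:
        try:
            est = fit_univariate_cox(scores.loc[pathway], surv)
        except Exception as exc:  # lifelines raises assorted error types
            logger.warning("pathway %r excluded from the screen: %s", pathway, exc)
            continue
        rows.append({
            "pathway": pathway,
            "log2_hr": est.log2_hr,
            "p_value": est.p_value,
            "n_events": est.n_events,
            "significant": est.p_value < alpha,
            "direction": "risk" if est.log2_hr > 0 else "protective",
            "flagged": est.flagged,
        })
    return pd.DataFrame(rows, columns=["pathway", "log2_hr", "p_value", "n_events",
                                       "significant", "direction", "flagged"])


def intersect_significant(*screens: pd.DataFrame) -> list[str]:
    """Pathways significant in every cohort screen (the multi-cohort intersection)."""
    sets = [set(s.loc[s["significant"], "pathway"]) for s in screens]
    return sorted(set.intersection(*sets)) if sets else []
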