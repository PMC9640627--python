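"""Purity-adjusted lncRNA-pathway association screen.

For every lncRNA the screen (i) computes a first-order partial correlation
with each mRNA, controlling for tumor purity,

    PCC = (R_lm - R_lp * R_mp) / (sqrt(1 - R_lp^2) * sqrt(1 - R_mp^2)),

(ii) converts it to a normal-approximation p-value
``P = 2 * Phi(-|PCC * sqrt((n-3)/(1-PCC^2))|)``, (iii) builds the signed
rank index ``RI = -ln(P) * sign(PCC)``, (iv) ranks all mRNAs by descending
RI and asks, via a weighted-KS preranked enrichment test with gene-label
permutations, whether a target gene set concentrates at either extreme, and
(v) condenses direction and significance into the total enrichment score

    TES = (1 - 2 * P_adj) * sign(ES),   TES in [-1, 1],

where ``P_adj`` is the Benjamini-Hochberg-adjusted permutation p-value
(one family = all lncRNAs of one screen). Candidates must pass
``|TES| > tes_threshold`` and ``P_adj < fdr_threshold``.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, check_purity
from .scoring import _running_sum_es

logger = logging.getLogger(__name__)

#: cap on |RI| when the p-value underflows to 0 (-ln of the smallest double)
DEFAULT_LN_CAP = 745.0


@dataclass(frozen=True)
class PairAssociation:
    """Association record for one (lncRNA, mRNA) pair."""

    lnc_id: str
    mrna_id: str
    r_lnc_m: float
    r_lnc_p: float
    r_m_p: float
    n: int
    pcc: float | None = None
    p_value: float | None = None
    ri: float | None = None


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant vector: Pearson correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def partial_correlation(lnc, m, purity, lnc_id: str = "lnc", mrna_id: str = "mRNA") -> PairAssociation:
    """First-order partial correlation of *lnc* and *m* given *purity*."""
    lnc = np.asarray(lnc, float)
    m = np.asarray(m, float)
    purity = np.asarray(purity, float)
    n = lnc.size
    if not (m.size == n == purity.size):
        raise ValueError("vectors must be aligned")
    if n < 4:
        raise ValueError("need at least 4 samples")
    r_lm = _pearson(lnc, m)
    r_lp = _pearson(lnc, purity)
    r_mp = _pearson(m, purity)
    if abs(r_lp) >= 1 or abs(r_mp) >= 1:
        raise ValueError("purity collinear with expression: denominator undefined")
    pcc = (r_lm - r_lp * r_mp) / (math.sqrt(1 - r_lp**2) * math.sqrt(1 - r_mp**2))
    pcc = float(np.clip(pcc, -1.0, 1.0))
    return PairAssociation(lnc_id=lnc_id, mrna_id=mrna_id, r_lnc_m=r_lm,
                           r_lnc_p=r_lp, r_m_p=r_mp, n=n, pcc=pcc)


def _pcc_pvalue(pcc: np.ndarray, n: int) -> np.ndarray:
    """Two-sided normal-approximation p-value of a partial correlation."""
    pcc = np.asarray(pcc, float)
    with np.errstate(divide="ignore"):
        z = np.abs(pcc) * np.sqrt((n - 3) / np.maximum(1 - pcc**2, 0.0))
    p = 2.0 * ndtr(-z)
    return np.where(np.abs(pcc) >= 1.0, 0.0, p)


def partial_correlation_pvalue(assoc: PairAssociation) -> PairAssociation:
    """Fill ``p_value`` from ``pcc`` (|pcc| = 1 yields the p = 0 limit, flagged)."""
    if assoc.pcc is None:
        raise ValueError("pcc not computed")
    if assoc.n <= 3:
        raise ValueError("need n > 3 for the p-value")
    if abs(assoc.pcc) >= 1:
        logger.warning("pair (%s, %s): |pcc| = 1, p-value set to 0 limit",
                       assoc.lnc_id, assoc.mrna_id)
        return replace(assoc, p_value=0.0)
    return replace(assoc, p_value=float(_pcc_pvalue(assoc.pcc, assoc.n)))


def total_enrichment_score(p_adj, es):
    """TES = (1 - 2 * P) * sign(ES): direction and significance in one score in [-1, 1]."""
    return (1.0 - 2.0 * np.asarray(p_adj, float)) * np.sign(es)


def rank_index(assoc: PairAssociation, ln_cap: float = DEFAULT_LN_CAP) -> PairAssociation:
    """Fill ``ri = -ln(p) * sign(pcc)``; underflowed p capped at ``+-ln_cap``."""
    if assoc.p_value is None:
        raise ValueError("p_value not computed")
    if assoc.p_value == 0:
        logger.warning("pair (%s, %s): p-value underflow, RI capped at %g",
                       assoc.lnc_id, assoc.mrna_id, ln_cap)
        ri = ln_cap * np.sign(assoc.pcc)
    else:
        ri = -math.log(assoc.p_value) * np.sign(assoc.pcc)
    return replace(assoc, ri=float(ri))


# -- vectorized all-pairs pass --------------------------------------------

def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant rows cannot be standardized")
    return (X - mu) / sd


def pair_association_matrices(lnc: pd.DataFrame, mrna: pd.DataFrame,
                              purity: pd.Series | None,
                              ln_cap: float = DEFAULT_LN_CAP):
    """All-pairs PCC / p-value / RI as (lncRNA x mRNA) DataFrames.

    One matrix pass over standardized data (O(n * L * G) arithmetic, no
    per-pair loops). ``purity=None`` (or a constant vector upstream) skips
    the adjustment: the "partial" correlation degrades to plain Pearson.
    """
    n = lnc.shape[1]
    Zl = _standardize_rows(lnc.to_numpy(float))
    Zm = _standardize_rows(mrna.to_numpy(float))
    r_lm = np.clip(Zl @ Zm.T / n, -1.0, 1.0)
    if purity is None:
        pcc = r_lm
    else:
        p = np.asarray(purity, float)
        zp = (p - p.mean()) / p.std()
        r_lp = np.clip(Zl @ zp / n, -1.0, 1.0)
        r_mp = np.clip(Zm @ zp / n, -1.0, 1.0)
        if np.any(np.abs(r_lp) >= 1) or np.any(np.abs(r_mp) >= 1):
            raise ValueError("purity collinear with an expression row")
        pcc = (r_lm - np.outer(r_lp, r_mp)) / np.outer(
            np.sqrt(1 - r_lp**2), np.sqrt(1 - r_mp**2))
        pcc = np.clip(pcc, -1.0, 1.0)
    pval = _pcc_pvalue(pcc, n)
    with np.errstate(divide="ignore"):
        ri = np.where(pval > 0, -np.log(np.maximum(pval, 1e-320)), ln_cap)
    ri = np.minimum(ri, ln_cap) * np.sign(pcc)
    idx, cols = lnc.index, mrna.index
    return (pd.DataFrame(pcc, index=idx, columns=cols),
            pd.DataFrame(pval, index=idx, columns=cols),
            pd.DataFrame(ri, index=idx, columns=cols))


def pair_association_table(lnc: pd.DataFrame, mrna: pd.DataFrame,
                           purity: pd.Series | None) -> pd.DataFrame:
    """Long-format pair table (one row per lncRNA-mRNA pair); large output."""
    pcc, pval, ri = pair_association_matrices(lnc, mrna, purity)
    out = pd.concat({"pcc": pcc.stack(), "p_value": pval.stack(), "ri": ri.stack()}, axis=1)
    out.index.names = ["lnc_id", "mrna_id"]
    return out.reset_index()


# -- the screen ------------------------------------------------------------

def screen_lncrnas(expr: ExpressionMatrix, purity: pd.Series | None, target_set,
                   n_perm: int = 1000, weight_exp: float = 1.0,
                   tes_threshold: float = 0.95, fdr_threshold: float = 0.05,
                   seed=None, ln_cap: float = DEFAULT_LN_CAP) -> pd.DataFrame:
    """Screen every lncRNA for association with *target_set*.

    Returns a DataFrame with one row per lncRNA — columns ``lnc_id, es,
    p_raw, p_adj, tes, is_candidate`` — sorted by |tes| descending then
    lnc_id. Constant lncRNAs are skipped with a warning; a constant purity
    vector disables the adjustment (with a warning) rather than failing.
    """
    target_set = list(dict.fromkeys(target_set))
    mrna = expr.mrna
    if len(target_set) == 0:
        raise ValueError("target gene set is empty")
    unknown = set(target_set) - set(mrna.index)
    if unknown:
        raise ValueError(f"target set genes outside the mRNA partition: {sorted(unknown)[:5]}")
    if len(target_set) >= mrna.shape[0]:
        raise ValueError("target set must be a proper subset of the mRNA partition")

    if purity is not None:
        purity = check_purity(pd.Series(purity), expr.sample_ids)
        if purity.std() == 0:
            logger.warning("purity vector is constant; screening without adjustment")
            purity = None

    lnc = expr.lncrna
    keep = lnc.std(axis=1) > 0
    for skipped in lnc.index[~keep]:
        logger.warning("skipping constant lncRNA %s", skipped)
    lnc = lnc.loc[keep]
    mkeep = mrna.std(axis=1) > 0
    mrna = mrna.loc[mkeep]
    if set(target_set) - set(mrna.index):
        raise ValueError("target set contains constant mRNAs")

    _, _, ri = pair_association_matrices(lnc, mrna, purity, ln_cap=ln_cap)
    member = mrna.index.isin(set(target_set))
    s, G = int(member.sum()), mrna.shape[0]

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(lnc.index))
    rows = []
    ri_np = ri.to_numpy()
    for i, lnc_id in enumerate(lnc.index):
        order = np.argsort(-ri_np[i], kind="stable")
        w = np.abs(ri_np[i][order]) ** weight_exp
        hits = member[order]
        es = float(_running_sum_es(w, hits)[0])
        rng = np.random.default_rng(children[i])
        pick = np.argpartition(rng.random((n_perm, G)), s - 1, axis=1)[:, :s]
        null_hits = np.zeros((n_perm, G), dtype=bool)
        np.put_along_axis(null_hits, pick, True, axis=1)
        es_null = _running_sum_es(w, null_hits)
        exceed = int(np.sum(np.abs(es_null) >= abs(es)))
        rows.append((lnc_id, es, (1 + exceed) / (n_perm + 1)))

    out = pd.DataFrame(rows, columns=["lnc_id", "es", "p_raw"])
    out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    out["tes"] = total_enrichment_score(out["p_adj"], out["es"])
    out["is_candidate"] = (out["tes"].abs() > tes_threshold) & (out["p_adj"] < fdr_threshold)
    out = out.sort_values(["tes", "lnc_id"], key=lambda c: -c.abs() if c.name == "tes" else c,
                          kind="stable").reset_index(drop=True)
    return out


def intersect_candidates(*screens: pd.DataFrame) -> list[str]:
    """Candidate lncRNA ids shared by every screen result (identifier equality)."""
    sets = [set(s.loc[s["is_candidate"], "lnc_id"]) for s in screens]
    return sorted(set.intersection(*sets)) if sets else []
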