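"""Gene-set scoring: single-sample GSEA and preranked enrichment.

Two rank statistics live here:

* :func:`ssgsea_scores` — per-sample pathway activity: for each sample genes
  are ranked by expression and the score is the integrated difference
  between the weighted in-set cumulative distribution (weights = rank^tau)
  and the unweighted out-of-set cumulative distribution (Barbie-style).
* :func:`preranked_es` — weighted Kolmogorov-Smirnov enrichment score of a
  gene set on an externally ranked list (hit increments proportional to
  |stat|^weight_exp, uniform miss decrements); the ES is the running-sum
  deviation of maximal absolute value, signed. :func:`permutation_pvalue`
  attaches a gene-label permutation p-value.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentStat:
    """Enrichment score with its permutation p-value."""

    es: float
    p_raw: float
    n_perm: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.es <= 1.0 + 1e-12:
            raise ValueError("enrichment score outside [-1, 1]")
        lo = 1.0 / (self.n_perm + 1)
        if not lo - 1e-15 <= self.p_raw <= 1.0 + 1e-15:
            raise ValueError("permutation p-value outside [1/(n_perm+1), 1]")


# -- core running sum ------------------------------------------------------

def _running_sum_es(abs_weights: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """Signed max-deviation ES for one ranked list and a batch of hit masks.

    Parameters
    ----------
    abs_weights
        ``(G,)`` nonnegative weights of the ranked list (already ``|stat|^w``).
    hits
        Boolean ``(..., G)`` in-set indicator(s) aligned to the ranked list.
    """
    hits = np.atleast_2d(hits)
    G = hits.shape[-1]
    s = hits.sum(axis=-1)
    if np.any(s == 0) or np.any(s == G):
        raise ValueError("gene set must overlap the list and be a proper subset")
    hit_w = np.where(hits, abs_weights, 0.0)
    denom = hit_w.sum(axis=-1, keepdims=True)
    # all-zero hit weights (every in-set stat exactly 0): fall back to uniform
    flat = denom[:, 0] == 0
    if flat.any():
        hit_w[flat] = hits[flat] / s[flat, None]
        denom[flat] = 1.0
    # per-step increments (divide before summing: matches a sequential
    # running-sum evaluation bit for bit)
    steps = hit_w / denom - (~hits) / (G - s)[:, None]
    dev = np.cumsum(steps, axis=-1)
    max_p = dev.max(axis=-1)
    min_p = dev.min(axis=-1)
    # signed max deviation; exact ties go to the negative extreme
    return np.where(max_p > -min_p, max_p, min_p)


def preranked_es(ranked_stats: pd.Series, gene_set, weight_exp: float = 1.0) -> float:
    """ES of *gene_set* on an ordered gene list (index = gene ids, top first).

    ``ranked_stats`` must already be in ranking order; values are used only
    through ``|stat|^weight_exp`` as hit weights. Ties in the input keep
    their order (deterministic).
    """
    genes = ranked_stats.index
    if genes.has_duplicates:
        raise ValueError("duplicate gene identifiers in ranked list")
    hits = genes.isin(set(gene_set))
    w = np.abs(ranked_stats.to_numpy(float)) ** weight_exp
    return float(_running_sum_es(w, hits)[0])


def permutation_pvalue(ranked_stats: pd.Series, gene_set, weight_exp: float = 1.0,
                       n_perm: int = 1000, seed=None) -> EnrichmentStat:
    """Gene-label permutation test for :func:`preranked_es`.

    Null scores come from random same-size gene sets; the p-value compares
    magnitudes, ``p = (1 + #{|ES_null| >= |ES_obs|}) / (n_perm + 1)``, so it
    is floored at ``1/(n_perm+1)``, never zero, and uniform for a random
    set; the observed ES sign carries the direction.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = ranked_stats.index
    hits = genes.isin(set(gene_set))
    w = np.abs(ranked_stats.to_numpy(float)) ** weight_exp
    es_obs = float(_running_sum_es(w, hits)[0])
    s, G = int(hits.sum()), hits.size
    rng = np.random.default_rng(seed)
    pick = np.argpartition(rng.random((n_perm, G)), s - 1, axis=1)[:, :s]
    null_hits = np.zeros((n_perm, G), dtype=bool)
    np.put_along_axis(null_hits, pick, True, axis=1)
    es_null = _running_sum_es(w, null_hits)
    exceed = int(np.sum(np.abs(es_null) >= abs(es_obs)))
    return EnrichmentStat(es=es_obs, p_raw=(1 + exceed) / (n_perm + 1), n_perm=n_perm)


# -- ssGSEA ----------------------------------------------------------------

def ssgsea_scores(expr: ExpressionMatrix | pd.DataFrame, sets: GeneSetCollection,
                  exponent: float = 0.25, normalize: bool = False) -> pd.DataFrame:
    """Single-sample GSEA scores, one row per gene set, one column per sample.

    Per sample, genes are ranked by expression (average ranks on ties; the
    highest-expressed gene has the largest rank) and the set score is the
    sum over the descending-expression walk of the difference between the
    in-set rank^``exponent``-weighted CDF and the out-of-set ECDF. With
    ``normalize=True`` the whole matrix is min-max rescaled (cohort level).

    Sets sharing fewer than 2 genes with the matrix are skipped with a
    warning; a set covering every gene is an error (out-of-set ECDF
    undefined).
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    genes = values.index
    X = values.to_numpy(float)
    G, N = X.shape
    order = np.argsort(-X, axis=0, kind="stable")            # descending walk
    ranks = rankdata(X, axis=0)                               # ascending, ties averaged
    w = np.take_along_axis(ranks, order, axis=0) ** exponent  # weights in walk order
    cols = np.arange(N)

    rows = {}
    for name in sets:
        member = genes.isin(set(sets[name]))
        overlap = int(member.sum())
        if overlap == G:
            raise ValueError(f"gene set {name!r} covers every gene; score undefined")
        if overlap < 2:
            logger.warning("skipping gene set %r: fewer than 2 genes overlap", name)
            continue
        inset = member[order]                                 # (G, N) walk-order mask
        hit_w = np.where(inset, w, 0.0)
        p_hit = np.cumsum(hit_w, axis=0) / hit_w.sum(axis=0)[cols]
        p_miss = np.cumsum(~inset, axis=0) / (G - overlap)
        rows[name] = (p_hit - p_miss).sum(axis=0)
    scores = pd.DataFrame(rows, index=values.columns).T
    if normalize and scores.size:
        lo, hi = scores.to_numpy().min(), scores.to_numpy().max()
        if hi > lo:
            scores = (scores - lo) / (hi - lo)
    return scores
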