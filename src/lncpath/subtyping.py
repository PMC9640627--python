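"""Consensus clustering of candidate-lncRNA expression into subtypes.

Samples are repeatedly subsampled (80% without replacement by default),
clustered with seeded k-means for each k in a range, and pairwise
co-assignment frequencies are accumulated into a per-k consensus matrix
(normalized by how often each pair was co-selected). The empirical CDF of
consensus entries summarizes stability; the number of clusters is chosen by
the delta-area elbow rule (largest k whose relative gain in area under the
CDF exceeds a threshold). Final labels come from average-linkage
hierarchical clustering of the selected consensus matrix.

The base k-means (k-means++ initialization, vectorized Lloyd iterations
across restarts) is implemented in-package: the resampling loop runs tens
of thousands of fits, which an off-the-shelf estimator object would make
the bottleneck. A unit test cross-checks it against scikit-learn's KMeans.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import kruskal
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# -- small fast k-means ----------------------------------------------------

def _kmeanspp_init(X: np.ndarray, k: int, n_init: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding for *n_init* restarts; returns (n_init, k, d) centers."""
    m = X.shape[0]
    centers = np.empty((n_init, k, X.shape[1]))
    first = rng.integers(m, size=n_init)
    centers[:, 0] = X[first]
    d2 = ((X[None, :, :] - centers[:, 0][:, None, :]) ** 2).sum(-1)  # (n_init, m)
    for j in range(1, k):
        total = d2.sum(axis=1, keepdims=True)
        probs = np.where(total > 0, d2 / np.maximum(total, 1e-300), 1.0 / m)
        r = rng.random(n_init)
        idx = (probs.cumsum(axis=1) < r[:, None]).sum(axis=1).clip(max=m - 1)
        centers[:, j] = X[idx]
        nd2 = ((X[None, :, :] - centers[:, j][:, None, :]) ** 2).sum(-1)
        d2 = np.minimum(d2, nd2)
    return centers


def kmeans(X: np.ndarray, k: int, rng: np.random.Generator,
           n_init: int = 4, max_iter: int = 100) -> np.ndarray:
    """Euclidean k-means labels for the best of *n_init* seeded restarts."""
    X = np.asarray(X, float)
    m, d = X.shape
    if k > m:
        raise ValueError("k exceeds the number of points")
    centers = _kmeanspp_init(X, k, n_init, rng)           # (R, k, d)
    R = n_init
    x2 = (X**2).sum(1)
    labels = np.zeros((R, m), dtype=np.intp)
    for _ in range(max_iter):
        flat = centers.reshape(R * k, d)
        # squared distances (m, R*k) via the expansion trick
        D = x2[:, None] - 2.0 * X @ flat.T + (flat**2).sum(1)[None, :]
        new_labels = D.reshape(m, R, k).argmin(axis=2).T   # (R, m)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        # recompute centers; empty clusters get the globally farthest point
        onehot = np.zeros((R, m, k))
        onehot[np.arange(R)[:, None], np.arange(m)[None, :], labels] = 1.0
        counts = onehot.sum(axis=1)                        # (R, k)
        sums = np.einsum("rmk,md->rkd", onehot, X)
        with np.errstate(invalid="ignore"):
            centers = sums / counts[:, :, None]
        if np.any(counts == 0):
            Dmin = D.reshape(m, R, k).min(axis=2).T        # (R, m)
            for r, c in zip(*np.nonzero(counts == 0)):
                centers[r, c] = X[int(Dmin[r].argmax())]
    # pick the restart with the lowest inertia
    flat = centers.reshape(R * k, d)
    D = (x2[:, None] - 2.0 * X @ flat.T + (flat**2).sum(1)[None, :]).reshape(m, R, k)
    inertia = np.take_along_axis(D, labels.T[:, :, None], axis=2)[:, :, 0].sum(axis=0)
    return labels[int(inertia.argmin())]


# -- consensus clustering --------------------------------------------------

@dataclass
class ConsensusResult:
    """Per-k consensus matrices, CDF summaries, and the selected partition."""

    k_values: list[int]
    consensus: dict[int, pd.DataFrame]
    cdf: dict[int, pd.DataFrame]          # columns: value, cdf
    area: dict[int, float]
    delta_area: dict[int, float]
    selected_k: int
    labels: pd.Series                     # subtype label (1..selected_k) per sample


_CDF_GRID = np.linspace(0.0, 1.0, 101)


def _cdf_and_area(consensus: np.ndarray):
    vals = consensus[np.triu_indices(consensus.shape[0], 1)]
    cdf = np.searchsorted(np.sort(vals), _CDF_GRID, side="right") / vals.size
    area = float(np.trapezoid(cdf, _CDF_GRID))
    return pd.DataFrame({"value": _CDF_GRID, "cdf": cdf}), area


def consensus_cluster(candidate_expr: pd.DataFrame, k_min: int = 2, k_max: int = 10,
                      n_resamples: int = 500, sample_fraction: float = 0.8,
                      seed=None, standardize: bool = True, n_init: int = 4,
                      elbow_threshold: float = 0.15) -> ConsensusResult:
    """Consensus clustering of *candidate_expr* (rows = lncRNAs, cols = samples).

    For each k in ``[k_min, k_max]`` and each resample, ceil(fraction * n)
    samples are drawn without replacement and clustered; co-assignment
    counts normalized by co-selection counts form the consensus matrix. A
    resample whose best partition leaves a cluster empty is redrawn (at most
    10 times). ``selected_k`` is the largest k whose relative delta-area
    exceeds *elbow_threshold* (the CDF elbow rule).
    """
    if candidate_expr.shape[0] < 2:
        raise ValueError("need at least 2 candidate lncRNAs")
    n = candidate_expr.shape[1]
    if n < k_max * 3:
        raise ValueError(f"need at least {k_max * 3} samples for k_max={k_max}")
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must lie in (0, 1]")
    X = candidate_expr.to_numpy(float).T  # samples x features
    if standardize:
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant candidate lncRNA cannot be standardized")
        X = (X - X.mean(axis=0)) / sd
    m = int(np.ceil(sample_fraction * n))
    rng = np.random.default_rng(seed)
    samples = candidate_expr.columns

    k_values = list(range(k_min, k_max + 1))
    consensus, cdfs, areas = {}, {}, {}
    for k in k_values:
        I = np.zeros((n, n))
        S = np.zeros((n, n))
        for _ in range(n_resamples):
            for attempt in range(10):
                idx = rng.choice(n, size=m, replace=False)
                labels = kmeans(X[idx], k, rng, n_init=n_init)
                if len(np.unique(labels)) == k:
                    break
            else:
                raise RuntimeError(f"k={k}: empty cluster in 10 consecutive resamples")
            S[np.ix_(idx, idx)] += 1.0
            for c in range(k):
                mem = idx[labels == c]
                I[np.ix_(mem, mem)] += 1.0
        with np.errstate(invalid="ignore"):
            M = np.where(S > 0, I / np.maximum(S, 1), 0.0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0
        consensus[k] = pd.DataFrame(M, index=samples, columns=samples)
        cdfs[k], areas[k] = _cdf_and_area(M)

    delta = {}
    prev = None
    for k in k_values:
        delta[k] = areas[k] if prev is None else (areas[k] - areas[prev]) / areas[prev]
        prev = k
    above = [k for k in k_values if delta[k] > elbow_threshold]
    selected_k = max(above) if above else k_values[0]

    labels = _labels_from_consensus(consensus[selected_k].to_numpy(), selected_k)
    return ConsensusResult(
        k_values=k_values, consensus=consensus, cdf=cdfs, area=areas,
        delta_area=delta, selected_k=selected_k,
        labels=pd.Series(labels, index=samples, name="subtype"),
    )


def _labels_from_consensus(M: np.ndarray, k: int) -> np.ndarray:
    """Cut an average-linkage tree of (1 - consensus) into k groups."""
    dist = squareform(np.clip(1.0 - M, 0.0, None), checks=False)
    Z = linkage(dist, method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(labels)) < k:  # tied merge heights can under-split
        labels = fcluster(Z, t=k, criterion="maxclust_monocrit",
                          monocrit=np.arange(Z.shape[0], dtype=float))
    return labels


# -- subtype vs pathway-score comparison ----------------------------------

def compare_scores_across_subtypes(scores: pd.DataFrame, labels: pd.Series,
                                   alpha: float = 0.05,
                                   min_group: int = 3) -> pd.DataFrame:
    """Kruskal-Wallis comparison of each pathway score across subtypes.

    Subtypes with fewer than *min_group* samples are excluded (warning).
    Pathways that are constant across all retained samples get p = 1 and a
    ``degenerate`` flag. P-values are BH-adjusted across pathways.
    """
    labels = pd.Series(labels).reindex(scores.columns).dropna()
    counts = labels.value_counts()
    small = counts.index[counts < min_group]
    for g in small:
        logger.warning("excluding subtype %r with %d (< %d) samples", g, counts[g], min_group)
    labels = labels[~labels.isin(small)]
    if labels.nunique() < 2:
        raise ValueError("need at least 2 subtypes with enough samples")

    rows = []
    groups = {g: labels.index[labels == g] for g in sorted(labels.unique())}
    for pathway in scores.index:
        vals = [scores.loc[pathway, ix].to_numpy(float) for ix in groups.values()]
        if np.ptp(np.concatenate(vals)) == 0:
            rows.append((pathway, 0.0, 1.0, True))
            continue
        stat, p = kruskal(*vals)
        rows.append((pathway, float(stat), float(p), False))
    out = pd.DataFrame(rows, columns=["pathway", "statistic", "p_value", "degenerate"])
    out["p_adj"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    return out
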