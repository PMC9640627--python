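"""Synthetic tumor cohorts with planted structure.

The generator emulates the statistical situation the screen is built for:
bulk log-expression in which a latent pathway activity drives a block of
mRNAs, a handful of lncRNAs track that activity at a controllable effect
size, tumor purity confounds bulk correlations, samples fall into a few
molecular subtypes separated in active-lncRNA space, and survival follows a
proportional-hazards law driven by the pathway activity.

Generative model (all variables per sample, standardized purity P'):

* purity        ~ Beta(a, b) (default Beta(5, 2), a high-purity cohort);
  P' is purity standardized by its analytic Beta moments.
* activity      A = rho * P' + sqrt(1 - rho^2) * Z with Z ~ N(0,1) and
  rho = ``purity_confounding``; bulk pathway activity co-varies with purity.
* pathway mRNA  m = l_A * A + rho * P' + eps, unit total variance: the same
  direct purity loading as the background plus the activity path, whose
  extra l_A * rho purity covariation is what an unadjusted screen chases.
* background gene (inactive mRNA or inert lncRNA)
                x = rho * P' + sqrt(1 - rho^2) * eps.
* active lncRNA x = a * Z + pc * P' + s(subtype) + eps, with loading ``a``
  solved so that corr(x, A) = ``effect_r`` marginally (subtype-shift
  variance included); effect_r = 0 means a = 0, i.e. conditionally null
  given purity.
* survival      exponential event times with hazard
                lambda = baseline_rate * exp(hazard_beta * A [+ subtype
                offset]); independent Uniform(0, u) censoring with u solved
                so the expected censored fraction equals ``censor_rate``.

Given purity, pathway genes retain only a weak shared component (through
Z), so the purity-adjusted screen is approximately null for inert lncRNAs,
while the unadjusted screen sees the pathway block's systematically higher
purity covariation — the confounding the screen exists to remove.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import ExpressionMatrix, GeneSetCollection, LNCRNA, MRNA
from . import io

PATHWAY_SET_NAME = "PLANTED_PATHWAY"


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the planted-structure generator (defaults = desk-scale cohort)."""

    n_samples: int = 300
    n_mrna: int = 400
    n_lncrna: int = 60
    pathway_set_size: int = 40
    n_active_lnc: int = 5
    effect_r: float = 0.6            # target marginal corr(active lncRNA, activity)
    purity_confounding: float = 0.4  # purity loading on expression and on activity
    n_subtypes: int = 3
    subtype_shift: float = 3.0       # mean centroid separation per active lncRNA, expression units
    hazard_beta: float = 0.7         # log-hazard per unit activity
    censor_rate: float = 0.3
    seed: int = 0
    # secondary knobs (fixed once, documented in docs/methods.md)
    mrna_activity_loading: float = 0.15
    baseline_rate: float = 0.1       # exponential baseline hazard per time unit
    purity_alpha: float = 5.0
    purity_beta: float = 2.0
    baseline_mean: float = 5.0       # additive log-expression baseline per gene
    n_decoy_sets: int = 9            # extra null gene sets written to the GMT
    subtype_log_hr: tuple | None = None  # optional per-subtype log-hazard offsets

    def validate(self) -> None:
        if min(self.n_samples, self.n_mrna, self.n_lncrna, self.pathway_set_size) <= 0:
            raise ValueError("sizes must be positive")
        if self.pathway_set_size > self.n_mrna:
            raise ValueError("pathway_set_size exceeds n_mrna")
        if not 0 <= self.n_active_lnc <= self.n_lncrna:
            raise ValueError("n_active_lnc must lie in [0, n_lncrna]")
        if not 0 <= self.effect_r <= 1:
            raise ValueError("effect_r must lie in [0, 1]")
        if not 0 <= self.purity_confounding < 1:
            raise ValueError("purity_confounding must lie in [0, 1)")
        if self.n_subtypes < 2:
            raise ValueError("n_subtypes must be >= 2")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.subtype_shift < 0:
            raise ValueError("subtype_shift must be nonnegative")
        rho = self.purity_confounding
        if self.mrna_activity_loading ** 2 >= 1:
            raise ValueError("mrna_activity_loading too large")
        if self.subtype_log_hr is not None and len(self.subtype_log_hr) != self.n_subtypes:
            raise ValueError("subtype_log_hr length must equal n_subtypes")
        # fail early if the active-lncRNA loading is unsolvable (effect_r too
        # close to 1 for the requested confounding): probe with zero shift
        if self.effect_r > 0 and self.n_active_lnc > 0:
            _solve_active_loading(self.effect_r, rho, 0.0)


@dataclass
class CohortTruth:
    """Ground truth planted by the generator, for verification downstream."""

    activity: pd.Series            # latent pathway activity per sample
    active_lncrnas: list[str]
    pathway_genes: list[str]
    subtypes: pd.Series            # planted subtype label per sample (1-based)

    def to_dict(self) -> dict:
        return {
            "activity": {k: float(v) for k, v in self.activity.items()},
            "active_lncrnas": list(self.active_lncrnas),
            "pathway_genes": list(self.pathway_genes),
            "subtypes": {k: int(v) for k, v in self.subtypes.items()},
        }


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    purity: pd.Series
    survival: pd.DataFrame
    truth: CohortTruth
    gene_sets: GeneSetCollection
    config: SyntheticConfig

    def __post_init__(self) -> None:
        samples = set(self.expression.sample_ids)
        if set(self.survival.index) != samples:
            raise ValueError("survival must cover exactly the expression samples")
        if not set(self.truth.active_lncrnas) <= set(self.expression.lncrna.index):
            raise ValueError("active lncRNAs must be a subset of lncRNA identifiers")


def _solve_active_loading(effect_r: float, rho: float, shift_var: float) -> float:
    """Loading ``a`` on the purity-free activity component Z for one active lncRNA.

    Solves corr(a*Z + rho*P' + s + eps, A) = effect_r with Var(eps) = 1 and
    shift variance ``shift_var``; raises when no nonnegative solution exists
    (effect size unattainable at the requested confounding).
    """
    if effect_r == 0:
        return 0.0
    q = math.sqrt(1.0 - rho * rho)       # corr(A, Z)
    c0 = rho * rho                        # Cov(x, A) contribution of the purity path
    K = rho * rho + shift_var + 1.0       # Var(x) - a^2
    e2 = effect_r * effect_r
    # (a*q + c0)^2 = e2 * (a^2 + K)
    A2 = q * q - e2
    A1 = 2.0 * q * c0
    A0 = c0 * c0 - e2 * K
    err = ValueError(
        f"effect_r={effect_r} unattainable with purity_confounding={rho} "
        "(implied noise variance negative)"
    )
    if abs(A2) < 1e-12:
        if A1 <= 0:
            raise err
        roots = [-A0 / A1]
    else:
        disc = A1 * A1 - 4.0 * A2 * A0
        if disc < 0:
            raise err
        sq = math.sqrt(disc)
        roots = [(-A1 - sq) / (2 * A2), (-A1 + sq) / (2 * A2)]
    valid = [a for a in roots if a >= 0 and a * q + c0 > 0
             and abs((a * q + c0) / math.sqrt(a * a + K) - effect_r) < 1e-8]
    if not valid:
        raise err
    return min(valid)


def _censor_horizon(lam: np.ndarray, censor_rate: float) -> float:
    """Upper bound of Uniform(0, u) censoring hitting ``censor_rate`` in expectation.

    For exponential event time T with rate lam and C ~ U(0, u),
    P(C < T) = (1 - exp(-lam*u)) / (lam*u); solve the cohort mean for u.
    """

    def frac(u):
        x = lam * u
        return float(np.mean(-np.expm1(-x) / x)) - censor_rate

    # frac is decreasing in u, -> 1 - censor_rate as u -> 0
    lo, hi = 1e-9, 1e9
    return brentq(frac, lo, hi, xtol=1e-10, rtol=1e-12)


def _subtype_centroids(rng: np.random.Generator, k: int, dim: int, shift: float) -> np.ndarray:
    """Random centered centroids with mean pairwise separation ``shift`` per coordinate.

    ``shift`` is in expression units per active lncRNA: centroids are scaled
    so the mean pairwise Euclidean distance equals ``shift * sqrt(dim)``,
    i.e. subtypes differ by about ``shift`` units in each active lncRNA.
    """
    if dim == 0 or shift == 0:
        return np.zeros((k, dim))
    c = rng.standard_normal((k, dim))
    c -= c.mean(axis=0)
    d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
    mean_d = d[np.triu_indices(k, 1)].mean()
    if mean_d == 0:  # degenerate draw; retry deterministically
        return _subtype_centroids(rng, k, dim, shift)
    return c * (shift * math.sqrt(dim) / mean_d)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a seeded cohort with planted pathway, lncRNA, subtype and hazard structure."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    rho = config.purity_confounding

    samples = [f"S{i:04d}" for i in range(n)]
    mrna_ids = [f"MRNA_{i:04d}" for i in range(config.n_mrna)]
    lnc_ids = [f"LNC_{i:03d}" for i in range(config.n_lncrna)]
    pathway_genes = mrna_ids[: config.pathway_set_size]
    active_lnc = lnc_ids[: config.n_active_lnc]

    # latent structure
    purity = rng.beta(config.purity_alpha, config.purity_beta, size=n)
    mu_p = config.purity_alpha / (config.purity_alpha + config.purity_beta)
    var_p = (config.purity_alpha * config.purity_beta
             / ((config.purity_alpha + config.purity_beta) ** 2
                * (config.purity_alpha + config.purity_beta + 1)))
    p_std = (purity - mu_p) / math.sqrt(var_p)
    z = rng.standard_normal(n)
    activity = rho * p_std + math.sqrt(1 - rho * rho) * z

    subtypes = rng.integers(1, config.n_subtypes + 1, size=n)
    centroids = _subtype_centroids(rng, config.n_subtypes,
                                   config.n_active_lnc, config.subtype_shift)
    # population shift variance per active-lncRNA coordinate (equal subtype mass)
    shift_var = centroids.var(axis=0, ddof=0) if config.n_active_lnc else np.zeros(0)

    values = np.empty((config.n_mrna + config.n_lncrna, n))
    l_a = config.mrna_activity_loading
    # pathway gene: l_a*A + rho*P' + noise (direct purity loading matches the
    # background, the activity path adds l_a*rho on top — the differential
    # purity covariation an unadjusted screen chases)
    var_path = 1 - l_a * l_a - rho * rho - 2 * l_a * rho * rho
    if var_path <= 0:
        raise ValueError("implied pathway-mRNA noise variance negative "
                         "(mrna_activity_loading/purity_confounding too large)")
    sd_path = math.sqrt(var_path)
    sd_bg = math.sqrt(1 - rho * rho)

    # mRNAs: pathway block then background
    npath = config.pathway_set_size
    values[:npath] = (l_a * activity + rho * p_std
                      + sd_path * rng.standard_normal((npath, n)))
    nbg = config.n_mrna - npath
    values[npath:config.n_mrna] = (rho * p_std
                                   + sd_bg * rng.standard_normal((nbg, n)))

    # lncRNAs: active block then inert
    off = config.n_mrna
    for j in range(config.n_active_lnc):
        a = _solve_active_loading(config.effect_r, rho, float(shift_var[j]))
        shift = centroids[subtypes - 1, j]
        values[off + j] = a * z + rho * p_std + shift + rng.standard_normal(n)
    ninert = config.n_lncrna - config.n_active_lnc
    values[off + config.n_active_lnc:] = (rho * p_std
                                          + sd_bg * rng.standard_normal((ninert, n)))

    # gene-specific baselines keep correlations intact but mimic log-expression levels
    values += config.baseline_mean + 0.5 * rng.standard_normal(values.shape[0])[:, None]

    expr = pd.DataFrame(values, index=mrna_ids + lnc_ids, columns=samples)
    partition = pd.Series([MRNA] * config.n_mrna + [LNCRNA] * config.n_lncrna,
                          index=expr.index)

    # survival: exponential PH in activity (+ optional subtype offsets)
    eta = config.hazard_beta * activity
    if config.subtype_log_hr is not None:
        eta = eta + np.asarray(config.subtype_log_hr, float)[subtypes - 1]
    lam = config.baseline_rate * np.exp(eta)
    t_event = rng.exponential(1.0 / lam)
    if config.censor_rate > 0:
        u = _censor_horizon(lam, config.censor_rate)
        t_cens = rng.uniform(0.0, u, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, int)
    surv = pd.DataFrame({"time": time, "event": event}, index=samples)

    # gene sets: the planted pathway plus decoy sets from background mRNAs
    sets = {PATHWAY_SET_NAME: list(pathway_genes)}
    bg_pool = np.array(mrna_ids[npath:])
    for d in range(config.n_decoy_sets):
        size = min(config.pathway_set_size, len(bg_pool))
        if size < 2:
            break
        sets[f"DECOY_{d:02d}"] = list(rng.choice(bg_pool, size=size, replace=False))
    collection = GeneSetCollection(sets, source="synthetic")

    truth = CohortTruth(
        activity=pd.Series(activity, index=samples, name="activity"),
        active_lncrnas=active_lnc,
        pathway_genes=list(pathway_genes),
        subtypes=pd.Series(subtypes, index=samples, name="subtype"),
    )
    return SyntheticCohort(
        expression=ExpressionMatrix(expr, partition),
        purity=pd.Series(purity, index=samples, name="purity"),
        survival=surv,
        truth=truth,
        gene_sets=collection,
        config=config,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write the cohort's TSV/GMT/JSON files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "partition": outdir / "partition.tsv",
        "purity": outdir / "purity.tsv",
        "survival": outdir / "survival.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth": outdir / "truth.json",
    }
    io.write_expression(cohort.expression, paths["expression"])
    io.write_partition(cohort.expression, paths["partition"])
    io.write_purity(cohort.purity, paths["purity"])
    io.write_survival(cohort.survival, paths["survival"])
    io.write_gmt(cohort.gene_sets, paths["gene_sets"])
    truth = cohort.truth.to_dict()
    truth["config"] = {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(cohort.config).items()}
    io.write_json(truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
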