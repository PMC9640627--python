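"""End-to-end orchestration: simulate/load -> score -> screens -> subtypes -> risk.

Stage order follows the analysis the package implements: ssGSEA pathway
scores, univariate Cox pathway screen, purity-adjusted lncRNA screen
against the target gene set, consensus subtyping of candidate lncRNAs, and
the lncRNA risk model. Every stage writes plain-text outputs into the run
directory and the manifest records seeds, parameters and record counts.

All randomness derives from the single config seed: per-stage seeds are
``SeedSequence(seed).generate_state(n) % 2**31`` taken in a fixed stage
order (0 = simulate, 1 = lncRNA screen, 2 = subtyping), so reruns are
byte-identical and stages are individually reproducible.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .containers import ExpressionMatrix, check_purity, check_survival
from .risk import fit_risk_model, plot_survival_curves, survival_curves
from .scoring import ssgsea_scores
from .screen import screen_lncrnas
from .subtyping import compare_scores_across_subtypes, consensus_cluster
from .survival_screen import fit_univariate_cox, screen_pathways
from .synthetic import SyntheticConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Inputs (real paths XOR a synthetic block) plus stage parameters."""

    outdir: str = "lncpath_run"
    seed: int = 0
    # real inputs
    expression: str | None = None
    partition: str | None = None
    purity: str | None = None
    survival: str | None = None
    gene_sets: str | None = None
    target_set: str | None = None    # name of the set screened against; default: first
    # synthetic block
    synthetic: SyntheticConfig | None = None
    # stage parameters
    ssgsea_exponent: float = 0.25
    ssgsea_normalize: bool = False
    cox_alpha: float = 0.05
    n_perm: int = 1000
    weight_exp: float = 1.0
    tes_threshold: float = 0.95
    fdr_threshold: float = 0.05
    k_min: int = 2
    k_max: int = 10
    n_resamples: int = 500
    sample_fraction: float = 0.8
    standardize: bool = True
    risk_mode: str = "multivariate"
    risk_alpha: float = 0.05         # univariate prefilter for key lncRNAs
    plots: bool = False

    def validate(self) -> None:
        real = [self.expression, self.purity, self.survival, self.gene_sets]
        if self.synthetic is not None and any(p is not None for p in real):
            raise ValueError("config must specify real input paths or a synthetic block, not both")
        if self.synthetic is None and not all(p is not None for p in real):
            raise ValueError("config must specify all real input paths or a synthetic block")
        if self.synthetic is not None:
            self.synthetic.validate()
        if not (0 < self.cox_alpha <= 1 and 0 < self.fdr_threshold <= 1):
            raise ValueError("significance levels must lie in (0, 1]")
        if not 0 <= self.tes_threshold < 1:
            raise ValueError("tes_threshold must lie in [0, 1)")
        if self.risk_mode not in ("multivariate", "univariate"):
            raise ValueError("risk_mode must be 'multivariate' or 'univariate'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            if "subtype_log_hr" in syn and syn["subtype_log_hr"] is not None:
                syn["subtype_log_hr"] = tuple(syn["subtype_log_hr"])
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {"simulate": seeds[0], "screen_lnc": seeds[1], "subtype": seeds[2]},
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in ("synthetic", "outdir")  # outdir is where the manifest lives
        },
        "stages": {},
    }

    # -- stage 0: inputs ---------------------------------------------------
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=seeds[0])
        logger.info("simulate: generating cohort (seed %d)", seeds[0])
        cohort = generate_cohort(syn)
        write_cohort(cohort, outdir / "inputs")
        expr, purity, surv = cohort.expression, cohort.purity, cohort.survival
        sets = cohort.gene_sets
        manifest["parameters"]["synthetic"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(syn).items()
        }
    else:
        expr = io.read_expression(config.expression, config.partition)
        purity = io.read_purity(config.purity)
        surv = io.read_survival(config.survival)
        sets = io.read_gmt(config.gene_sets)

    # align everything on the intersection of sample ids, once
    samples = expr.sample_ids.intersection(purity.index).intersection(surv.index)
    dropped = len(expr.sample_ids) - len(samples)
    if dropped:
        logger.warning("dropping %d samples absent from purity/survival", dropped)
    expr = expr.subset_samples(samples)
    purity = check_purity(purity, samples)
    surv = check_survival(surv, samples)
    target_name = config.target_set or next(iter(sets))
    if target_name not in sets.sets:
        raise ValueError(f"target set {target_name!r} not in the collection")
    manifest["stages"]["inputs"] = {
        "n_samples": int(len(samples)), "n_dropped": int(dropped),
        "n_mrna": int(expr.mrna.shape[0]), "n_lncrna": int(expr.lncrna.shape[0]),
        "n_gene_sets": len(sets), "target_set": target_name,
    }

    # -- stage 1: ssGSEA pathway scores -----------------------------------
    logger.info("score: ssGSEA over %d gene sets", len(sets))
    scores = ssgsea_scores(expr.mrna, sets, exponent=config.ssgsea_exponent,
                           normalize=config.ssgsea_normalize)
    io.write_table(scores, outdir / "pathway_scores.tsv", index_label="pathway")
    manifest["stages"]["score"] = {"n_pathways": int(scores.shape[0])}

    # -- stage 2: pathway survival screen ---------------------------------
    logger.info("screen-pathways: univariate Cox at alpha=%g", config.cox_alpha)
    pscreen = screen_pathways(scores, surv, alpha=config.cox_alpha)
    io.write_table(pscreen, outdir / "pathway_screen.tsv")
    manifest["stages"]["screen_pathways"] = {
        "n_fitted": int(pscreen.shape[0]),
        "n_significant": int(pscreen["significant"].sum()) if len(pscreen) else 0,
    }

    # -- stage 3: lncRNA screen -------------------------------------------
    logger.info("screen-lnc: target set %r, n_perm=%d", target_name, config.n_perm)
    lscreen = screen_lncrnas(expr, purity, sets[target_name], n_perm=config.n_perm,
                             weight_exp=config.weight_exp,
                             tes_threshold=config.tes_threshold,
                             fdr_threshold=config.fdr_threshold, seed=seeds[1])
    io.write_table(lscreen, outdir / "lnc_screen.tsv")
    candidates = lscreen.loc[lscreen["is_candidate"], "lnc_id"].tolist()
    manifest["stages"]["screen_lnc"] = {
        "n_screened": int(lscreen.shape[0]), "n_candidates": len(candidates),
    }

    # -- stage 4: consensus subtyping -------------------------------------
    if len(candidates) >= 2:
        logger.info("subtype: %d candidates, k in [%d, %d]",
                    len(candidates), config.k_min, config.k_max)
        k_max = min(config.k_max, len(samples) // 3)
        res = consensus_cluster(expr.values.loc[candidates], k_min=config.k_min,
                                k_max=k_max, n_resamples=config.n_resamples,
                                sample_fraction=config.sample_fraction,
                                seed=seeds[2], standardize=config.standardize)
        io.write_table(res.labels.to_frame(), outdir / "subtype_labels.tsv",
                       index_label="sample")
        summary = pd.DataFrame({
            "k": res.k_values,
            "area": [res.area[k] for k in res.k_values],
            "delta_area": [res.delta_area[k] for k in res.k_values],
        })
        io.write_table(summary, outdir / "consensus_summary.tsv")
        for k in res.k_values:
            io.write_table(res.consensus[k], outdir / f"consensus_k{k}.tsv",
                           index_label="sample")
        comp = compare_scores_across_subtypes(scores, res.labels)
        io.write_table(comp, outdir / "subtype_pathway_tests.tsv")
        manifest["stages"]["subtype"] = {
            "selected_k": int(res.selected_k),
            "n_significant_pathways": int(comp["significant"].sum()),
        }
        labels = res.labels
    else:
        logger.warning("subtype: skipped (%d candidate(s))", len(candidates))
        manifest["stages"]["subtype"] = {"skipped": True}
        labels = None

    # -- stage 5: risk model ----------------------------------------------
    key = _select_key_lncrnas(expr, surv, candidates, alpha=config.risk_alpha)
    if key:
        logger.info("risk: %d key lncRNAs, mode=%s", len(key), config.risk_mode)
        model = fit_risk_model(expr.values.loc[key], surv, mode=config.risk_mode)
        risk_tbl = pd.DataFrame({"score": model.risk_scores, "group": model.groups})
        io.write_table(risk_tbl, outdir / "risk_scores.tsv", index_label="sample")
        io.write_json(model.to_dict(), outdir / "risk_model.json")
        curves, stat, p = survival_curves(surv, model.groups)
        for g, tbl in curves.items():
            io.write_table(tbl, outdir / f"km_{g}.tsv")
        if config.plots:
            plot_survival_curves(curves, outdir / "km_risk_groups.png")
        manifest["stages"]["risk"] = {
            "n_key_lncrnas": len(key),
            "logrank_p": None if model.logrank_p is None else float(model.logrank_p),
            "degenerate": bool(model.degenerate),
        }
    else:
        logger.warning("risk: skipped (no key lncRNAs)")
        manifest["stages"]["risk"] = {"skipped": True}

    io.write_json(manifest, outdir / "manifest.json")
    return manifest


def _select_key_lncrnas(expr: ExpressionMatrix, surv: pd.DataFrame,
                        candidates: list[str], alpha: float) -> list[str]:
    """Candidates individually prognostic by univariate Cox (fallback: all)."""
    if not candidates:
        return []
    keep = []
    for lnc in candidates:
        try:
            est = fit_univariate_cox(expr.values.loc[lnc], surv)
        except Exception as exc:
            logger.warning("key-lncRNA prefilter: %s excluded (%s)", lnc, exc)
            continue
        if est.p_value < alpha:
            keep.append(lnc)
    return keep or candidates
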