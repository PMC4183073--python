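"""End-to-end orchestration of the count-matrix-to-regulators workflow.

Stages run in the fixed order: (optional) simulate -> preprocess -> network
-> module statistics -> differential connectivity -> enrichment ->
regulators.  Every stage is a pure function of (inputs, parameters, seed):
a single global seed is fanned out to per-stage seeds through a fixed
counter scheme, so a repeated run with the same configuration is
byte-identical, and running a stage never perturbs another stage's
randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import SimulationConfig, SyntheticStudy, read_study, simulate_study, write_study
from .diffconn import differential_connectivity, select_diff_genes
from .enrichment import enrich_module
from .modules import (
    gene_trait_correlation,
    module_eigengenes,
    module_membership,
    module_trait,
    refine_module,
    select_modules,
)
from .network import WGCNA
from .preprocess import (
    filter_low_expression,
    normalize,
    select_by_connectivity,
    size_factors,
    variance_filter,
)
from .regulators import (
    TightClusterEnsemble,
    ensemble_regulator_scores,
    per_run_tree_collections,
    regulator_significance,
    standardize,
    top_regulators,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

# offsets of the per-stage seed fan-out; order-independent reproducibility
_SEED_OFFSETS = {"simulate": 1, "regulators": 2, "significance": 3}


@dataclass
class PipelineConfig:
    """All inputs, outputs and stage parameters of one pipeline run."""

    out_dir: str = "adiponet_run"
    #: directory with counts.tsv/phenotypes.csv/... ; None -> simulate
    input_dir: str | None = None
    seed: int = 0
    # simulate
    n_genes: int = 2000
    # preprocess
    low_count_threshold: float = 5.0
    sd_min_network: float = 0.25
    sd_min_regulators: float = 0.5
    top_n_connectivity: int = 1500
    # network
    beta: int | str = "auto"
    r2_target: float = 0.90
    min_module_size: int = 50
    cut_height_quantile: float | None = None
    # module statistics
    mtr_threshold: float = 0.5
    kme_own_min: float = 0.6
    kme_other_max: float = 0.6
    # differential connectivity
    beta_subnetwork: int = 9
    kdiff_threshold: float = 0.6
    t_threshold: float = 1.96
    # enrichment
    alpha: float = 0.05
    # regulators
    n_gibbs_runs: int = 10
    n_gibbs_sweeps: int = 200
    min_cluster_size: int = 10
    cocluster_threshold: float = 0.8
    top_regulator_pct: float = 0.01
    n_random_regulator_sets: int = 100

    def validate(self) -> None:
        in_unit = {
            "mtr_threshold": self.mtr_threshold,
            "kme_own_min": self.kme_own_min,
            "kme_other_max": self.kme_other_max,
            "alpha": self.alpha,
            "r2_target": self.r2_target,
            "cocluster_threshold": self.cocluster_threshold,
            "top_regulator_pct": self.top_regulator_pct,
        }
        for name, v in in_unit.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.cut_height_quantile is not None and not 0 < self.cut_height_quantile <= 1:
            raise ValueError("cut_height_quantile must lie in (0, 1] or be null")
        if self.beta != "auto" and int(self.beta) < 1:
            raise ValueError("beta must be 'auto' or a positive integer")
        for name in ("kdiff_threshold", "t_threshold", "low_count_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_module_size < 2 or self.min_cluster_size < 2:
            raise ValueError("minimum module/cluster sizes must be >= 2")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat key-value YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _scaled_simulation_config(n_genes: int, seed: int) -> SimulationConfig:
    """The reference study shape scaled proportionally to ``n_genes``."""
    fractions = (0.12, 0.10, 0.09, 0.08, 0.07)
    sizes = tuple(max(12, int(round(f * n_genes))) for f in fractions)
    n_low = int(round(0.05 * n_genes))
    planted = sum(sizes) + 10 + 30 + 2
    n_bg = n_genes - planted - n_low
    if n_bg < 20:
        raise ValueError(f"n_genes={n_genes} too small for the study shape")
    return SimulationConfig(
        n_genes=n_genes,
        module_sizes=sizes,
        n_candidate_regulators=min(200, 2 + n_bg // 2),
        seed=seed,
    )


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    ss = np.random.SeedSequence([config.seed, _SEED_OFFSETS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write per-stage outputs and a machine-readable report.

    Returns the report dict (also written as ``report.json``).  Any stage
    failure aborts with the stage name in the exception and leaves a FAILED
    marker next to the partial outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages": {},
    }
    log_lines = [f"adiponet {__version__} seed={config.seed}"]
    stage = "setup"
    try:
        # ------------------------------------------------------------ input
        stage = "simulate"
        if config.input_dir is None:
            study = simulate_study(
                _scaled_simulation_config(config.n_genes, _stage_seed(config, "simulate"))
            )
            write_study(study, out / "study")
            log_lines.append(f"simulated study: {config.n_genes} genes, seed fan-out")
        else:
            study = read_study(config.input_dir)
            log_lines.append(f"loaded study from {config.input_dir}")
        report["stages"]["input"] = {
            "n_genes": int(study.counts.shape[0]),
            "n_samples": int(study.counts.shape[1]),
        }

        # ------------------------------------------------------- preprocess
        stage = "preprocess"
        counts = filter_low_expression(study.counts, config.low_count_threshold)
        sf = size_factors(counts)
        expr = normalize(counts, sf, study.phenotypes)
        expr = expr.loc[expr.std(axis=1, ddof=1) > 0]  # constant genes carry nothing
        expr.to_csv(out / "normalized.tsv", sep="\t")
        expr_net = variance_filter(expr, config.sd_min_network)
        groups = study.phenotypes["group"]
        top_n = min(config.top_n_connectivity, expr_net.shape[0])
        beta_sel = config.beta if config.beta != "auto" else 7
        network_genes = select_by_connectivity(
            expr_net, groups, top_n=top_n, beta=int(beta_sel)
        )
        (out / "selected_genes.txt").write_text("".join(g + "\n" for g in network_genes))
        report["stages"]["preprocess"] = {
            "n_after_low_count_filter": int(counts.shape[0]),
            "n_after_sd_filter": int(expr_net.shape[0]),
            "n_network_genes": len(network_genes),
        }

        # ---------------------------------------------------------- network
        stage = "network"
        net = WGCNA(
            beta=config.beta,
            min_module_size=config.min_module_size,
            cut_height_quantile=config.cut_height_quantile,
            r2_target=config.r2_target,
        ).fit(expr.loc[network_genes])
        net.modules_.rename("module").to_csv(out / "modules.tsv", sep="\t")
        if net.scale_free_sweep_ is not None:
            net.scale_free_sweep_.to_csv(out / "scale_free_sweep.tsv", sep="\t", index=False)
        module_sizes = net.modules_.value_counts().to_dict()
        report["stages"]["network"] = {
            "beta": int(net.beta_),
            "n_modules": int(len([m for m in module_sizes if m != "grey"])),
            "module_sizes": {str(k): int(v) for k, v in sorted(module_sizes.items())},
        }

        # ----------------------------------------------- module statistics
        stage = "modules"
        eig, var_explained = module_eigengenes(expr.loc[network_genes], net.modules_)
        quant_traits = study.phenotypes.select_dtypes("number")
        mtr = module_trait(eig, quant_traits)
        kme = module_membership(expr.loc[network_genes], eig)
        gs = gene_trait_correlation(expr.loc[network_genes], quant_traits)
        eig.to_csv(out / "eigengenes.tsv", sep="\t")
        mtr.r.to_csv(out / "mtr.tsv", sep="\t")
        mtr.p.to_csv(out / "mtr_pvalues.tsv", sep="\t")
        kme.to_csv(out / "kme.tsv", sep="\t")
        gs.to_csv(out / "gene_significance.tsv", sep="\t")
        selected = select_modules(mtr, config.mtr_threshold)
        refined = {
            m: refine_module(
                kme.loc[net.modules_.index[net.modules_ == m]],
                m,
                own_min=config.kme_own_min,
                other_max=config.kme_other_max,
            )
            for m in selected
        }
        (out / "selected_modules.txt").write_text("".join(m + "\n" for m in selected))
        report["stages"]["modules"] = {
            "var_explained": {m: round(float(v), 4) for m, v in var_explained.items()},
            "mtr_max_abs": round(float(mtr.r.abs().max().max()), 4) if not mtr.r.empty else None,
            "selected_modules": selected,
            "refined_sizes": {m: len(g) for m, g in refined.items()},
        }

        # --------------------------------------- differential connectivity
        stage = "diffconn"
        dc = differential_connectivity(
            expr_net,
            groups,
            beta=config.beta_subnetwork,
            kd_threshold=config.kdiff_threshold,
            t_threshold=config.t_threshold,
        )
        dc.to_csv(out / "diffconn.tsv", sep="\t")
        diff_genes = select_diff_genes(dc, config.kdiff_threshold, config.t_threshold)
        report["stages"]["diffconn"] = {
            "n_differentially_connected": int((dc["k_diff"].abs() > config.kdiff_threshold).sum()),
            "n_selected": len(diff_genes),
        }

        # ------------------------------------------------------- enrichment
        stage = "enrich"
        enrich_counts = {}
        for m in selected:
            genes = refined[m] if len(refined[m]) >= 2 else list(
                net.modules_.index[net.modules_ == m]
            )
            table = enrich_module(
                genes, network_genes, study.gene_sets, study.gene_lengths, alpha=config.alpha
            )
            table.to_csv(out / f"enrichment_{m}.tsv", sep="\t")
            enrich_counts[m] = int(table["significant"].sum())
        report["stages"]["enrich"] = {"n_significant_terms": enrich_counts}

        # ------------------------------------------------------- regulators
        stage = "regulators"
        expr_reg = variance_filter(expr, config.sd_min_regulators)
        scaled = standardize(expr_reg)
        ensemble = TightClusterEnsemble(
            n_runs=config.n_gibbs_runs,
            freq_threshold=config.cocluster_threshold,
            min_cluster_size=config.min_cluster_size,
            n_sweeps=config.n_gibbs_sweeps,
            random_state=_stage_seed(config, "regulators"),
        ).fit(scaled)
        ensemble.assignments_.to_csv(out / "clusters.tsv", sep="\t")
        collections = per_run_tree_collections(
            scaled, ensemble.runs_, min_size=config.min_cluster_size
        )
        reg_expr = standardize(expr)  # candidates may sit below the SD filter
        scores = ensemble_regulator_scores(reg_expr, study.candidate_regulators, collections)
        score_table = scores.per_cluster.copy()
        score_table["global_score"] = scores.global_score
        score_table.to_csv(out / "regulator_scores.tsv", sep="\t")
        top = top_regulators(scores.global_score, config.top_regulator_pct)
        sig = regulator_significance(
            reg_expr,
            collections,
            assigned=top if len(top) >= 2 else list(scores.global_score.index[:2]),
            candidates=study.candidate_regulators,
            n_random=config.n_random_regulator_sets,
            seed=_stage_seed(config, "significance"),
        )
        (out / "top_regulators.txt").write_text("".join(g + "\n" for g in top))
        report["stages"]["regulators"] = {
            "n_genes_clustered": int(scaled.shape[0]),
            "n_tight_clusters": len(ensemble.clusters_),
            "top_regulators": top,
            "t_test_p": float(sig.p_value),
        }
    except Exception as err:
        (out / "FAILED").write_text(f"stage={stage}: {err}\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    report_text = json.dumps(report, indent=1, sort_keys=True)
    (out / "report.json").write_text(report_text)
    log_lines.append("pipeline complete")
    (out / "run.log").write_text("".join(line + "\n" for line in log_lines))
    return report
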