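"""End-to-end orchestration of the signature pipeline.

``run_analysis`` is the in-memory core: gene extraction → pair matrices →
invariance filter → univariate screen → (optional) consensus subtyping →
robust LASSO selection → forward AUROC model build → per-cohort scoring
and reports.  ``run_pipeline`` wraps it for on-disk artifacts driven by a
``RunConfig`` (all stochastic stages take the single mandatory seed), and
``simulate_to_dir`` materialises synthetic cohorts as the same TSV/GMT
files the readers consume.  Re-running with an identical config and seed
reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    SignatureModel,
    read_clinical,
    read_expression,
    read_gmt,
    write_clinical,
    write_expression,
    write_gmt,
    write_model,
)
from .pairs import (
    apply_pairs,
    build_pair_matrix,
    extract_metabolic_genes,
    filter_invariant_pairs,
    write_pairs,
)
from .signature import (
    RiskAssignment,
    forward_auroc_build,
    robust_lasso_select,
    score_samples,
)
from .simulate import SimulationConfig, simulate
from .subtypes import compare_subtype_survival, consensus_cluster
from .survival import screen_pairs
from .reporting import survival_comparison_report

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_analysis", "run_pipeline",
           "simulate_to_dir"]


@dataclass
class RunConfig:
    """File-driven pipeline configuration (paths relative to the config)."""

    cohorts: dict[str, tuple[str, str]]  # name -> (expression TSV, clinical TSV)
    gmt: str
    seed: int
    validation: list[str] = field(default_factory=list)
    name_pattern: str = "METABOLISM"
    filter_threshold: float = 0.80
    alpha: float = 0.05
    n_iter: int = 1000
    min_freq: int = 50
    horizon: float = 3.0
    k: int | None = None
    out_dir: str = "pairsig_run"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for every pipeline run")
        if not self.cohorts:
            raise ValueError("at least one cohort is required")
        training = [n for n in self.cohorts if n not in self.validation]
        if not training:
            raise ValueError("at least one training cohort is required")


@dataclass
class PipelineResult:
    genes: list[str]
    kept_pairs: list
    screen_report: pd.DataFrame
    robust_reports: list
    model: SignatureModel
    assignments: dict[str, RiskAssignment]
    funnel: dict[str, int]
    subtypes: pd.Series | None = None
    subtype_logrank: tuple[float, float] | None = None
    consensus: pd.DataFrame | None = None


def _merge_training(
    cohorts: dict[str, tuple[ExpressionMatrix, ClinicalTable]],
    training: list[str],
    kept_pairs,
):
    mats = [apply_pairs(cohorts[n][0], kept_pairs) for n in training]
    values = np.concatenate([m.values for m in mats], axis=1)
    sample_ids = [s for m in mats for s in m.sample_ids]
    from .pairs import PairMatrix

    merged_pm = PairMatrix(list(kept_pairs), sample_ids, values)
    clin_frames = [cohorts[n][1].data[["time", "event"]] for n in training]
    merged_clin = ClinicalTable(pd.concat(clin_frames, axis=0))
    return merged_pm, merged_clin


def run_analysis(
    cohorts: dict[str, tuple[ExpressionMatrix, ClinicalTable]],
    gsc: GeneSetCollection,
    seed: int,
    validation: list[str] | None = None,
    name_pattern: str = "METABOLISM",
    filter_threshold: float = 0.80,
    alpha: float = 0.05,
    n_iter: int = 1000,
    min_freq: int = 50,
    horizon: float = 3.0,
    k: int | None = None,
    consensus_resamples: int = 200,
) -> PipelineResult:
    """Run the full cascade in memory and return every stage's output.

    Cohorts named in ``validation`` are excluded from screening and model
    fitting but participate in the invariance filter (the filter is an
    any-dataset rule) and are scored with the final model.
    """
    validation = list(validation or [])
    training = [n for n in cohorts if n not in validation]
    if not training:
        raise ValueError("no training cohorts left after exclusions")

    genes = extract_metabolic_genes(
        gsc, [expr for expr, _ in cohorts.values()], name_pattern
    )
    pair_mats = {n: build_pair_matrix(expr, genes)
                 for n, (expr, _) in cohorts.items()}
    kept, excluded = filter_invariant_pairs(pair_mats, filter_threshold)
    if not kept:
        raise ValueError("no pairs survive the invariance filter")

    merged_pm, merged_clin = _merge_training(cohorts, training, kept)
    screened, screen_report = screen_pairs(merged_pm, merged_clin, alpha)
    if not screened:
        raise ValueError("no pairs pass the prognostic screen")
    screened_pm = merged_pm.subset_pairs(screened)

    subtypes = subtype_logrank = consensus = None
    if k is not None:
        cc = consensus_cluster(screened_pm, k=k, n_resamples=consensus_resamples,
                               seed=seed)
        stat, p, _ = compare_subtype_survival(cc.labels, merged_clin)
        subtypes, subtype_logrank, consensus = cc.labels, (stat, p), cc.consensus

    robust = robust_lasso_select(screened_pm, merged_clin, n_iter=n_iter,
                                 min_freq=min_freq, seed=seed)
    model = forward_auroc_build(robust, screened_pm, merged_clin, horizon)
    model.provenance.update({"seed": seed, "training_cohorts": training,
                             "alpha": alpha, "n_iter": n_iter,
                             "min_freq": min_freq})

    assignments = {}
    for name, (expr, _) in cohorts.items():
        # project every cohort (training and held-out) into the pair space
        assignments[name] = score_samples(model, apply_pairs(expr, kept))

    funnel = {
        "genes": len(genes),
        "pairs_built": pair_mats[training[0]].n_pairs,
        "pairs_kept_after_filter": len(kept),
        "pairs_screened": len(screened),
        "pairs_robust": sum(r.robust for r in robust),
        "pairs_final": len(model.pairs),
    }
    logger.info("funnel: %s", funnel)
    return PipelineResult(
        genes=genes, kept_pairs=kept, screen_report=screen_report,
        robust_reports=robust, model=model, assignments=assignments,
        funnel=funnel, subtypes=subtypes, subtype_logrank=subtype_logrank,
        consensus=consensus,
    )


def run_pipeline(config: RunConfig, base_dir: str | Path = ".") -> Path:
    """File-in, artifacts-out pipeline run; returns the artifact directory."""
    base = Path(base_dir)
    cohorts = {}
    for name, (expr_path, clin_path) in config.cohorts.items():
        expr = read_expression(base / expr_path)
        clin = read_clinical(base / clin_path)
        common = [s for s in expr.sample_ids if s in set(clin.sample_ids)]
        expr = ExpressionMatrix(expr.data[common])
        cohorts[name] = (expr, clin.subset(common))
    gsc = read_gmt(base / config.gmt)

    result = run_analysis(
        cohorts, gsc, seed=config.seed, validation=config.validation,
        name_pattern=config.name_pattern,
        filter_threshold=config.filter_threshold, alpha=config.alpha,
        n_iter=config.n_iter, min_freq=config.min_freq,
        horizon=config.horizon, k=config.k,
    )

    out = base / config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    (out / "genes.txt").write_text("\n".join(result.genes) + "\n")
    write_pairs(result.kept_pairs, out / "pairs_kept.tsv")
    result.screen_report.to_csv(out / "screen_report.tsv", sep="\t")
    pd.DataFrame(
        [{"pair": r.pair.label, "frequency": r.frequency, "n_iter": r.n_iter,
          "univariate_p": r.univariate_p, "robust": r.robust}
         for r in result.robust_reports]
    ).to_csv(out / "robust_report.tsv", sep="\t", index=False)
    write_model(result.model, out / "model.json")
    for name, assignment in result.assignments.items():
        assignment.to_frame().to_csv(out / f"assignment_{name}.tsv", sep="\t")
        report = survival_comparison_report(
            assignment, cohorts[name][1].subset(assignment.sample_ids),
            horizons=[config.horizon], cohort_name=name,
        )
        (out / f"report_{name}.txt").write_text(report)
    if result.subtypes is not None:
        result.subtypes.to_csv(out / "subtypes.tsv", sep="\t")
        result.consensus.to_csv(out / "consensus.tsv", sep="\t")
    pd.Series(result.funnel).to_csv(out / "funnel.tsv", sep="\t", header=False)
    provenance = {
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "version": __version__,
        "seed": config.seed,
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n"
    )
    return out


def simulate_to_dir(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Emit synthetic cohorts as the TSV/GMT fixtures the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (name, _), (expr, clin) in zip(config.cohorts, simulate(config)):
        write_expression(expr, out / f"{name}_expression.tsv")
        write_clinical(clin, out / f"{name}_clinical.tsv")
    if config.marker_sets is not None:
        write_gmt(config.marker_sets, out / "markers.gmt")
    return out
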