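"""Self-contained synthetic validation studies for the pipeline.

Each function sets up a fully specified synthetic study — the generator
parameters ARE the study conditions — runs the relevant pipeline stages,
and returns the measured quantities.  The test suite asserts on these
numbers and the acceptance script reports them; both call the same code.

Studies:

* ``pair_invariance_study`` — pair matrices must be bit-identical across
  per-sample monotone platform distortions.
* ``filter_study`` — every pair kept by the invariance filter has
  minority-class fraction at least 1 − threshold in every cohort, and
  kept/excluded partition the pair universe.
* ``screen_null_calibration`` — type-I error of the univariate Cox screen
  under a planted null (β = 0).
* ``recovery_study`` — end-to-end signature recovery: 5 planted pairs
  (β = 1.5, prevalence 0.5) among 50 gene-disjoint null pairs, two
  training cohorts of 150 with ~30% uniform censoring, a held-out cohort
  of 150 for risk-group separation.
* ``consensus_block_study`` — consensus clustering must perfectly recover
  two well-separated planted sample blocks (adjusted Rand index).
* ``dca_reference_check`` — closed-form treat-all/treat-none reference
  curves of decision-curve analysis.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io import ClinicalTable
from .pairs import PairDefinition, PairMatrix, apply_pairs, filter_invariant_pairs
from .reporting import decision_curve
from .signature import forward_auroc_build, robust_lasso_select, score_samples
from .simulate import PlantedPair, SimulationConfig, gene_name, simulate
from .subtypes import consensus_cluster
from .survival import log_rank, screen_pairs

__all__ = [
    "recovery_conditions",
    "pair_invariance_study",
    "filter_study",
    "screen_null_calibration",
    "recovery_seed_run",
    "recovery_study",
    "consensus_block_study",
    "dca_reference_check",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


# ---------------------------------------------------------------- recovery

PLANTED_BETA = 1.5
N_PLANTED = 5
N_NULL_PAIRS = 50


def recovery_conditions(seed: int, n_cohorts: int = 3) -> tuple[
    SimulationConfig, list[PairDefinition], set[tuple[str, str]]
]:
    """Study conditions for the end-to-end recovery benchmark.

    Five planted pairs (β = 1.5) on genes G00000..G00009 plus 50 null
    pairs on 100 further genes, pairwise gene-disjoint so the nulls carry
    no survival signal.  Cohorts of 150; baseline hazard 0.01 with uniform
    censoring on (0, 10) gives ~30% censoring under the planted hazards.
    """
    planted = tuple(
        PlantedPair(gene_name(2 * i), gene_name(2 * i + 1), PLANTED_BETA)
        for i in range(N_PLANTED)
    )
    nulls = [
        PairDefinition.canonical(gene_name(10 + 2 * i), gene_name(11 + 2 * i))
        for i in range(N_NULL_PAIRS)
    ]
    candidates = [
        PairDefinition.canonical(p.gene_a, p.gene_b) for p in planted
    ] + nulls
    cohorts = tuple((f"C{i}", 150) for i in range(n_cohorts))
    config = SimulationConfig(
        n_genes=10 + 2 * N_NULL_PAIRS,
        cohorts=cohorts,
        planted_pairs=planted,
        baseline_hazard=0.01,
        censor_max=10.0,
        seed=seed,
    )
    planted_set = {(p.gene_a, p.gene_b) for p in candidates[:N_PLANTED]}
    return config, candidates, planted_set


def _merged_training(data, candidates, kept):
    mats = [apply_pairs(expr, kept) for expr, _ in data[:2]]
    merged = PairMatrix(
        list(kept),
        mats[0].sample_ids + mats[1].sample_ids,
        np.concatenate([m.values for m in mats], axis=1),
    )
    clin = ClinicalTable(
        pd.concat([d[1].data[["time", "event"]] for d in data[:2]])
    )
    return merged, clin


def recovery_seed_run(
    seed: int,
    n_iter: int = 1000,
    min_freq: int = 50,
    horizon: float = 3.0,
) -> dict:
    """One seed of the end-to-end recovery study; returns recall, precision
    and the held-out log-rank p of the high/low split."""
    config, candidates, planted_set = recovery_conditions(seed)
    data = simulate(config)
    pms = {name: apply_pairs(expr, candidates)
           for (name, _), (expr, _) in zip(config.cohorts, data)}
    kept, _ = filter_invariant_pairs(
        {n: pms[n] for n, _ in config.cohorts[:2]}
    )
    merged, clin = _merged_training(data, candidates, kept)
    screened, _ = screen_pairs(merged, clin)
    robust = robust_lasso_select(
        merged.subset_pairs(screened), clin,
        n_iter=n_iter, min_freq=min_freq, seed=seed + 1,
    )
    model = forward_auroc_build(robust, merged.subset_pairs(screened), clin,
                                horizon)
    got = {tuple(sorted(p)) for p in model.pairs}
    hit = got & planted_set
    test_expr, test_clin = data[2]
    assignment = score_samples(model, apply_pairs(test_expr, candidates))
    if len(set(assignment.group)) < 2:
        holdout_p = 1.0
    else:
        _, holdout_p = log_rank(test_clin.time, test_clin.event,
                                assignment.group)
    return {
        "recall": len(hit) / len(planted_set),
        "precision": len(hit) / len(got),
        "holdout_logrank_p": float(holdout_p),
        "model_size": len(model.pairs),
        "n_screened": len(screened),
    }


def recovery_study(seed: int, n_seeds: int = 20, **kwargs) -> dict:
    runs = [recovery_seed_run(s, **kwargs) for s in _child_seeds(seed, n_seeds)]
    return {
        "mean_recall": float(np.mean([r["recall"] for r in runs])),
        "mean_precision": float(np.mean([r["precision"] for r in runs])),
        "max_holdout_logrank_p": float(max(r["holdout_logrank_p"] for r in runs)),
        "runs": runs,
    }


# -------------------------------------------------------------- invariance

DISTORTIONS = ("identity", ("affine", 2.5, 1.0), ("power", 0.3))


def pair_invariance_study(seed: int, n_seeds: int = 20) -> dict:
    """Count pair-matrix entries that change under monotone distortions."""
    mismatches = 0
    total = 0
    for s in _child_seeds(seed, n_seeds):
        config, candidates, _ = recovery_conditions(s, n_cohorts=1)
        reference = None
        for spec in DISTORTIONS:
            cfg = dataclasses.replace(config, batch_distortion={"C0": spec})
            expr, _ = simulate(cfg)[0]
            pm = apply_pairs(expr, candidates)
            if reference is None:
                reference = pm.values
                total += pm.values.size
            else:
                mismatches += int((pm.values != reference).sum())
    return {"mismatching_entries": mismatches, "entries_compared": total,
            "n_seeds": n_seeds}


# ------------------------------------------------------------------ filter

def filter_study(seed: int, threshold: float = 0.80) -> dict:
    """Minority-class bound and exhaustiveness of the invariance filter."""
    config, candidates, _ = recovery_conditions(seed)
    data = simulate(config)
    pms = {name: apply_pairs(expr, candidates)
           for (name, _), (expr, _) in zip(config.cohorts, data)}
    kept, excluded = filter_invariant_pairs(pms, threshold)
    kept_set, exc_set = set(kept), set(excluded)
    exhaustive = (kept_set | exc_set == set(candidates)) and not (kept_set & exc_set)
    minority = 1.0
    for pm in pms.values():
        sub = pm.subset_pairs(kept)
        ones = sub.values.sum(axis=1)
        n = sub.n_samples
        minority = min(minority, float(np.minimum(ones, n - ones).min()) / n)
    return {
        "min_minority_fraction": minority,
        "partition_exhaustive": bool(exhaustive),
        "n_kept": len(kept),
        "n_excluded": len(excluded),
    }


# ------------------------------------------------------------- calibration

def screen_null_calibration(
    seed: int, n_reps: int = 1000, n: int = 100, alpha: float = 0.05
) -> dict:
    """Fraction of truly null pairs the Cox screen keeps at ``alpha``."""
    kept = 0
    usable = 0
    for s in _child_seeds(seed, n_reps):
        config = SimulationConfig(
            n_genes=2,
            cohorts=(("N", n),),
            planted_pairs=(PlantedPair(gene_name(0), gene_name(1), 0.0),),
            baseline_hazard=0.1,
            censor_max=15.0,
            seed=s,
        )
        expr, clin = simulate(config)[0]
        pm = apply_pairs(expr, [PairDefinition.canonical(gene_name(0), gene_name(1))])
        kept_pairs, report = screen_pairs(pm, clin, alpha=alpha)
        if not report["degenerate"].iloc[0]:
            usable += 1
            kept += len(kept_pairs)
    return {"keep_fraction": kept / usable, "n_usable": usable, "n_reps": n_reps}


# --------------------------------------------------------------- consensus

def consensus_block_study(
    seed: int, n_per_block: int = 30, n_pairs: int = 40, flip: float = 0.05,
    n_resamples: int = 100,
) -> dict:
    """ARI of consensus clustering against two planted sample blocks."""
    rng = np.random.default_rng(seed)
    proto_a = rng.random(n_pairs) < 0.5
    proto_b = ~proto_a
    profiles = []
    truth = []
    for proto, label in ((proto_a, 0), (proto_b, 1)):
        for _ in range(n_per_block):
            noise = rng.random(n_pairs) < flip
            profiles.append(np.where(noise, ~proto, proto))
            truth.append(label)
    values = np.array(profiles, dtype=np.uint8).T
    pairs = [PairDefinition(gene_name(2 * i), gene_name(2 * i + 1))
             for i in range(n_pairs)]
    pm = PairMatrix(pairs, [f"S{i:03d}" for i in range(2 * n_per_block)], values)
    result = consensus_cluster(pm, k=2, n_resamples=n_resamples, seed=seed)
    ari = adjusted_rand_score(truth, result.label_array())
    return {"ari": float(ari), "n_samples": 2 * n_per_block}


# --------------------------------------------------------------------- DCA

def dca_reference_check(seed: int, n: int = 200) -> dict:
    """Max deviation of DCA reference policies from their closed forms."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.35).astype(int)
    prevalence = y.mean()
    pt = np.linspace(0.05, 0.95, 19)
    always_pos = decision_curve(np.ones(n), y, pt)
    always_neg = decision_curve(np.zeros(n), y, pt)
    closed_form = prevalence - (1 - prevalence) * pt / (1 - pt)
    return {
        "treat_all_max_abs_error": float(
            np.abs(always_pos.net_benefit - closed_form).max()
        ),
        "treat_none_max_abs": float(np.abs(always_neg.net_benefit).max()),
        "reference_consistency": float(
            np.abs(always_pos.treat_all - closed_form).max()
        ),
    }
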