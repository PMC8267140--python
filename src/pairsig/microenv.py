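"""Tumour-microenvironment characterisation downstream of the signature.

Marker-panel abundance scores (mean log-expression of a cell population's
markers), rank-based single-sample gene-set scores with immune/stromal
composites, differential-signature calls between risk groups, the
four-quadrant tumour-microenvironment immune typing on CD274 (PD-L1) and
CD8A, checkpoint-gene group comparisons, and score-vs-risk Spearman
correlations.

The single-sample set score is a documented rank statistic: genes are
ranked ascending within each sample (average ranks on ties) and a set's
score is the mean member rank rescaled to [-1, 1] —
``2 * (meanRank(S) - (G+1)/2) / (G-1)`` for G genes.  Being rank-based it
inherits the same per-sample monotone-transform invariance as the pair
indicators.  Marker lists are user-supplied GMTs throughout; no published
coefficient sets are bundled.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata, spearmanr
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "marker_abundance",
    "set_variation_score",
    "estimate_like_scores",
    "differential_signatures",
    "tmit_classify",
    "gene_group_comparison",
    "score_risk_correlation",
    "DEFAULT_CHECKPOINT_GENES",
]

#: Commonly assayed immune checkpoint genes; fully overridable by callers.
DEFAULT_CHECKPOINT_GENES = [
    "PDCD1", "CD274", "CTLA4", "LAG3", "HAVCR2", "TIGIT", "PDCD1LG2",
]


def marker_abundance(
    expr: ExpressionMatrix, markers: GeneSetCollection
) -> pd.DataFrame:
    """Mean log2-scale expression of each marker panel, per sample.

    ``expr`` is expected on a log2 scale.  Markers absent from the matrix
    are dropped with a log message; a panel with no present marker is an
    error.
    """
    rows = {}
    for name, genes in markers.sets.items():
        present = [g for g in genes if g in expr.data.index]
        absent = sorted(set(genes) - set(present))
        if not present:
            raise ValueError(f"marker set '{name}' has no gene present in the matrix")
        if absent:
            logger.info("marker set '%s': %d absent markers dropped: %s",
                        name, len(absent), absent)
        rows[name] = expr.data.loc[present].mean(axis=0)
    return pd.DataFrame(rows).T


def set_variation_score(
    expr: ExpressionMatrix, sets: GeneSetCollection
) -> pd.DataFrame:
    """Rank-based single-sample set score in [-1, 1] (sets x samples)."""
    G = expr.n_genes
    if G < 2:
        raise ValueError("need at least 2 genes")
    ranks = np.apply_along_axis(rankdata, 0, expr.values)  # ascending, ties=avg
    gene_loc = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = {}
    for name, genes in sets.sets.items():
        idx = [gene_loc[g] for g in genes if g in gene_loc]
        if not idx:
            raise ValueError(f"gene set '{name}' is disjoint from the matrix genes")
        mean_rank = ranks[idx].mean(axis=0)
        rows[name] = 2.0 * (mean_rank - (G + 1) / 2.0) / (G - 1)
    return pd.DataFrame(rows, index=expr.sample_ids).T


def estimate_like_scores(
    expr: ExpressionMatrix,
    immune_set: Sequence[str],
    stromal_set: Sequence[str],
) -> pd.DataFrame:
    """Per-sample immune, stromal and combined scores.

    Immune and stromal are the rank-based set scores of the two panels;
    the combined score is their sum (an index of overall non-tumour
    content, in the spirit of purity scores built from immune + stromal
    enrichment).
    """
    gsc = GeneSetCollection(sets={"immune": list(immune_set),
                                  "stromal": list(stromal_set)})
    scores = set_variation_score(expr, gsc)
    out = scores.T
    out["combined"] = out["immune"] + out["stromal"]
    return out


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0  # constant vector: no evidence, never flagged
    return float(mannwhitneyu(a, b, alternative="two-sided").pvalue)


def differential_signatures(
    scores: pd.DataFrame,
    groups: pd.Series,
    fc_threshold: float = 0.2,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Flag sets whose scores differ between two groups.

    ``scores`` is sets x samples; ``groups`` a binary per-sample label.
    The effect is the difference of group mean scores (set scores can be
    negative, so a ratio-based fold change is undefined); p-values are
    two-sided rank-sum tests, Benjamini–Hochberg adjusted across sets.
    A set is flagged iff |effect| > fc_threshold and adjusted p <
    p_threshold.
    """
    groups = groups.loc[scores.columns]
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    in_b = (groups == levels[1]).to_numpy()
    a = scores.loc[:, ~in_b].to_numpy()
    b = scores.loc[:, in_b].to_numpy()
    effect = b.mean(axis=1) - a.mean(axis=1)
    pvals = np.array([_ranksum_p(a[i], b[i]) for i in range(scores.shape[0])])
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "effect": effect,
        "p": pvals,
        "p_adj": padj,
        "flagged": (np.abs(effect) > fc_threshold) & (padj < p_threshold),
    }, index=scores.index)


def tmit_classify(
    expr: ExpressionMatrix,
    cd274_gene: str = "CD274",
    cd8a_gene: str = "CD8A",
    cutpoint: str | dict[str, float] = "median",
) -> pd.Series:
    """Four-quadrant tumour-microenvironment immune type per sample.

    Quadrants on (CD274 high/low) x (CD8A high/low): I = both high (the
    favourable-immunotherapy quadrant), II = CD274 high only, III = both
    low, IV = CD8A high only.  Values exactly at the cutpoint count as
    low.  ``cutpoint`` is per-gene: "median" or an explicit
    {gene: threshold} mapping.
    """
    for g in (cd274_gene, cd8a_gene):
        if g not in expr.data.index:
            raise KeyError(f"gene '{g}' not in expression matrix")
    cd274 = expr.data.loc[cd274_gene]
    cd8a = expr.data.loc[cd8a_gene]
    if cutpoint == "median":
        cut274, cut8a = float(cd274.median()), float(cd8a.median())
    else:
        cut274, cut8a = float(cutpoint[cd274_gene]), float(cutpoint[cd8a_gene])
    logger.info("TMIT cutpoints: %s=%g, %s=%g", cd274_gene, cut274,
                cd8a_gene, cut8a)
    hi274 = cd274 > cut274
    hi8a = cd8a > cut8a
    labels = np.select(
        [hi274 & hi8a, hi274 & ~hi8a, ~hi274 & hi8a],
        ["I", "II", "IV"],
        default="III",
    )
    return pd.Series(labels, index=expr.sample_ids, name="tmit")


def gene_group_comparison(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    groups: pd.Series,
) -> pd.DataFrame:
    """Per-gene two-group rank-sum comparison with BH adjustment and
    significance stars (*, **, *** at 0.05 / 0.01 / 0.001)."""
    missing = [g for g in genes if g not in expr.data.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    groups = groups.loc[expr.sample_ids]
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    in_b = (groups == levels[1]).to_numpy()
    rows = []
    for g in genes:
        vals = expr.data.loc[g].to_numpy(dtype=float)
        a, b = vals[~in_b], vals[in_b]
        rows.append({"gene": g, "effect": b.mean() - a.mean(),
                     "p": _ranksum_p(a, b)})
    out = pd.DataFrame(rows).set_index("gene")
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["stars"] = [
        "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
        for p in out["p_adj"]
    ]
    return out


def score_risk_correlation(
    scores: pd.DataFrame, risk: pd.Series
) -> pd.DataFrame:
    """Spearman correlation of each set score with the risk score."""
    common = [s for s in scores.columns if s in risk.index]
    if len(common) < 5:
        raise ValueError(f"need at least 5 aligned samples, got {len(common)}")
    r = risk.loc[common].to_numpy(dtype=float)
    rows = []
    for name in scores.index:
        v = scores.loc[name, common].to_numpy(dtype=float)
        if np.ptp(v) == 0 or np.ptp(r) == 0:
            rows.append({"set": name, "rho": np.nan, "p": np.nan,
                         "note": "constant vector"})
            continue
        rho, p = spearmanr(v, r)
        rows.append({"set": name, "rho": float(rho), "p": float(p), "note": ""})
    return pd.DataFrame(rows).set_index("set")
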