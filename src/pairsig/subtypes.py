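"""Consensus clustering of samples in prognostic-pair space.

Samples are clustered on their binary pair profiles by resampled
hierarchical clustering (Jaccard distance, average linkage by default);
the consensus matrix records how often two samples co-cluster among the
resamples where both were drawn, and the final labels come from cutting a
hierarchical tree built on 1 − consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from .io import ClinicalTable  # noqa: F401 - public signature type
from .pairs import PairMatrix
from .survival import SurvivalCurve, kaplan_meier, log_rank

logger = logging.getLogger(__name__)

__all__ = ["ConsensusResult", "consensus_cluster", "pac_score",
           "compare_subtype_survival"]


@dataclass
class ConsensusResult:
    k: int
    labels: pd.Series            # sample -> cluster id in 1..k
    consensus: pd.DataFrame      # samples x samples co-clustering frequency
    n_resamples: int

    def label_array(self) -> np.ndarray:
        return self.labels.to_numpy()


def _cluster_once(profiles: np.ndarray, k: int, metric: str, method: str
                  ) -> np.ndarray:
    dist = pdist(profiles, metric=metric)
    dist = np.nan_to_num(dist, nan=0.0)  # two all-zero profiles are identical
    Z = scipy_linkage(dist, method=method)
    return fcluster(Z, t=k, criterion="maxclust")


def consensus_cluster(
    pm: PairMatrix,
    k: int,
    n_resamples: int = 500,
    subsample_frac: float = 0.8,
    seed: int = 0,
    metric: str = "jaccard",
    method: str = "average",
) -> ConsensusResult:
    """Consensus clustering of the samples of ``pm`` into ``k`` subtypes."""
    if k < 2:
        raise ValueError("k must be at least 2")
    n = pm.n_samples
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2*k} samples, got {n}")
    profiles = pm.values.T.astype(bool)
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample_frac * n)))
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        labels = _cluster_once(profiles[idx], k, metric, method)
        same = labels[:, None] == labels[None, :]
        together[np.ix_(idx, idx)] += same
        sampled[np.ix_(idx, idx)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
    final = _final_labels(consensus, k, method)
    labels = pd.Series(final, index=pm.sample_ids, name="subtype")
    cons_df = pd.DataFrame(consensus, index=pm.sample_ids, columns=pm.sample_ids)
    return ConsensusResult(k=k, labels=labels, consensus=cons_df,
                           n_resamples=n_resamples)


def _final_labels(consensus: np.ndarray, k: int, method: str) -> np.ndarray:
    dist = squareform(1.0 - consensus, checks=False)
    Z = scipy_linkage(dist, method=method)
    return fcluster(Z, t=k, criterion="maxclust")


def pac_score(result: ConsensusResult, lower: float = 0.1, upper: float = 0.9
              ) -> float:
    """Proportion of ambiguous clustering: fraction of off-diagonal consensus
    entries strictly inside (lower, upper).  Lower is cleaner; a report to
    assist choosing k, never an automatic selector."""
    c = result.consensus.to_numpy()
    off = c[~np.eye(c.shape[0], dtype=bool)]
    return float(((off > lower) & (off < upper)).mean())


def compare_subtype_survival(
    labels: pd.Series, clin: ClinicalTable
) -> tuple[float, float, dict[int, SurvivalCurve]]:
    """Log-rank comparison plus per-subtype Kaplan–Meier curves."""
    aligned = clin.subset(list(labels.index))
    t = aligned.time.to_numpy()
    e = aligned.event.to_numpy()
    g = labels.to_numpy()
    stat, p = log_rank(t, e, g)
    curves = {
        int(lab): kaplan_meier(t[g == lab], e[g == lab])
        for lab in np.unique(g)
    }
    return stat, p, curves
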