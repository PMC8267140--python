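"""Decision-curve analysis, cohort summary tables and consolidated reports."""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ClinicalTable
from .signature import RiskAssignment
from .survival import harrell_c, kaplan_meier, log_rank, time_roc, _fit_cox

__all__ = [
    "NetBenefitCurve",
    "decision_curve",
    "risk_to_event_probability",
    "cohort_summary",
    "summary_to_text",
    "survival_comparison_report",
]


@dataclass
class NetBenefitCurve:
    """Net benefit of a classification rule across threshold probabilities.

    NB(pt) = TP/n − (FP/n) · pt/(1−pt), with a sample called positive iff
    its predicted probability is at least pt.  ``treat_all`` and
    ``treat_none`` are the two reference policies.
    """

    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pt": self.thresholds,
            "net_benefit": self.net_benefit,
            "treat_all": self.treat_all,
            "treat_none": self.treat_none,
        })


def decision_curve(predicted_prob, outcome, thresholds) -> NetBenefitCurve:
    p = np.asarray(predicted_prob, dtype=float)
    y = np.asarray(outcome, dtype=int)
    pt = np.asarray(thresholds, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome must be binary")
    if ((pt <= 0) | (pt >= 1)).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = y.size
    prevalence = y.mean()
    odds = pt / (1.0 - pt)
    positive = p[:, None] >= pt[None, :]
    tp = (positive & (y == 1)[:, None]).sum(axis=0) / n
    fp = (positive & (y == 0)[:, None]).sum(axis=0) / n
    nb = tp - fp * odds
    treat_all = prevalence - (1.0 - prevalence) * odds
    return NetBenefitCurve(pt, nb, treat_all, np.zeros_like(pt))


def risk_to_event_probability(
    score, clin: ClinicalTable, horizon: float
) -> np.ndarray:
    """Map risk scores to predicted event probabilities by ``horizon``.

    Fits a one-covariate Cox model of the score and returns
    ``1 − S0(horizon) ** exp(score − mean(score))`` from its baseline
    survival — the model-implied probability of failure by the horizon.
    """
    s = np.asarray(score, dtype=float)
    df = pd.DataFrame({
        "score": s,
        "time": clin.time.to_numpy(),
        "event": clin.event.to_numpy(),
    })
    cph = _fit_cox(df)
    base = cph.baseline_survival_
    idx = base.index.to_numpy(dtype=float)
    k = int(np.searchsorted(idx, horizon, side="right"))
    s0 = 1.0 if k == 0 else float(base.iloc[k - 1, 0])
    beta = float(cph.params_["score"])
    return 1.0 - s0 ** np.exp(beta * (s - s.mean()))


def _round_half_up(x: float, places: int = 1) -> float:
    q = decimal.Decimal(10) ** -places
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def cohort_summary(clin: ClinicalTable, variables: Sequence[str]) -> dict:
    """Per-variable category counts with percentages of cohort n.

    Percentages are rounded half-up to one decimal; missing values are
    counted as their own "Unknown" category.
    """
    n = len(clin.data)
    if n == 0:
        raise ValueError("empty cohort")
    out: dict[str, list[tuple[str, int, float]]] = {}
    for var in variables:
        if var not in clin.data.columns:
            raise KeyError(f"variable '{var}' not in clinical table")
        col = clin.data[var].astype(object).where(clin.data[var].notna(), "Unknown")
        counts = col.value_counts(dropna=False)
        out[var] = [
            (str(cat), int(cnt), _round_half_up(100.0 * cnt / n))
            for cat, cnt in sorted(counts.items(), key=lambda kv: str(kv[0]))
        ]
    return out


def summary_to_text(summary: dict, n: int) -> str:
    lines = [f"Cohort summary (n = {n})"]
    for var, cats in summary.items():
        lines.append(f"{var}, n (%)")
        for cat, cnt, pct in cats:
            lines.append(f"  {cat}\t{cnt}({pct})")
    return "\n".join(lines) + "\n"


def survival_comparison_report(
    assignment: RiskAssignment,
    clin: ClinicalTable,
    horizons: Sequence[float],
    cohort_name: str = "cohort",
) -> str:
    """Plain-text report: risk-group KM summary, log-rank p, time-dependent
    AUC at each horizon and the C-index of the score.  Deterministic for
    fixed inputs."""
    aligned = clin.subset(assignment.sample_ids)
    t = aligned.time.to_numpy()
    e = aligned.event.to_numpy()
    g = np.asarray(assignment.group)
    lines = [f"# Survival comparison — {cohort_name}",
             f"samples: {len(t)}, events: {int(e.sum())}"]
    groups = np.unique(g)
    for grp in groups:
        sel = g == grp
        curve = kaplan_meier(t[sel], e[sel])
        final = curve.survival[-1] if curve.times.size else 1.0
        lines.append(
            f"group {grp}: n={int(sel.sum())}, events={int(e[sel].sum())}, "
            f"final KM survival={final:.4f}"
        )
    if len(groups) >= 2:
        stat, p = log_rank(t, e, g)
        lines.append(f"log-rank: statistic={stat:.4f}, p={p:.4g}")
    else:
        lines.append("log-rank: skipped (single risk group)")
    for h in horizons:
        try:
            roc = time_roc(assignment.score, t, e, h)
            lines.append(f"time-dependent AUC at t={h}: {roc.auc:.4f}")
        except ValueError as exc:
            lines.append(f"time-dependent AUC at t={h}: unavailable ({exc})")
    lines.append(f"C-index of score: {harrell_c(assignment.score, t, e):.4f}")
    return "\n".join(lines) + "\n"
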