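"""Survival machinery shared by the pipeline stages.

Kaplan–Meier curves, log-rank tests and Cox proportional-hazards fits are
delegated to lifelines (Efron tie handling, Wald p-values); Harrell's
concordance index and the time-dependent ROC are implemented here because
their exact estimator semantics matter downstream:

* ``time_roc`` is the cumulative-case / dynamic-control estimator with
  inverse-probability-of-censoring weights from the Kaplan–Meier estimate
  of the censoring distribution — cases observed by the horizon are
  weighted 1/G(T−), controls are subjects still under observation past the
  horizon.  Without censoring before the horizon it reduces exactly to the
  empirical binary ROC.
* ``optimal_cutoff`` maximises Youden's J = TPR − FPR over the observed
  score thresholds, breaking ties toward the smaller threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from statsmodels.stats.multitest import multipletests

from .pairs import PairDefinition, PairMatrix
from .io import ClinicalTable

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCurve",
    "CoxScreenResult",
    "TimeROC",
    "kaplan_meier",
    "log_rank",
    "cox_univariate",
    "screen_pairs",
    "cox_multivariate",
    "harrell_c",
    "time_roc",
    "optimal_cutoff",
]


def _as_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival data")
    if t.shape != e.shape:
        raise ValueError("time and event have different lengths")
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicators must be 0/1")
    return t, e


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate, recorded at the distinct event times."""

    times: np.ndarray       # sorted distinct event times
    survival: np.ndarray    # S(t) at each event time (right-continuous)
    at_risk: np.ndarray     # number at risk just before each event time

    def at(self, t: float, left: bool = False) -> float:
        """Step-function value S(t); ``left`` gives the left limit S(t−)."""
        if left:
            k = int(np.searchsorted(self.times, t, side="left"))
        else:
            k = int(np.searchsorted(self.times, t, side="right"))
        return 1.0 if k == 0 else float(self.survival[k - 1])


def kaplan_meier(time, event) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimator (censored-only data stays at 1)."""
    t, e = _as_arrays(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(ev.index).to_numpy()
    at_risk = ev["at_risk"].to_numpy(dtype=int)
    return SurvivalCurve(times=times, survival=surv, at_risk=at_risk)


def log_rank(time, event, group) -> tuple[float, float]:
    """Two-sided log-rank chi-square test across >=2 groups."""
    t, e = _as_arrays(time, event)
    g = np.asarray(group)
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxScreenResult:
    """Univariate proportional-hazards fit of one pair indicator."""

    pair: PairDefinition | None
    log_hr: float
    se: float
    p_value: float
    degenerate: bool = False


def _fit_cox(df: pd.DataFrame, penalizer: float = 0.0) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=penalizer)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    return cph


def cox_univariate(covariate, time, event, pair: PairDefinition | None = None
                   ) -> CoxScreenResult:
    """Single-covariate Cox fit with Wald p-value.

    A constant covariate (or a fit that fails to converge, e.g. complete
    separation) yields ``degenerate=True`` rather than an exception;
    all-censored data is an error.
    """
    t, e = _as_arrays(time, event)
    x = np.asarray(covariate, dtype=float)
    if e.sum() < 1:
        raise ValueError("cannot fit a Cox model with zero events")
    if np.ptp(x) == 0:
        return CoxScreenResult(pair, np.nan, np.nan, np.nan, degenerate=True)
    df = pd.DataFrame({"x": x, "time": t, "event": e})
    try:
        cph = _fit_cox(df)
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return CoxScreenResult(pair, np.nan, np.nan, np.nan, degenerate=True)
    s = cph.summary.loc["x"]
    return CoxScreenResult(pair, float(s["coef"]), float(s["se(coef)"]),
                           float(s["p"]), degenerate=False)


def screen_pairs(
    pm: PairMatrix, clin: ClinicalTable, alpha: float = 0.05
) -> tuple[list[PairDefinition], pd.DataFrame]:
    """Univariate Cox screen over every pair at significance ``alpha``.

    Keeps pairs with a non-degenerate fit and unadjusted p < alpha (no
    multiplicity correction is applied to the selection, by design);
    Benjamini–Hochberg adjusted p-values are reported alongside for
    transparency only.
    """
    if set(pm.sample_ids) != set(clin.sample_ids):
        raise ValueError("pair matrix and clinical table sample ids do not match")
    aligned = clin.subset(pm.sample_ids)
    t, e = aligned.time.to_numpy(), aligned.event.to_numpy()
    rows = []
    for i, pair in enumerate(pm.pairs):
        res = cox_univariate(pm.values[i], t, e, pair=pair)
        rows.append({
            "pair": pair.label,
            "gene_a": pair.gene_a,
            "gene_b": pair.gene_b,
            "log_hr": res.log_hr,
            "se": res.se,
            "p": res.p_value,
            "degenerate": res.degenerate,
        })
    report = pd.DataFrame(rows).set_index("pair")
    ok = ~report["degenerate"]
    padj = np.full(len(report), np.nan)
    if ok.any():
        padj[ok.to_numpy()] = multipletests(report.loc[ok, "p"], method="fdr_bh")[1]
    report["p_adj_bh"] = padj
    report["kept"] = ok & (report["p"] < alpha)
    kept = [p for p, k in zip(pm.pairs, report["kept"]) if k]
    logger.info("screen: %d of %d pairs kept at alpha=%g", len(kept), pm.n_pairs, alpha)
    return kept, report


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    cols: list[str] = []
    kept: list[str] = []
    arr = X.to_numpy(dtype=float)
    arr = arr - arr.mean(axis=0)
    current = np.empty((arr.shape[0], 0))
    for j, name in enumerate(X.columns):
        cand = np.column_stack([current, arr[:, j]])
        if np.linalg.matrix_rank(cand) > current.shape[1]:
            current = cand
            kept.append(name)
        else:
            cols.append(name)
    return cols


def cox_multivariate(design: pd.DataFrame, time, event) -> pd.DataFrame:
    """Joint Cox fit; returns per-covariate log HR, 95% CI and Wald p.

    Constant columns are dropped with a warning; a rank-deficient design is
    an error naming the collinear columns.
    """
    t, e = _as_arrays(time, event)
    X = design.copy()
    const = [c for c in X.columns if np.ptp(X[c].to_numpy(dtype=float)) == 0]
    if const:
        logger.warning("dropping constant covariates: %s", const)
        X = X.drop(columns=const)
    if X.shape[1] == 0:
        raise ValueError("no non-degenerate covariates left")
    collinear = _collinear_columns(X)
    if collinear:
        raise ValueError(f"collinear covariate columns: {collinear}")
    df = X.astype(float).copy()
    df["time"] = t
    df["event"] = e
    cph = _fit_cox(df)
    s = cph.summary
    return pd.DataFrame({
        "log_hr": s["coef"],
        "se": s["se(coef)"],
        "ci_lower": s["coef lower 95%"],
        "ci_upper": s["coef upper 95%"],
        "p": s["p"],
    })


def harrell_c(risk, time, event) -> float:
    """Harrell's concordance index of a risk score (higher risk = earlier failure).

    Ties in risk among comparable pairs count 1/2; censored subjects are
    usable only as the later member of a pair.
    """
    t, e = _as_arrays(time, event)
    r = np.asarray(risk, dtype=float)
    if not e.any():
        raise ValueError("concordance undefined: no events, hence no usable pairs")
    try:
        return float(_lifelines_cindex(t, -r, e))
    except ZeroDivisionError as exc:
        raise ValueError("concordance undefined: no usable pairs") from exc


@dataclass
class TimeROC:
    """Cumulative/dynamic time-dependent ROC at one horizon."""

    horizon: float
    thresholds: np.ndarray  # ascending unique score values
    tpr: np.ndarray         # P(score > c | case), IPCW-weighted
    fpr: np.ndarray         # P(score > c | control)
    auc: float

    def youden(self) -> np.ndarray:
        return self.tpr - self.fpr


def time_roc(risk, time, event, horizon: float) -> TimeROC:
    """Time-dependent ROC of ``risk`` for the event "failure by ``horizon``".

    Cases are subjects with an observed event at or before the horizon,
    weighted by 1/G(T−) where G is the Kaplan–Meier estimate of the
    censoring survival function; controls are subjects observed beyond the
    horizon.  AUC is the trapezoid area under the resulting step curve.
    """
    t, e = _as_arrays(time, event)
    r = np.asarray(risk, dtype=float)
    if not (t.min() <= horizon <= t.max()):
        raise ValueError(f"horizon {horizon} outside observed time range "
                         f"[{t.min()}, {t.max()}]")
    case = (t <= horizon) & (e == 1)
    control = t > horizon
    if not case.any():
        raise ValueError(f"no cases (events by t={horizon})")
    if not control.any():
        raise ValueError(f"no controls (subjects observed beyond t={horizon})")

    cens_curve = kaplan_meier(t, 1 - e)
    w = np.zeros(t.size)
    g_left = np.array([cens_curve.at(ti, left=True) for ti in t[case]])
    if (g_left <= 0).any():
        raise ValueError("zero censoring-survival weight for an observed case")
    w[case] = 1.0 / g_left

    thresholds = np.unique(r)
    pos = r[:, None] > thresholds[None, :]          # n x m: score strictly above c
    w_case_total = w[case].sum()
    tpr = (w[case, None] * pos[case]).sum(axis=0) / w_case_total
    fpr = pos[control].sum(axis=0) / control.sum()

    # prepend the all-positive point (threshold below min score) -> (1, 1);
    # the largest threshold gives (0, 0): fpr runs 1 -> 0, use -trapezoid
    fpr_curve = np.concatenate([[1.0], fpr])
    tpr_curve = np.concatenate([[1.0], tpr])
    auc = float(-np.trapezoid(tpr_curve, fpr_curve))
    return TimeROC(horizon=float(horizon), thresholds=thresholds,
                   tpr=tpr, fpr=fpr, auc=auc)


def optimal_cutoff(roc: TimeROC) -> float:
    """Youden-optimal score threshold; ties resolved toward the smaller value."""
    j = roc.youden()
    if np.ptp(j) == 0:
        logger.warning("all thresholds give equal Youden J; returning the smallest")
        return float(roc.thresholds[0])
    return float(roc.thresholds[int(np.argmax(j))])


def roc_to_frame(roc: TimeROC) -> pd.DataFrame:
    return pd.DataFrame({
        "threshold": roc.thresholds, "tpr": roc.tpr, "fpr": roc.fpr,
    })
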