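"""Signature construction: frequency-robust LASSO, forward AUROC build,
risk scoring and stratified evaluation.

The selection cascade works on a screened pair matrix:

1. ``robust_lasso_select`` repeatedly subsamples the cohort, fits an
   L1-penalised Cox model (penalty chosen per iteration by cross-validated
   partial likelihood) and counts how often each pair enters the active
   set; pairs selected in strictly more than ``min_freq`` of ``n_iter``
   iterations are "robust".
2. ``forward_auroc_build`` walks the frequency-ordered robust list,
   fitting an unpenalised multivariate Cox model on each prefix and
   scoring its linear predictor by time-dependent AUC at a fixed horizon;
   the first prefix attaining the maximum AUC becomes the signature, and
   its risk cutoff is the Youden-optimal threshold of that model's ROC.
3. ``score_samples`` applies the signature (score = sum of coefficient
   times pair indicator) and splits samples into high risk (score strictly
   above the cutoff) and low risk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .io import ClinicalTable, SignatureModel
from .pairs import PairDefinition, PairMatrix
from .survival import (
    cox_univariate,
    kaplan_meier,
    log_rank,
    optimal_cutoff,
    time_roc,
    _fit_cox,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RobustPairReport",
    "RiskAssignment",
    "robust_lasso_select",
    "forward_auroc_build",
    "score_samples",
    "stratified_analysis",
    "crossed_risk_analysis",
]


@dataclass
class RobustPairReport:
    pair: PairDefinition
    frequency: int
    n_iter: int
    univariate_p: float

    @property
    def robust(self) -> bool:
        # strict ">": a pair appearing exactly min_freq times is not robust
        return self.frequency > self._min_freq

    _min_freq: int = 0


def _partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of fixed linear predictors."""
    order = np.argsort(time, kind="stable")
    t, e, x = time[order], event[order], lp[order]
    # suffix log-sum-exp of x (risk set = everyone with time >= t_i)
    rev = np.logaddexp.accumulate(x[::-1])[::-1]
    # for tied times the risk set starts at the first tied index
    first = np.searchsorted(t, t, side="left")
    ll = x[e == 1] - rev[first[e == 1]]
    return float(ll.sum())


def _cv_coxnet_select(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    rng: np.random.Generator,
    n_folds: int = 3,
    n_alphas: int = 25,
) -> np.ndarray | None:
    """One L1-Cox fit with the penalty chosen by CV partial likelihood.

    Returns the boolean active-set mask at the selected penalty, or None if
    the iteration is unusable (too few events, numerical failure).
    """
    if event.sum() < n_folds:
        return None
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            path = CoxnetSurvivalAnalysis(
                l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.05
            )
            path.fit(X, y)
    except (ArithmeticError, ValueError):
        return None
    alphas = np.asarray(path.alphas_)
    cv_ll = np.zeros(alphas.size)
    cv_n = np.zeros(alphas.size)
    kf = KFold(n_splits=n_folds, shuffle=True,
               random_state=int(rng.integers(2**31 - 1)))
    for train, test in kf.split(X):
        if event[train].sum() < 1 or event[test].sum() < 1:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fold = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
                fold.fit(X[train], y[train])
        except (ArithmeticError, ValueError):
            continue
        fitted = np.asarray(fold.alphas_)
        coefs = fold.coef_  # (n_features, n_fitted_alphas)
        for k, a in enumerate(alphas):
            hit = np.flatnonzero(np.isclose(fitted, a))
            if hit.size == 0:
                continue
            lp = X[test] @ coefs[:, hit[0]]
            cv_ll[k] += _partial_loglik(lp, time[test], event[test])
            cv_n[k] += 1
    usable = cv_n > 0
    if not usable.any():
        return None
    mean_ll = np.where(usable, cv_ll / np.maximum(cv_n, 1), -np.inf)
    best = int(np.argmax(mean_ll))
    coef = path.coef_[:, best]
    return coef != 0


def robust_lasso_select(
    pm: PairMatrix,
    clin: ClinicalTable,
    n_iter: int = 1000,
    min_freq: int = 50,
    subsample_frac: float = 0.8,
    bootstrap: bool = False,
    seed: int = 0,
) -> list[RobustPairReport]:
    """Selection-frequency report over ``n_iter`` resampled L1-Cox fits.

    Each iteration resamples ``subsample_frac`` of the samples (without
    replacement by default; with replacement if ``bootstrap``), fits the
    penalised model and records the active pairs.  The returned list covers
    every pair, sorted by frequency descending with ties broken by
    univariate p ascending; ``report.robust`` is True iff
    frequency > ``min_freq``.
    """
    if pm.n_pairs < 2:
        raise ValueError("need at least 2 candidate pairs")
    aligned = clin.subset(pm.sample_ids)
    t = aligned.time.to_numpy()
    e = aligned.event.to_numpy()
    if e.sum() < 10:
        raise ValueError(f"need at least 10 events, got {int(e.sum())}")
    X_full = pm.values.T.astype(float)
    n = X_full.shape[0]
    m = max(2, int(round(subsample_frac * n)))
    rng = np.random.default_rng(seed)
    freq = np.zeros(pm.n_pairs, dtype=int)
    n_failed = 0
    for _ in range(n_iter):
        idx = (rng.integers(0, n, size=m) if bootstrap
               else rng.choice(n, size=m, replace=False))
        mask = _cv_coxnet_select(X_full[idx], t[idx], e[idx], rng)
        if mask is None:
            n_failed += 1
            continue
        freq += mask
    if n_failed:
        logger.warning("%d of %d LASSO iterations unusable", n_failed, n_iter)
    uni_p = np.array([
        cox_univariate(pm.values[i], t, e).p_value for i in range(pm.n_pairs)
    ])
    reports = [
        RobustPairReport(pair=p, frequency=int(f), n_iter=n_iter,
                         univariate_p=float(up), _min_freq=min_freq)
        for p, f, up in zip(pm.pairs, freq, uni_p)
    ]
    reports.sort(key=lambda r: (-r.frequency,
                                r.univariate_p if np.isfinite(r.univariate_p) else np.inf))
    logger.info("robust selection: %d of %d pairs with frequency > %d",
                sum(r.robust for r in reports), pm.n_pairs, min_freq)
    return reports


def forward_auroc_build(
    robust: list[RobustPairReport],
    pm: PairMatrix,
    clin: ClinicalTable,
    horizon: float,
) -> SignatureModel:
    """Sequential prefix search over the frequency-ordered robust pairs.

    Prefix j uses the first j robust pairs; the prefix whose multivariate
    Cox linear predictor first attains the maximum time-dependent AUC at
    ``horizon`` becomes the model.  Coefficients are that unpenalised
    fit's; the cutoff is the Youden optimum of the winning model's ROC.
    """
    candidates = [r.pair for r in robust if r.robust]
    if not candidates:
        raise ValueError("no robust pairs to build from")
    aligned = clin.subset(pm.sample_ids)
    t = aligned.time.to_numpy()
    e = aligned.event.to_numpy()
    sub = pm.subset_pairs(candidates)
    X = sub.values.T.astype(float)

    trace: list[dict] = []
    fits: dict[int, tuple[np.ndarray, object]] = {}
    for j in range(1, len(candidates) + 1):
        cols = [p.label for p in candidates[:j]]
        df = pd.DataFrame(X[:, :j], columns=cols)
        if any(np.ptp(df[c]) == 0 for c in cols):
            logger.warning("prefix %d skipped: constant pair column", j)
            continue
        df["time"], df["event"] = t, e
        try:
            cph = _fit_cox(df)
        except Exception as exc:  # degenerate fit at this prefix
            logger.warning("prefix %d skipped: %s", j, exc)
            continue
        coefs = cph.params_[cols].to_numpy()
        lp = X[:, :j] @ coefs
        roc = time_roc(lp, t, e, horizon)
        trace.append({"prefix": j, "auc": roc.auc})
        fits[j] = (coefs, roc)
    if not trace:
        raise ValueError("every candidate prefix produced a degenerate fit")
    aucs = [row["auc"] for row in trace]
    best_j = trace[int(np.argmax(aucs))]["prefix"]  # argmax takes first maximum
    coefs, roc = fits[best_j]
    cutoff = optimal_cutoff(roc)
    model = SignatureModel(
        pairs=[tuple(p) for p in candidates[:best_j]],
        coefficients=list(coefs),
        auroc_horizon=float(horizon),
        cutoff=float(cutoff),
        provenance={
            "n_candidates": len(candidates),
            "winning_prefix": best_j,
            "winning_auc": float(max(aucs)),
            "auc_trace": trace,
            "cutoff_rule": "youden",
        },
    )
    return model


@dataclass
class RiskAssignment:
    """Per-sample risk score and high/low group call."""

    sample_ids: list[str]
    score: np.ndarray
    group: list[str]  # "high" iff score > cutoff else "low"
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.score, "group": self.group},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


def score_samples(model: SignatureModel, pm: PairMatrix) -> RiskAssignment:
    """Apply a signature to a pair matrix (all model pairs must be present)."""
    pairs = [PairDefinition(*p) for p in model.pairs]
    sub = pm.subset_pairs(pairs)  # KeyError naming any missing pair
    score = np.asarray(model.coefficients) @ sub.values.astype(float)
    group = ["high" if s > model.cutoff else "low" for s in score]
    return RiskAssignment(list(pm.sample_ids), score, group, float(model.cutoff))


def stratified_analysis(
    assignment: RiskAssignment, clin: ClinicalTable, strata: str
) -> pd.DataFrame:
    """Per-stratum Kaplan–Meier / log-rank comparison of the risk groups.

    Strata where only one risk group is present are skipped with a warning
    (statistic and p reported as NaN).
    """
    aligned = clin.subset(assignment.sample_ids)
    if strata not in aligned.data.columns:
        raise KeyError(f"stratum column '{strata}' not in clinical table")
    df = assignment.to_frame()
    df["time"] = aligned.time
    df["event"] = aligned.event
    df["stratum"] = aligned.data[strata].to_numpy()
    rows = []
    for value, part in df.groupby("stratum", sort=True):
        groups = part["group"].unique()
        if len(groups) < 2:
            logger.warning("stratum %s=%r has a single risk group; skipped",
                           strata, value)
            rows.append({"stratum": value, "n": len(part),
                         "statistic": np.nan, "p": np.nan, "skipped": True})
            continue
        stat, p = log_rank(part["time"], part["event"], part["group"])
        rows.append({"stratum": value, "n": len(part),
                     "statistic": stat, "p": p, "skipped": False})
    return pd.DataFrame(rows).set_index("stratum")


def crossed_risk_analysis(
    assignment: RiskAssignment, clin: ClinicalTable, covariate: str
) -> tuple[pd.Series, pd.DataFrame]:
    """Cross risk group with a binary covariate (e.g. metastasis) and run all
    pairwise log-rank tests among the resulting groups."""
    aligned = clin.subset(assignment.sample_ids)
    if covariate not in aligned.data.columns:
        raise KeyError(f"covariate '{covariate}' not in clinical table")
    cov = aligned.data[covariate].astype(str)
    labels = pd.Series(
        [f"{covariate}={c}/risk={g}" for c, g in zip(cov, assignment.group)],
        index=aligned.data.index, name="cross_group",
    )
    df = pd.DataFrame({"time": aligned.time, "event": aligned.event,
                       "label": labels})
    uniq = sorted(df["label"].unique())
    rows = []
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            part = df[df["label"].isin([a, b])]
            stat, p = log_rank(part["time"], part["event"], part["label"])
            rows.append({"group_a": a, "group_b": b, "statistic": stat, "p": p})
    return labels, pd.DataFrame(rows)
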