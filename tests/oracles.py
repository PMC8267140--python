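"""Independent brute-force oracles for the survival estimators.

Deliberately naive implementations (explicit loops, direct formulas) kept
separate from the package so they can serve as a second route in tests of
Kaplan-Meier, the log-rank statistic, Harrell's C, the IPCW time-dependent
ROC and the Youden cutoff.
"""

from __future__ import annotations

import math

import numpy as np


def km_survival(times, events, t_query):
    """Product-limit estimate S(t_query) by direct product over event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    for t in sorted(set(times[events == 1])):
        if t > t_query:
            break
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
    return s


def logrank_two_group(times, events, groups):
    """Two-group log-rank chi-square via the O-E / V formula, one event time
    at a time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert len(labels) == 2
    g1 = groups == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        n = int((times >= t).sum())
        n1 = int((times[g1] >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times[g1] == t) & (events[g1] == 1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    from scipy.stats import chi2 as chi2_dist

    return chi2, float(chi2_dist.sf(chi2, df=1))


def harrell_c(risk, times, events):
    """Concordance by pair enumeration: usable pairs have the earlier member
    observed to fail; risk ties count 1/2."""
    risk = np.asarray(risk, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    n = len(risk)
    num = 0.0
    den = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1.0
                elif risk[i] == risk[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no usable pairs")
    return num / den


def ipcw_time_roc(risk, times, events, horizon):
    """Direct evaluation of the cumulative/dynamic IPCW ROC.

    Cases: observed events at or before the horizon, weighted by the
    reciprocal of the censoring-survival left limit at their event time;
    controls: observed past the horizon, unweighted.  Returns
    (thresholds, tpr, fpr, auc) with trapezoid AUC including the virtual
    all-positive endpoint.
    """
    risk = np.asarray(risk, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)

    def censor_surv_left(t):
        # KM of the censoring distribution, left limit at t
        s = 1.0
        for tc in sorted(set(times[events == 0])):
            if tc >= t:
                break
            at_risk = int((times >= tc).sum())
            d = int(((times == tc) & (events == 0)).sum())
            s *= 1.0 - d / at_risk
        return s

    cases = [i for i in range(len(risk)) if times[i] <= horizon and events[i] == 1]
    controls = [i for i in range(len(risk)) if times[i] > horizon]
    w = {i: 1.0 / censor_surv_left(times[i]) for i in cases}
    thresholds = sorted(set(risk))
    tpr, fpr = [], []
    wtot = sum(w.values())
    for c in thresholds:
        tpr.append(sum(w[i] for i in cases if risk[i] > c) / wtot)
        fpr.append(sum(1 for j in controls if risk[j] > c) / len(controls))
    xs = [1.0] + fpr
    ys = [1.0] + tpr
    auc = 0.0
    for k in range(1, len(xs)):
        auc += (xs[k - 1] - xs[k]) * (ys[k - 1] + ys[k]) / 2.0
    return np.array(thresholds), np.array(tpr), np.array(fpr), auc


def youden_scan(thresholds, tpr, fpr):
    """Exhaustive argmax of J = tpr - fpr, smallest threshold on ties."""
    best_j = -math.inf
    best_c = None
    for c, t, f in zip(thresholds, tpr, fpr):
        j = t - f
        if j > best_j:
            best_j, best_c = j, c
    return best_c


def net_benefit(prob, outcome, pt):
    prob = np.asarray(prob, float)
    outcome = np.asarray(outcome, int)
    n = len(prob)
    tp = sum(1 for p, y in zip(prob, outcome) if p >= pt and y == 1)
    fp = sum(1 for p, y in zip(prob, outcome) if p >= pt and y == 0)
    return tp / n - (fp / n) * pt / (1 - pt)
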