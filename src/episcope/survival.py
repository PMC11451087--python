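"""Survival and discrimination evaluation: ROC/AUC, Kaplan–Meier, log-rank,
and Table-1-style cohort comparisons.

AUC is computed through its rank-sum identity, AUC = U / (n_pos * n_neg)
with midrank tie handling, and its significance (AUC != 0.5) from the
Mann–Whitney normal approximation with tie correction. Kaplan–Meier curves
use the product-limit estimator (via lifelines); the log-rank test is the
Mantel–Haenszel observed-minus-expected statistic with hypergeometric
variance at each event time, which keeps per-group observed/expected
counts available for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import CohortTable
from .stats import fisher_exact_2x2, mann_whitney_u, welch_t

__all__ = [
    "ROCResult",
    "KMCurve",
    "LogRankResult",
    "roc_auc",
    "km_curve",
    "logrank_test",
    "compare_groups",
    "clinical_score_benchmark",
    "SCORE_DIRECTIONS",
]

#: +1 if a higher score indicates the positive class (death / failure),
#: -1 if higher is protective (the SAVE score estimates survival chances)
SCORE_DIRECTIONS = {"apache2": +1, "lods": +1, "mods": +1, "sofa": +1, "save_score": -1}


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    p_value: float
    n_pos: int
    n_neg: int
    direction: int = +1  # sign applied to the scores before evaluation


@dataclass
class KMCurve:
    times: np.ndarray  # distinct observed times (events and censorings)
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    survival: np.ndarray  # S(t) just after each time


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]
    df: int = 1


def roc_auc(scores, labels, *, direction: int = +1) -> ROCResult:
    """ROC curve and AUC with a rank-sum significance test.

    ``direction=-1`` flips the score orientation first (for clinical scores
    where a higher value predicts survival rather than death); the output
    records the direction used.
    """
    scores = np.asarray(scores, dtype=float) * direction
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")

    res = mann_whitney_u(scores[labels == 1], scores[labels == 0], method="approx")
    auc = float(res.statistic) / (n_pos * n_neg)

    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(
        fpr=fpr, tpr=tpr, thresholds=thr, auc=auc, p_value=res.p_two_sided,
        n_pos=n_pos, n_neg=n_neg, direction=direction,
    )


def km_curve(times, events) -> KMCurve:
    """Product-limit survival estimate.

    Samples censored at an event time are counted at risk for that time
    (the standard convention). Times must be positive.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape:
        raise ValueError("times and events must have the same length")
    if np.any(times <= 0):
        raise ValueError("times must be positive")

    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
    ts = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(ts).to_numpy(dtype=float)
    return KMCurve(
        times=ts,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        censored=table["censored"].to_numpy(dtype=int),
        survival=surv,
    )


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group Mantel–Haenszel log-rank test (1 df)."""
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if not (ea.any() or eb.any()):
        raise ValueError("log-rank test undefined: no events in either group")

    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o1 = e1 = o2 = e2 = v = 0.0
    for t in event_times:
        n1 = float(np.sum(ta >= t))
        n2 = float(np.sum(tb >= t))
        d1 = float(np.sum(ea & (ta == t)))
        d2 = float(np.sum(eb & (tb == t)))
        n, d = n1 + n2, d1 + d2
        if n == 0:
            continue
        o1 += d1
        o2 += d2
        e1 += d * n1 / n
        e2 += d * n2 / n
        if n > 1:
            v += d * (n - d) * n1 * n2 / (n**2 * (n - 1))
    if v <= 0:
        return LogRankResult(0.0, 1.0, (o1, o2), (e1, e2))
    chi = (o1 - e1) ** 2 / v
    p = float(_sps.chi2.sf(chi, 1))
    return LogRankResult(float(chi), p, (o1, o2), (e1, e2))


def _fmt_median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}, {q3:.1f})"


def compare_groups(
    cohort: CohortTable,
    grouping: str = "outcome",
    *,
    variables=None,
) -> pd.DataFrame:
    """Table-1-style comparison of covariates between the two outcome groups.

    Binary covariates are tested with Fisher's exact test on the 2x2 table;
    continuous ones with Welch's t test (summarized as median (IQR)).
    Multi-level categoricals are reported descriptively without a p-value
    unless collapsed beforehand; constant covariates are flagged
    non-testable rather than raising.
    """
    df = cohort.data
    if grouping not in ("outcome", "early_outcome"):
        raise ValueError("grouping must be 'outcome' or 'early_outcome'")
    pos_level = "non_survivor" if grouping == "outcome" else "failure"
    g_pos = df[grouping] == pos_level
    variables = list(variables) if variables is not None else list(cohort.covariates)

    rows = []
    for var in variables:
        col = df[var]
        entry = {"variable": var, "test": "", "p_value": float("nan")}
        uniq = col.dropna().unique()
        if len(uniq) <= 1:
            entry["test"] = "not_testable"
            entry["summary_all"] = str(uniq[0]) if len(uniq) else ""
        elif pd.api.types.is_numeric_dtype(col) and len(uniq) > 2:
            a = col[~g_pos].to_numpy(dtype=float)
            b = col[g_pos].to_numpy(dtype=float)
            res = welch_t(a, b)
            entry.update(
                test="welch_t",
                p_value=res.p_two_sided,
                summary_all=_fmt_median_iqr(col.to_numpy(dtype=float)),
                summary_neg=_fmt_median_iqr(a),
                summary_pos=_fmt_median_iqr(b),
            )
        elif len(uniq) == 2:
            levels = sorted(uniq, key=str)
            yes = levels[-1]  # report the lexically last level as "positive"
            a = int(((col == yes) & ~g_pos).sum())
            b = int(((col != yes) & ~g_pos).sum())
            c = int(((col == yes) & g_pos).sum())
            d = int(((col != yes) & g_pos).sum())
            res = fisher_exact_2x2(a, b, c, d)
            entry.update(
                test="fisher_exact",
                p_value=res.p_two_sided,
                summary_all=f"{a + c}/{len(col)}",
                summary_neg=f"{a}/{a + b}",
                summary_pos=f"{c}/{c + d}",
            )
        else:
            entry["test"] = "descriptive"
            entry["summary_all"] = "; ".join(
                f"{lv}:{int((col == lv).sum())}" for lv in sorted(map(str, uniq))
            )
        rows.append(entry)
    return pd.DataFrame(rows)


def clinical_score_benchmark(
    cohort: CohortTable, endpoint: str = "early_outcome"
) -> dict[str, ROCResult]:
    """ROC/AUC of each clinical score against the chosen endpoint.

    Scores with an inverted orientation (higher SAVE = better survival)
    are flipped via ``SCORE_DIRECTIONS``. All-missing scores are skipped
    with a warning.
    """
    if endpoint == "outcome":
        labels = cohort.outcome_vector()
    elif endpoint == "early_outcome":
        labels = cohort.early_outcome_vector()
    else:
        raise ValueError("endpoint must be 'outcome' or 'early_outcome'")

    results: dict[str, ROCResult] = {}
    for score, direction in SCORE_DIRECTIONS.items():
        vals = cohort.data[score].to_numpy(dtype=float)
        if np.isnan(vals).all():
            warnings.warn(f"score {score!r} entirely missing; skipped", stacklevel=2)
            continue
        ok = ~np.isnan(vals)
        results[score] = roc_auc(vals[ok], labels[ok], direction=direction)
    return results
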