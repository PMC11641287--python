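"""Kaplan-Meier estimation, log-rank testing and survival-direction calls.

Candidate miRNAs are dichotomized at the median of their expression in an
independent survival cohort; the two strata are compared with the standard
log-rank test (hypergeometric variance, no continuity correction, 1 df
chi-square).  A candidate passes the survival filter only when the stratum
with worse survival matches its tumor-vs-normal direction: an upregulated
miRNA must have worse survival in its high-expression stratum, and a
downregulated one in its low-expression stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SurvivalTable


@dataclass
class KMCurve:
    """Product-limit survival curve at the distinct event times."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray     # n_i at each event time
    events: np.ndarray      # d_i at each event time


@dataclass
class LogRankResult:
    mirna_id: str
    chi2: float
    p_value: float
    worse_group: str        # "high" or "low"
    n_high: int
    n_low: int
    median_cut: float
    defined: bool = True    # False when no events exist at all


@dataclass
class ConcordanceCall:
    mirna_id: str
    mirna_direction: str
    survival_pass: bool
    reason: str
    logrank: LogRankResult | None = None


def km_estimator(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored-only times shrink the risk set but contribute no step; the
    curve is reported at distinct event times only.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if np.any(times <= 0):
        raise ValueError("survival times must be strictly positive")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    surv, at_risk, d_counts = [], [], []
    s = 1.0
    for t in event_times:
        n_i = int(np.sum(times >= t))
        d_i = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        d_counts.append(d_i)
    return KMCurve(
        times=event_times,
        survival=np.array(surv),
        at_risk=np.array(at_risk),
        events=np.array(d_counts),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test: (chi2 with 1 df, upper-tail p).

    Observed-minus-expected events in group A summed over distinct event
    times, with the usual hypergeometric variance.  With zero events
    overall the statistic is undefined and ``(nan, nan)`` is returned.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("each group needs at least one subject")
    all_event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    if all_event_times.size == 0:
        return float("nan"), float("nan")
    o_minus_e = 0.0
    var = 0.0
    for t in all_event_times:
        n1 = int(np.sum(ta >= t))
        n2 = int(np.sum(tb >= t))
        d1 = int(np.sum((ta == t) & (ea == 1)))
        d2 = int(np.sum((tb == t) & (eb == 1)))
        n = n1 + n2
        d = d1 + d2
        if n < 2 or n1 == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def median_split(values: pd.Series) -> pd.Series:
    """Assign samples to expression strata: strictly above the median ->
    ``high``, at or below -> ``low``."""
    values = pd.Series(values).astype(float)
    if len(values) < 4:
        raise ValueError("median split needs at least 4 samples")
    if values.nunique() == 1:
        raise ValueError("all expression values identical; no split possible")
    cut = float(values.median())
    return pd.Series(np.where(values > cut, "high", "low"), index=values.index)


def survival_concordance(
    mirna_id: str,
    mirna_de: pd.DataFrame,
    survival: SurvivalTable,
    alpha_surv: float = 0.06,
) -> ConcordanceCall:
    """Median-split + log-rank + direction rule for one candidate miRNA.

    Passes only when the log-rank p is <= ``alpha_surv`` and the worse
    stratum matches the differential-expression direction (up -> high
    expression worse; down -> low expression worse).
    """
    if mirna_id not in mirna_de.index:
        return ConcordanceCall(mirna_id, "ns", False, "no differential-expression result")
    direction = mirna_de.loc[mirna_id, "direction"]
    if direction == "ns":
        return ConcordanceCall(mirna_id, direction, False, "not differentially expressed")
    if mirna_id not in survival.expression.columns:
        return ConcordanceCall(mirna_id, direction, False, "no survival data")
    expr = survival.expression[mirna_id]
    try:
        strata = median_split(expr)
    except ValueError as exc:
        return ConcordanceCall(mirna_id, direction, False, str(exc))
    hi = strata == "high"
    result = _logrank_with_direction(
        mirna_id,
        survival.time[hi], survival.event[hi],
        survival.time[~hi], survival.event[~hi],
        median_cut=float(expr.median()),
    )
    if not result.defined:
        return ConcordanceCall(mirna_id, direction, False, "no events in cohort", result)
    ok = result.p_value <= alpha_surv and (
        (direction == "up" and result.worse_group == "high")
        or (direction == "down" and result.worse_group == "low")
    )
    if ok:
        reason = "worse survival in the %s-expression stratum (p=%.3g)" % (
            result.worse_group, result.p_value)
    elif result.p_value > alpha_surv:
        reason = f"log-rank p={result.p_value:.3g} above alpha={alpha_surv}"
    else:
        reason = (
            f"direction mismatch: miRNA {direction} but worse survival in the "
            f"{result.worse_group}-expression stratum"
        )
    return ConcordanceCall(mirna_id, direction, bool(ok), reason, result)


def _logrank_with_direction(
    mirna_id, times_high, events_high, times_low, events_low, median_cut
) -> LogRankResult:
    chi2, p = logrank_test(times_high, events_high, times_low, events_low)
    if np.isnan(chi2):
        return LogRankResult(mirna_id, float("nan"), float("nan"), "low",
                             len(times_high), len(times_low), median_cut, defined=False)
    # worse group: more observed than expected events in the high stratum
    th = np.asarray(times_high, float)
    eh = np.asarray(events_high, int)
    tl = np.asarray(times_low, float)
    el = np.asarray(events_low, int)
    o_minus_e = 0.0
    for t in np.unique(np.concatenate([th[eh == 1], tl[el == 1]])):
        n1 = int(np.sum(th >= t))
        n2 = int(np.sum(tl >= t))
        d1 = int(np.sum((th == t) & (eh == 1)))
        d2 = int(np.sum((tl == t) & (el == 1)))
        if n1 + n2 == 0:
            continue
        o_minus_e += d1 - (d1 + d2) * n1 / (n1 + n2)
    worse = "high" if o_minus_e > 0 else "low"
    return LogRankResult(mirna_id, chi2, p, worse,
                         int(len(th)), int(len(tl)), median_cut)
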