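"""Kaplan–Meier estimation and the two-group log-rank test.

Strata come from deregulation-score quartiles or RP-mutation status.  The
log-rank statistic is built from the 2x2 table at every distinct event
time, with hypergeometric variance, so the result object can report
observed and expected events per stratum — the quantity clinicians read
off the curves.  Deaths precede censorings at tied times (the conventional
product-limit treatment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import SurvivalRecord

__all__ = ["KMCurve", "LogRankResult", "km_curve", "logrank_test", "apply_strata"]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate.

    ``event_times`` are the distinct times with >= 1 event; ``survival`` is
    S(t) just after each of them.  S is 1 before the first event and drops
    only at event times.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def evaluate(self, t) -> np.ndarray:
        """S(t) at arbitrary times (right-continuous step function)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float
    strata: tuple[str, str]
    observed: tuple[float, float]
    expected: tuple[float, float]
    flag: str = ""

    def __str__(self) -> str:
        a, b = self.strata
        return (
            f"log-rank chi2 = {self.chi2:.4g} (df={self.df}), p = {self.p:.4g}; "
            f"{a}: O={self.observed[0]:.0f}/E={self.expected[0]:.2f}, "
            f"{b}: O={self.observed[1]:.0f}/E={self.expected[1]:.2f}"
        )


def _as_arrays(records):
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    return times, events


def km_curve(records) -> KMCurve:
    """Kaplan–Meier product-limit estimator for one stratum.

    Censored observations tied with an event time count as at risk for that
    event.  With no events at all the curve is identically 1.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one record")
    times, events = _as_arrays(records)
    event_times = np.unique(times[events])
    at_risk = np.array([(times >= t).sum() for t in event_times], dtype=float)
    d = np.array([((times == t) & events).sum() for t in event_times], dtype=float)
    with np.errstate(invalid="ignore"):
        survival = np.cumprod(1.0 - d / at_risk)
    return KMCurve(event_times=event_times, survival=survival, at_risk=at_risk, events=d)


def logrank_test(records) -> LogRankResult:
    """Two-group log-rank test over the strata labels in ``records``.

    At each distinct event time the observed events in stratum 1 are
    compared with the hypergeometric expectation given the risk sets; the
    squared sum of differences over the summed variance is chi-squared with
    1 df under the null of identical survival.
    """
    records = list(records)
    strata = sorted({r.stratum for r in records})
    if len(strata) != 2:
        raise ValueError(f"need exactly two strata, got {strata}")
    g1 = [r for r in records if r.stratum == strata[0]]
    g2 = [r for r in records if r.stratum == strata[1]]
    if not g1 or not g2:
        raise ValueError("both strata must be non-empty")
    t1, e1 = _as_arrays(g1)
    t2, e2 = _as_arrays(g2)
    all_times, all_events = np.concatenate([t1, t2]), np.concatenate([e1, e2])
    if not all_events.any():
        return LogRankResult(
            chi2=np.nan, df=1, p=np.nan, strata=(strata[0], strata[1]),
            observed=(0.0, 0.0), expected=(0.0, 0.0), flag="no_events",
        )
    event_times = np.unique(all_times[all_events])
    o1 = e1_sum = var = 0.0
    obs1 = obs2 = exp1 = exp2 = 0.0
    for t in event_times:
        n1 = float((t1 >= t).sum())
        n2 = float((t2 >= t).sum())
        n = n1 + n2
        d1 = float(((t1 == t) & e1).sum())
        d2 = float(((t2 == t) & e2).sum())
        d = d1 + d2
        e1j = d * n1 / n
        obs1 += d1
        obs2 += d2
        exp1 += e1j
        exp2 += d - e1j
        o1 += d1
        e1_sum += e1j
        if n > 1:
            var += d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1.0)
    if var == 0:
        chi2 = 0.0
        p = 1.0
        flag = "zero_variance"
    else:
        chi2 = (o1 - e1_sum) ** 2 / var
        p = float(stats.chi2.sf(chi2, df=1))
        flag = ""
    return LogRankResult(
        chi2=float(chi2),
        df=1,
        p=p,
        strata=(strata[0], strata[1]),
        observed=(obs1, obs2),
        expected=(exp1, exp2),
        flag=flag,
    )


def apply_strata(records, strata: dict, keep=("upper", "lower")):
    """Copy records, attach stratum labels, and keep the requested labels.

    ``strata`` maps sample_id -> label (e.g. quartile labels or RP-mutation
    status).  Samples without a label, or with labels outside ``keep``, are
    dropped — the upper-vs-lower quartile comparison ignores the middle half.
    """
    out = []
    for r in records:
        label = strata.get(r.sample_id)
        if label is not None and (keep is None or label in keep):
            out.append(SurvivalRecord(r.sample_id, r.time, r.event, stratum=str(label)))
    return out
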