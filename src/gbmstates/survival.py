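"""Signature-based survival stratification: median split, Kaplan-Meier
product-limit curves, and the Mantel-Cox log-rank test.

The estimator and the test are implemented from first principles (the tests
cross-check them against lifelines).  Patients are ranked by signature score
from high to low; the upper 50% form the "higher" group (ceiling on odd n,
ties at the boundary broken by patient order).  At tied times deaths are
processed before censorings (censored subjects leave the risk set after
their time).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .enrichment import ssgsea_matrix

__all__ = [
    "KMCurve",
    "LogRankResult",
    "stratify_median",
    "km_estimate",
    "km_median",
    "logrank_test",
    "signature_survival",
]


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the observed death times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t); 1 before the first death."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    pvalue: float
    observed: np.ndarray  # deaths per group (A, B)
    expected: np.ndarray


def stratify_median(scores: pd.Series) -> pd.Series:
    """Upper half (by score, descending) -> "higher", rest -> "lower".

    With odd n the higher group takes the extra patient; ties at the
    boundary are broken by patient order in the input.
    """
    if scores.size < 2:
        raise ValueError("need at least 2 patients to stratify")
    order = np.lexsort((np.arange(scores.size), -scores.to_numpy()))
    n_high = int(np.ceil(scores.size / 2))
    group = np.empty(scores.size, dtype=object)
    group[order[:n_high]] = "higher"
    group[order[n_high:]] = "lower"
    return pd.Series(group, index=scores.index, name="group")


def km_estimate(time: Sequence[float], event: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if t.shape != e.shape:
        raise ValueError("time and event vectors must be aligned")
    if (t < 0).any():
        raise ValueError("negative survival times")
    death_times = np.unique(t[e])
    at_risk = np.empty(death_times.size, dtype=np.int64)
    deaths = np.empty(death_times.size, dtype=np.int64)
    surv = np.empty(death_times.size)
    s = 1.0
    for i, ti in enumerate(death_times):
        n_i = int((t >= ti).sum())  # censored at ti are still at risk at ti
        d_i = int((e & (t == ti)).sum())
        s *= 1.0 - d_i / n_i
        at_risk[i] = n_i
        deaths[i] = d_i
        surv[i] = s
    return KMCurve(event_times=death_times, at_risk=at_risk, events=deaths, survival=surv)


def km_median(curve: KMCurve) -> float:
    """First time S(t) drops to 0.5 or below; inf if it never does."""
    below = np.flatnonzero(curve.survival <= 0.5)
    return float(curve.event_times[below[0]]) if below.size else float("inf")


def logrank_test(
    time_a: Sequence[float],
    event_a: Sequence[bool],
    time_b: Sequence[float],
    event_b: Sequence[bool],
) -> LogRankResult:
    """Two-sample Mantel-Cox log-rank test (chi-square, 1 df).

    At each pooled death time the observed deaths in group A are compared
    with the hypergeometric expectation given the risk sets; the statistic
    is (sum(O - E))^2 / sum(Var).
    """
    ta = np.asarray(time_a, dtype=float)
    ea = np.asarray(event_a, dtype=bool)
    tb = np.asarray(time_b, dtype=float)
    eb = np.asarray(event_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if not (ea.any() or eb.any()):
        raise ValueError("no events in either group; log-rank undefined")
    death_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_a = e_a = var = 0.0
    obs = np.zeros(2)
    for ti in death_times:
        n1 = int((ta >= ti).sum())
        n2 = int((tb >= ti).sum())
        n = n1 + n2
        d1 = int((ea & (ta == ti)).sum())
        d2 = int((eb & (tb == ti)).sum())
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        o_a += d1
        e_a += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        obs += (d1, d2)
    if var == 0.0:
        if abs(o_a - e_a) < 1e-12:
            stat = 0.0
        else:
            raise ValueError("log-rank variance is zero with nonzero O - E")
    else:
        stat = (o_a - e_a) ** 2 / var
    total_deaths = obs.sum()
    expected = np.array([e_a, total_deaths - e_a])
    return LogRankResult(
        statistic=float(stat),
        pvalue=float(chi2.sf(stat, df=1)),
        observed=obs,
        expected=expected,
    )


def signature_survival(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    signature: Sequence[str],
    tau: float = 0.25,
) -> Tuple[pd.Series, Mapping[str, KMCurve], LogRankResult]:
    """Score patients by ssGSEA, median-split, and compare survival.

    ``expression`` is patients x genes (bulk); ``clinical`` must carry
    ``time`` and ``event`` aligned to the same patients.  Returns the group
    assignment, per-group KM curves, and the log-rank result
    (A = higher, B = lower).
    """
    if not expression.index.equals(clinical.index):
        raise ValueError("expression and clinical tables are not aligned")
    scores = ssgsea_matrix(expression, {"signature": list(signature)}, tau=tau).es[
        "signature"
    ]
    groups = stratify_median(scores)
    curves = {}
    for g in ("higher", "lower"):
        mask = groups == g
        curves[g] = km_estimate(
            clinical.loc[mask, "time"], clinical.loc[mask, "event"]
        )
    hi = groups == "higher"
    result = logrank_test(
        clinical.loc[hi, "time"],
        clinical.loc[hi, "event"],
        clinical.loc[~hi, "time"],
        clinical.loc[~hi, "event"],
    )
    return groups, curves, result
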