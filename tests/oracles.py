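"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorized closed forms used by the package:
the ssGSEA oracle walks the ranked gene list position by position and
accumulates the two ECDFs explicitly (quadratic-time running sum), and the
Jensen-Shannon oracle evaluates the divergence term by term.
"""

import math

import numpy as np


def naive_ssgsea_es(values, gene_names, gene_set, tau=0.25):
    """Running-sum ES: rank genes by value descending (ties by input order),
    then accumulate weighted in-set ECDF minus uniform out-of-set ECDF."""
    n = len(gene_names)
    order = sorted(range(n), key=lambda i: (-values[i], i))
    in_set = set(gene_set)
    rank_value = {}
    for pos, i in enumerate(order):
        rank_value[i] = n - pos
    k = sum(1 for name in gene_names if name in in_set)
    w_total = sum(
        rank_value[i] ** tau for i in range(n) if gene_names[i] in in_set
    )
    es = 0.0
    p_in = 0.0
    p_out = 0.0
    for i in order:
        if gene_names[i] in in_set:
            p_in += rank_value[i] ** tau / w_total
        else:
            p_out += 1.0 / (n - k)
        es += p_in - p_out
    return es


def naive_jsd_base2(p, q):
    """Elementwise base-2 Jensen-Shannon divergence of two distributions."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)
    kl_pm = sum(
        pi * math.log2(pi / mi) for pi, mi in zip(p, m) if pi > 0
    )
    kl_qm = sum(
        qi * math.log2(qi / mi) for qi, mi in zip(q, m) if qi > 0
    )
    return 0.5 * kl_pm + 0.5 * kl_qm


def product_limit(times, events):
    """Hand product-limit estimator: returns {death_time: S(t)}."""
    times = list(times)
    events = list(events)
    out = {}
    s = 1.0
    for t in sorted({t for t, e in zip(times, events) if e}):
        n_at_risk = sum(1 for ti in times if ti >= t)
        deaths = sum(1 for ti, ei in zip(times, events) if ei and ti == t)
        s *= 1.0 - deaths / n_at_risk
        out[t] = s
    return out
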