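"""Cohort composition tables, count correlations, and the regulon
specificity score (RSS).

RSS compares a regulon's activity distribution over cells with the indicator
distribution of a target cell label: both are normalized to probability
vectors and RSS = 1 - sqrt(JSD) with the Jensen-Shannon divergence taken in
base-2 logs, so RSS is 1 for a regulon active exactly and uniformly on the
target cells and 0 when the supports are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import pearsonr, spearmanr

__all__ = ["CompositionTable", "composition", "pearson_correlation", "rss"]


@dataclass
class CompositionTable:
    """Sample x category counts and row-normalized proportions."""

    counts: pd.DataFrame
    proportions: pd.DataFrame


def composition(
    labels: Sequence[str], samples: Sequence[str]
) -> CompositionTable:
    """Cross-tabulate per-cell category labels by sample."""
    labels = pd.Series(labels, name="category").reset_index(drop=True)
    samples = pd.Series(samples, name="sample").reset_index(drop=True)
    if labels.size != samples.size:
        raise ValueError("label and sample vectors must be aligned")
    counts = pd.crosstab(samples, labels)
    proportions = counts.div(counts.sum(axis=1), axis=0)
    return CompositionTable(counts=counts, proportions=proportions)


def pearson_correlation(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> Tuple[float, float]:
    """Sample correlation between two per-sample count vectors.

    Pearson by default (two-sided t-distribution p-value, n-2 df); Spearman
    is available for a rank-based alternative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be the same length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        r, p = pearsonr(x, y)
    elif method == "spearman":
        r, p = spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def rss(
    activity: pd.DataFrame, labels: Sequence[str], target_label: str
) -> pd.Series:
    """Regulon specificity score per regulon for one target cell label.

    ``activity`` is cells x regulons with nonnegative values; ``labels``
    assigns a category to every cell.
    """
    labels = pd.Series(list(labels), index=activity.index)
    target = (labels == target_label).to_numpy(dtype=float)
    if target.sum() == 0:
        raise ValueError(f"no cell carries the label {target_label!r}")
    if (activity.to_numpy() < 0).any():
        raise ValueError("regulon activities must be nonnegative")
    p_c = target / target.sum()
    out = {}
    for reg in activity.columns:
        a = activity[reg].to_numpy(dtype=float)
        s = a.sum()
        if s <= 0:
            raise ValueError(f"regulon {reg!r} has zero total activity")
        p_r = a / s
        # scipy returns the JS *distance* = sqrt(JSD) for the given base
        out[reg] = 1.0 - float(jensenshannon(p_r, p_c, base=2))
    return pd.Series(out, name=f"rss:{target_label}")
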