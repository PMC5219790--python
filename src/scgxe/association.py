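"""Cluster-by-condition association tests and proportion-change intervals.

Associations between discovered cell states and culture conditions are scored
with Fisher's exact test on 2x2 tables (cluster membership vs condition), the
two-sided p-value being the sum of hypergeometric probabilities of all tables
with the observed margins that are no more probable than the observed one —
the convention of the classic R implementation.  Changes in cluster
proportions between conditions carry Newcombe hybrid-score (Wilson-based)
confidence intervals, which behave sensibly at the small per-chip cell counts
(<= 48) this design produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm

__all__ = [
    "ContingencyTable",
    "ProportionChange",
    "fisher_exact",
    "proportion_change_ci",
    "cluster_condition_scan",
]

# relative tolerance for "no more probable than observed" float ties
_TIE_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 nonnegative integer counts; rows = cluster in/out, cols = condition."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_array(cls, arr) -> "ContingencyTable":
        (a, b), (c, d) = np.asarray(arr, dtype=int)
        return cls(int(a), int(b), int(c), int(d))


@dataclass(frozen=True)
class ProportionChange:
    p1_hat: float
    p2_hat: float
    difference: float
    ci_low: float
    ci_high: float
    level: float


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact p for a 2x2 table, plus -log10(p).

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of those no more probable than the observed
    table (with a small relative tolerance for floating-point ties).
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable.from_array(table)
    n = table.total
    r1 = table.a + table.b            # cluster row margin
    c1 = table.a + table.c            # condition column margin
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(support, n, r1, c1)
    p_obs = probs[table.a - lo]
    p = float(probs[probs <= p_obs * (1 + _TIE_REL_TOL)].sum())
    p = min(p, 1.0)
    return p, -math.log10(p) if p > 0 else math.inf


def _wilson(x, n, z):
    """Wilson score interval; vectorised over x, n."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    p = x / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = (z / denom) * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return center - half, center + half


def proportion_change_ci(x1, n1, x2, n2, level: float = 0.95):
    """Newcombe hybrid-score interval for the difference p2 - p1.

    Wilson limits (l_i, u_i) for each proportion are combined as
    lower = d - sqrt((p2-l2)^2 + (u1-p1)^2), upper = d + sqrt((u2-p2)^2 + (p1-l1)^2),
    d = p2_hat - p1_hat.  Accepts scalars or equal-length arrays; scalar input
    returns a :class:`ProportionChange`.
    """
    x1a, n1a = np.asarray(x1, dtype=float), np.asarray(n1, dtype=float)
    x2a, n2a = np.asarray(x2, dtype=float), np.asarray(n2, dtype=float)
    if np.any(n1a < 1) or np.any(n2a < 1):
        raise ValueError("sample sizes must be >= 1")
    if np.any(x1a < 0) or np.any(x1a > n1a) or np.any(x2a < 0) or np.any(x2a > n2a):
        raise ValueError("successes must satisfy 0 <= x <= n")
    z = norm.ppf(0.5 + level / 2)
    p1 = x1a / n1a
    p2 = x2a / n2a
    l1, u1 = _wilson(x1a, n1a, z)
    l2, u2 = _wilson(x2a, n2a, z)
    d = p2 - p1
    lower = d - np.sqrt((p2 - l2) ** 2 + (u1 - p1) ** 2)
    upper = d + np.sqrt((u2 - p2) ** 2 + (p1 - l1) ** 2)
    lower = np.clip(lower, -1.0, 1.0)
    upper = np.clip(upper, -1.0, 1.0)
    if np.isscalar(x1) or (np.ndim(x1) == 0):
        return ProportionChange(float(p1), float(p2), float(d), float(lower), float(upper), level)
    return d, lower, upper


def cluster_condition_scan(
    labels: pd.Series,
    meta: pd.DataFrame,
    by: list[str] = ("media", "lps"),
    level: float = 0.95,
) -> pd.DataFrame:
    """Fisher tests + proportion-change CIs for every (cluster, condition level).

    ``labels`` holds cluster ids per cell (-1 / NaN = unassigned, excluded).
    For each retained cluster and each level of each ``by`` column, the 2x2
    table is (in cluster?) x (in condition level?), and the proportion change
    is the cluster's share among condition-level cells minus its share among
    the remaining cells.
    """
    labels = labels.dropna()
    labels = labels[labels != -1]
    meta = meta.loc[labels.index]
    rows = []
    for cluster in sorted(pd.unique(labels)):
        in_c = (labels == cluster).to_numpy()
        for colname in by:
            for lv in sorted(meta[colname].astype(str).unique()):
                in_l = (meta[colname].astype(str) == lv).to_numpy()
                a = int((in_c & in_l).sum())
                b = int((in_c & ~in_l).sum())
                c = int((~in_c & in_l).sum())
                d = int((~in_c & ~in_l).sum())
                p, nlp = fisher_exact(ContingencyTable(a, b, c, d))
                n1, n2 = a + c, b + d
                if n1 >= 1 and n2 >= 1:
                    change = proportion_change_ci(b, n2, a, n1, level=level)
                    diff, lo_ci, hi_ci = change.difference, change.ci_low, change.ci_high
                else:
                    diff = lo_ci = hi_ci = np.nan
                rows.append(
                    {
                        "cluster": cluster,
                        "condition": colname,
                        "level": lv,
                        "n_cluster_in": a,
                        "n_cluster_out": b,
                        "n_other_in": c,
                        "n_other_out": d,
                        "fisher_p": p,
                        "neg_log10_p": nlp,
                        "prop_change": diff,
                        "ci_low": lo_ci,
                        "ci_high": hi_ci,
                        "ci_level": level,
                    }
                )
    return pd.DataFrame(rows)
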