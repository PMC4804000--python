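"""Status-comparison statistics.

Exact tests relating PVA status metrics to sampling protocol and
community (traditional-knowledge) trend assessments: Fisher's exact
2x2 test, an exact two-sided Mann-Whitney U test, a two-sample z
comparison of abundance estimates, percent difference, Ward clustering
of (growth rate, probability of decline) status points, and
within-cluster least-squares slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom, linregress, norm

__all__ = [
    "ContingencyTable2x2",
    "StatusPoint",
    "fisher_exact_2x2",
    "mann_whitney_exact",
    "two_sample_z",
    "percent_difference",
    "ward_two_cluster",
    "cluster_slopes",
]

#: Above this many group labelings the U test falls back to the normal
#: approximation (with a logged downgrade).
EXACT_ENUMERATION_LIMIT = 10**6


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are trend/protocol categories,
    columns agreement vs disagreement."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @classmethod
    def from_array(cls, arr) -> "ContingencyTable2x2":
        (a, b), (c, d) = arr
        return cls(int(a), int(b), int(c), int(d))


@dataclass(frozen=True)
class StatusPoint:
    """One subpopulation's status record for the comparison layer."""

    subpop_id: str
    lambda_unharvested: float
    p_decline: float
    sampling: str = "entire"  # entire | partial
    tek_call: str = "stable_increasing"  # stable_increasing | declining
    pva_call: str = "stable_increasing"

    def __post_init__(self):
        if not (0.0 <= self.p_decline <= 1.0):
            raise ValueError("p_decline must lie in [0,1]")
        if self.sampling not in ("entire", "partial"):
            raise ValueError(f"unknown sampling protocol {self.sampling!r}")
        for call in (self.tek_call, self.pva_call):
            if call not in ("stable_increasing", "declining"):
                raise ValueError(f"unknown trend call {call!r}")


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by the minimum-likelihood rule.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's.
    Degenerate margins (an empty row or column) give p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    dist = hypergeom(n, r1, c1)
    a_min = max(0, c1 - r2)
    a_max = min(r1, c1)
    support = np.arange(a_min, a_max + 1)
    probs = dist.pmf(support)
    p_obs = dist.pmf(a)
    # tolerance guards against ties broken by floating error
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-7)].sum()))


def _rank_sum_u(values_a, values_b) -> float:
    """U statistic for group a using mid-ranks for ties."""
    pooled = np.concatenate([values_a, values_b])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    n_a = len(values_a)
    r_a = ranks[:n_a].sum()
    return r_a - n_a * (n_a + 1) / 2.0


def mann_whitney_exact(group_a, group_b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test.

    Enumerates every assignment of the pooled values to the two group
    sizes (mid-ranks for ties); the two-sided p is twice the smaller
    tail probability of the observed U, capped at 1.  Falls back to the
    normal approximation with tie correction when the number of
    labelings exceeds ``EXACT_ENUMERATION_LIMIT``.

    Returns
    -------
    (U, p) : U statistic of the first group and two-sided p-value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values are not allowed")
    u_obs = _rank_sum_u(a, b)
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    if math.comb(n, n_a) > EXACT_ENUMERATION_LIMIT:
        return u_obs, _mann_whitney_normal_p(a, b, u_obs)
    pooled = np.concatenate([a, b])
    us = np.array(
        [
            _rank_sum_u(pooled[list(idx)], np.delete(pooled, list(idx)))
            for idx in combinations(range(n), n_a)
        ]
    )
    eps = 1e-9
    p_low = float((us <= u_obs + eps).mean())
    p_high = float((us >= u_obs - eps).mean())
    return u_obs, min(1.0, 2.0 * min(p_low, p_high))


def _mann_whitney_normal_p(a, b, u_obs) -> float:
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


def two_sample_z(a, b) -> tuple[float, float]:
    """Two-sample z comparison of two abundance estimates.

    Accepts objects with ``N``/``se`` attributes or ``(N, se)`` pairs.
    """
    n_a, se_a = _as_estimate(a)
    n_b, se_b = _as_estimate(b)
    var = se_a**2 + se_b**2
    if var <= 0:
        raise ValueError("combined standard error must be positive")
    z = abs(n_a - n_b) / math.sqrt(var)
    return z, float(2.0 * norm.sf(z))


def _as_estimate(x):
    if hasattr(x, "N") and hasattr(x, "se"):
        return float(x.N), float(x.se)
    n, se = x
    return float(n), float(se)


def percent_difference(x: float, y: float) -> float:
    """100 * (higher - lower) / lower."""
    lo, hi = min(x, y), max(x, y)
    if lo <= 0:
        raise ValueError("percent difference requires positive values")
    return 100.0 * (hi - lo) / lo


def ward_two_cluster(points) -> np.ndarray:
    """Ward-linkage clustering of (lambda_unharvested, p_decline) status
    points on squared Euclidean distance, cut at two clusters.

    Features are deliberately unscaled.  Labels are 0/1 with cluster 0
    containing the first point; membership is invariant to input order.
    """
    points = list(points)
    if len(points) < 2:
        raise ValueError("need at least two status points")
    X = np.array([[p.lambda_unharvested, p.p_decline] for p in points])
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=2, criterion="maxclust")
    return (labels != labels[0]).astype(int)


@dataclass
class ClusterSlope:
    cluster: int
    slope: float
    p_value: float | None  # None for a 2-point cluster (no residual df)
    n: int


def cluster_slopes(points, labels) -> list:
    """Per-cluster least-squares slope of p_decline on the unharvested
    growth rate, with the t-test p-value for slope = 0."""
    points = list(points)
    labels = np.asarray(labels)
    out = []
    for lab in sorted(set(labels.tolist())):
        members = [p for p, l in zip(points, labels) if l == lab]
        if len(members) < 2:
            raise ValueError(f"cluster {lab} has fewer than 2 points")
        x = np.array([p.lambda_unharvested for p in members])
        y = np.array([p.p_decline for p in members])
        res = linregress(x, y)
        p_val = None if len(members) == 2 else float(res.pvalue)
        out.append(ClusterSlope(int(lab), float(res.slope), p_val, len(members)))
    return out
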