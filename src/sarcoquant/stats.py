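"""Rank-sum statistics used by the group comparisons.

The Mann-Whitney U test here is exact (full enumeration of group
assignments, mid-ranks for ties) whenever the smaller group has at most
8 members and the enumeration stays tractable; otherwise it uses the
normal approximation with tie correction and continuity correction.
Two-sided p-values are defined symmetrically as P(|U - n1*n2/2| >= |u - n1*n2/2|),
which matches the usual doubled-tail value for the symmetric null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["MannWhitneyResult", "mann_whitney_u", "mann_whitney"]

#: Enumeration budget: fall back to the normal approximation above this.
_MAX_ENUMERATION = 2_000_000


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first group
    p: float  # two-sided p-value
    n1: int
    n2: int
    method: str  # "exact" or "approx"


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> float:
    """U statistic of group ``a`` via mid-ranks (ties count one half)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ranks = rankdata(np.concatenate([a, b]))
    r1 = float(np.sum(ranks[: a.size]))
    return r1 - a.size * (a.size + 1) / 2.0


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of two independent samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = int(a.size), int(b.size)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = mann_whitney_u(a, b)
    mu = n1 * n2 / 2.0
    if min(n1, n2) <= 8 and math.comb(n1 + n2, n1) <= _MAX_ENUMERATION:
        p = _exact_p(a, b, u_obs)
        method = "exact"
    else:
        p = _approx_p(a, b, u_obs)
        method = "approx"
    return MannWhitneyResult(u_obs, p, n1, n2, method)


def _exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    n1 = a.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n = pooled.size
    mu = n1 * (n - n1) / 2.0
    dev_obs = abs(u_obs - mu) - 1e-12
    offset = n1 * (n1 + 1) / 2.0
    count = 0
    total = 0
    for combo in combinations(range(n), n1):
        u = ranks[list(combo)].sum() - offset
        total += 1
        if abs(u - mu) >= dev_obs:
            count += 1
    return count / total


def _approx_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    n1, n2 = a.size, b.size
    n = n1 + n2
    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations tied
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * norm.sf(z)))
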