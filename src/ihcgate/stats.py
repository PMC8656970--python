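"""Nonparametric group comparisons: two-sided Mann-Whitney U tests.

The comparison surface is the six predefined tissue-group pairs (healthy
against each lesion group, plus the two precursor-vs-carcinoma pairs on the
same HPV pathway), tested two-sided without multiple-testing adjustment.

Because published figures report significance stars rather than p-values,
the computation ladder is made explicit and auditable:

* ``exact`` - full null distribution of U by enumeration of rank
  configurations (dynamic programming), used when the pooled sample has no
  ties and at most 25 observations;
* ``permutation`` - exhaustive evaluation of U over all group splits of the
  pooled data (handles ties by midranks), used when feasible
  (<= ``PERMUTATION_CAP`` splits);
* ``mc_permutation`` - seeded Monte-Carlo permutation, available on request;
* ``normal_tie_corrected`` - normal approximation with tie correction and
  continuity correction, the fallback for large samples.

U is always computed from midranks.  Two-sided p is 2*min(P(U<=u), P(U>=u))
capped at 1 (the permutation null of U is symmetric about nA*nB/2, also
under ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb, sqrt
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "MannWhitneyResult",
    "mann_whitney",
    "pairwise_comparisons",
    "stars_for_p",
    "exact_u_distribution",
    "PREDEFINED_PAIRS",
    "PERMUTATION_CAP",
]

#: the six predefined group comparisons, in reporting order.
PREDEFINED_PAIRS = (
    ("healthy", "dVIN"),
    ("healthy", "VSCC_HPV_independent"),
    ("healthy", "HSIL"),
    ("healthy", "VSCC_HPV_dependent"),
    ("dVIN", "VSCC_HPV_independent"),
    ("HSIL", "VSCC_HPV_dependent"),
)

#: maximum number of group splits for exhaustive permutation.
PERMUTATION_CAP = 200_000

#: star bands, boundaries inclusive (p <= cut earns the stars).
STAR_BANDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass(frozen=True)
class MannWhitneyResult:
    pair: tuple[str, str]
    n_a: int
    n_b: int
    u_statistic: float
    p_two_sided: float
    method: str
    stars: str


def stars_for_p(p: float) -> str:
    for cut, label in STAR_BANDS:
        if p <= cut:
            return label
    return "ns"


@lru_cache(maxsize=128)
def exact_u_distribution(n_a: int, n_b: int) -> tuple[int, ...]:
    """Frequencies of U = 0..nA*nB under the tie-free null.

    ``f[u]`` counts the rank configurations (subsets of size nA of the pooled
    ranks) whose U statistic equals u; they sum to C(nA+nB, nA).  Computed by
    the standard recurrence f(u; m, n) = f(u-n; m-1, n) + f(u; m, n-1).
    """
    u_max = n_a * n_b
    # table[m][u] holds f(u; m, n) and is advanced in n by the recurrence
    # f(u; m, n) = f(u; m, n-1) + f(u-n; m-1, n); base f(u; m, 0) = [u == 0].
    # Ascending m keeps table[m-1] already at the current n when it is read.
    table = [[0] * (u_max + 1) for _ in range(n_a + 1)]
    for m in range(n_a + 1):
        table[m][0] = 1
    for n in range(1, n_b + 1):
        for m in range(1, n_a + 1):
            row, below = table[m], table[m - 1]
            for u in range(n, u_max + 1):
                row[u] += below[u - n]
    return tuple(table[n_a])


def _u_from_ranks(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def _two_sided_from_counts(u: float, freqs: np.ndarray) -> float:
    total = float(freqs.sum())
    # U may be half-integer under ties; <= / >= handle that directly.
    idx = np.arange(len(freqs))
    cdf = float(freqs[idx <= u + 1e-9].sum()) / total
    sf = float(freqs[idx >= u - 1e-9].sum()) / total
    return min(1.0, 2.0 * min(cdf, sf))


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    pair: tuple[str, str] = ("A", "B"),
    method: str = "auto",
    n_resamples: int = 100_000,
    seed: int | None = None,
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of two H-score samples.

    ``method`` is ``auto`` (the ladder described in the module docstring) or
    one of ``exact``, ``permutation``, ``mc_permutation``,
    ``normal_tie_corrected``.  ``seed`` only matters for ``mc_permutation``.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.isfinite(xa).all() and np.isfinite(xb).all()):
        raise ValueError("non-finite score")
    n_a, n_b = int(xa.size), int(xb.size)
    pooled = np.concatenate([xa, xb])
    ranks = rankdata(pooled)
    u = _u_from_ranks(ranks[:n_a], n_a)
    has_ties = np.unique(pooled).size < pooled.size

    if method == "auto":
        if not has_ties and n_a + n_b <= 25:
            method = "exact"
        elif comb(n_a + n_b, n_a) <= PERMUTATION_CAP:
            method = "permutation"
        else:
            method = "normal_tie_corrected"

    if method == "exact":
        if has_ties:
            raise ValueError("exact method requires tie-free data")
        freqs = np.array(exact_u_distribution(n_a, n_b), dtype=float)
        p = _two_sided_from_counts(u, freqs)
    elif method == "permutation":
        p = _permutation_p(ranks, n_a, u, exhaustive=True)
    elif method == "mc_permutation":
        p = _permutation_p(
            ranks, n_a, u, exhaustive=False, n_resamples=n_resamples, seed=seed
        )
    elif method == "normal_tie_corrected":
        p = _normal_p(ranks, n_a, n_b, u)
    else:
        raise ValueError(f"unknown method {method!r}")

    return MannWhitneyResult(
        pair=tuple(pair),
        n_a=n_a,
        n_b=n_b,
        u_statistic=u,
        p_two_sided=p,
        method=method,
        stars=stars_for_p(p),
    )


def _permutation_p(
    ranks: np.ndarray,
    n_a: int,
    u_obs: float,
    exhaustive: bool,
    n_resamples: int = 100_000,
    seed: int | None = None,
) -> float:
    n = ranks.size
    offset = n_a * (n_a + 1) / 2.0
    mid = n_a * (n - n_a) / 2.0
    if exhaustive:
        idx = np.fromiter(
            (i for c in combinations(range(n), n_a) for i in c), dtype=np.intp
        ).reshape(-1, n_a)
        us = ranks[idx].sum(axis=1) - offset
        dev = np.abs(us - mid)
        # symmetric null: two-sided p by deviation from the midpoint
        p = float(np.mean(dev >= abs(u_obs - mid) - 1e-9))
        return min(1.0, p)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(ranks)
        us = perm[:n_a].sum() - offset
        if abs(us - mid) >= abs(u_obs - mid) - 1e-9:
            count += 1
    # add-one correction keeps Monte-Carlo p strictly positive
    return min(1.0, (count + 1) / (n_resamples + 1))


def _normal_p(ranks: np.ndarray, n_a: int, n_b: int, u: float) -> float:
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    # continuity correction toward the mean
    z = (abs(u - mu) - 0.5) / sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * float(norm.sf(z)))


def pairwise_comparisons(
    scores_by_group: Mapping[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]] = PREDEFINED_PAIRS,
    method: str = "auto",
    seed: int | None = None,
) -> list[MannWhitneyResult]:
    """The predefined comparisons, in order, with unadjusted p-values.

    ``scores_by_group`` maps tissue-group label to its per-section H-scores.
    Raises ``KeyError`` naming the first missing group.
    """
    for pa, pb in pairs:
        for g in (pa, pb):
            if g not in scores_by_group:
                raise KeyError(f"missing group {g!r}")
    return [
        mann_whitney(
            scores_by_group[pa], scores_by_group[pb], pair=(pa, pb),
            method=method, seed=seed,
        )
        for pa, pb in pairs
    ]
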