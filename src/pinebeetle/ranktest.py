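"""Between-year rank-concordance test for treatment attractiveness.

Trap catches next to infested logs give each pine species (treatment) a
mean attraction per year; ranking treatments within each year (rank 1 =
most attractive) and summing squared rank differences across years gives
a concordance statistic

    D = sum_i (r1_i - r2_i)^2,

the numerator of Spearman's footrule-squared / rho relation: D = 0 for
identical rankings and D = k(k^2-1)/3 for a full reversal.  Because
small D means *similarity*, the test asks how often two independently
random rankings are at least as similar (D_rand <= D_obs).  The p-value
is estimated by Monte Carlo with the add-one correction
p = (1 + #{D_rand <= D_obs}) / (n_reps + 1), or computed exactly by
enumerating permutations for small k.

Enumerating with one ranking held fixed is valid because D depends only
on the relative permutation r2 o r1^{-1}; that equivalence is itself
checked in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Ranking",
    "RankTestResult",
    "rank_treatments",
    "rank_distance_statistic",
    "max_distance",
    "permutation_pvalue",
    "exact_pvalue",
]


@dataclass(frozen=True)
class Ranking:
    """Treatments ranked by attractiveness (rank 1 = most attractive)."""

    treatments: tuple[str, ...]
    ranks: tuple[float, ...]
    tie_method: str = "average"
    source_year: str = ""

    def __post_init__(self) -> None:
        if len(set(self.treatments)) != len(self.treatments):
            raise ValueError("duplicate treatment labels")
        k = len(self.treatments)
        if not math.isclose(sum(self.ranks), k * (k + 1) / 2, rel_tol=1e-9):
            raise ValueError("ranks must sum to k(k+1)/2")

    @property
    def k(self) -> int:
        return len(self.treatments)

    @property
    def has_ties(self) -> bool:
        return len(set(self.ranks)) != len(self.ranks)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.treatments, self.ranks))


@dataclass(frozen=True)
class RankTestResult:
    """Outcome of the concordance test (Monte Carlo or exact)."""

    d_obs: float
    k_items: int
    n_reps: int
    p_value: float
    method: str
    seed: int | None = None
    ties_present: bool = False


def rank_treatments(
    mean_catches: Mapping[str, float],
    tie_method: str = "average",
    source_year: str = "",
) -> Ranking:
    """Rank treatments from most to least attractive by mean catch.

    ``tie_method='average'`` assigns tied treatments their average rank;
    ``'first'`` breaks ties by input order (first occurrence wins).
    """
    if len(mean_catches) < 2:
        raise ValueError("need at least two treatments to rank")
    labels = list(mean_catches)
    means = np.array([mean_catches[t] for t in labels], dtype=float)
    if not np.all(np.isfinite(means)):
        raise ValueError("mean catches must be finite")
    if tie_method == "average":
        ranks = stats.rankdata(-means, method="average")
    elif tie_method == "first":
        ranks = stats.rankdata(-means, method="ordinal")
    else:
        raise ValueError(f"unknown tie_method {tie_method!r}")
    return Ranking(
        treatments=tuple(labels),
        ranks=tuple(float(r) for r in ranks),
        tie_method=tie_method,
        source_year=source_year,
    )


def _aligned_rank_arrays(r1: Ranking, r2: Ranking) -> tuple[np.ndarray, np.ndarray]:
    if set(r1.treatments) != set(r2.treatments):
        raise ValueError("rankings must cover the same treatments")
    d1 = r1.as_dict()
    d2 = r2.as_dict()
    a1 = np.array([d1[t] for t in r1.treatments])
    a2 = np.array([d2[t] for t in r1.treatments])
    return a1, a2


def rank_distance_statistic(r1: Ranking, r2: Ranking) -> float:
    """Sum of squared per-treatment rank differences between two years."""
    a1, a2 = _aligned_rank_arrays(r1, r2)
    return float(np.sum((a1 - a2) ** 2))


def max_distance(k: int) -> float:
    """Largest possible D for k untied items: k(k^2 - 1)/3 (full reversal)."""
    return k * (k * k - 1) / 3.0


def permutation_pvalue(
    r1: Ranking,
    r2: Ranking,
    n_reps: int = 999,
    seed: int = 0,
) -> RankTestResult:
    """Monte Carlo p-value for the similarity of two rankings.

    Each repetition draws two independent uniform-random permutations of
    1..k (randomizing both years) and recomputes D; the estimator
    ``p = (1 + #{D_rand <= D_obs}) / (n_reps + 1)`` counts ties as
    extreme and guarantees p >= 1/(n_reps+1).
    """
    if r1.k < 2:
        raise ValueError("need at least two treatments")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    d_obs = rank_distance_statistic(r1, r2)
    k = r1.k
    rng = np.random.default_rng(seed)
    # two independent random permutations per rep, via argsort of uniforms
    perms1 = np.argsort(rng.random((n_reps, k)), axis=1) + 1
    perms2 = np.argsort(rng.random((n_reps, k)), axis=1) + 1
    d_rand = np.sum((perms1 - perms2) ** 2, axis=1)
    m = int(np.count_nonzero(d_rand <= d_obs))
    return RankTestResult(
        d_obs=d_obs,
        k_items=k,
        n_reps=int(n_reps),
        p_value=(1 + m) / (n_reps + 1),
        method="monte_carlo",
        seed=int(seed),
        ties_present=r1.has_ties or r2.has_ties,
    )


def exact_pvalue(r1: Ranking, r2: Ranking) -> RankTestResult:
    """Exact p = P(D_rand <= D_obs) by full permutation enumeration.

    One ranking is held fixed while the other runs over all k!
    permutations; this is exact for untied rankings because the null
    distribution of D depends only on the relative permutation.  Refuses
    ties (the enumeration would not be over the right space) and k > 8
    (k! blows up).
    """
    if r1.has_ties or r2.has_ties:
        raise ValueError("exact enumeration requires untied rankings")
    k = r1.k
    if k < 2:
        raise ValueError("need at least two treatments")
    if k > 8:
        raise ValueError("exact enumeration limited to k <= 8")
    d_obs = rank_distance_statistic(r1, r2)
    base = np.arange(1, k + 1)
    count = 0
    total = 0
    for perm in itertools.permutations(range(k)):
        d = float(np.sum((base - base[list(perm)]) ** 2))
        count += d <= d_obs
        total += 1
    return RankTestResult(
        d_obs=d_obs,
        k_items=k,
        n_reps=total,
        p_value=count / total,
        method="exact",
        seed=None,
    )
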