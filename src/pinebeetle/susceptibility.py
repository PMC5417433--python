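"""Monte Carlo integration of stage estimates into overall susceptibility.

A beetle that lands on a tree only produces brood if it completes every
colonization stage: bark entry, phloem entry, and brood establishment.
Given per-species logit-scale estimates (mean and SE) for the three
stage probabilities, the integrator draws each stage's logit from an
independent normal, back-transforms to a probability, and multiplies the
three — a logit-normal propagation of estimation uncertainty through the
product.  Repeating this many times yields a susceptibility distribution
whose middle 95% (2.5th–97.5th empirical percentiles) summarizes how
likely a landing female is to leave live progeny under the bark.

Draws are taken on the logit scale but multiplied on the probability
scale: multiplying logits has no meaning for a product of probabilities.
Stages are assumed independent; no correlation structure is modeled.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .proportions import Stage, StageEstimate

__all__ = [
    "SusceptibilityDistribution",
    "integrate_susceptibility",
    "truncate_middle",
    "summarize_susceptibility",
]

#: canonical stage order used for substream assignment
_STAGE_ORDER = (Stage.BARK, Stage.PHLOEM, Stage.BROOD)


@dataclass(frozen=True)
class SusceptibilityDistribution:
    """Monte Carlo draws of the stage-product colonization probability."""

    species: str
    n_draws: int
    seed: int
    draws: np.ndarray
    median: float
    lower_2_5: float
    upper_97_5: float
    point_product: float


def _species_rng(seed: int, species: str) -> np.ndarray:
    """Independent substream per species, order-independent.

    The substream key hashes the species label, so results for one
    species do not depend on which other species are integrated or in
    what order.
    """
    return np.random.default_rng([int(seed), zlib.crc32(species.encode("utf8"))])


def integrate_susceptibility(
    stages: Sequence[StageEstimate],
    n_draws: int = 100_000,
    seed: int = 0,
) -> SusceptibilityDistribution:
    """Integrate three stage estimates into a susceptibility distribution.

    Parameters
    ----------
    stages
        Exactly one :class:`~pinebeetle.proportions.StageEstimate` per
        colonization stage (bark, phloem, brood), all for one species.
        Input order is irrelevant; stages are canonicalized internally.
    n_draws
        Number of Monte Carlo repetitions (default 100,000).
    seed
        Master seed; the species label selects a reproducible substream.

    Each draw samples stage logits ``mean + se * z`` with independent
    standard normals ``z``, so common random numbers are preserved when
    only the means change — raising one stage's logit mean raises every
    draw (stochastic monotonicity).
    """
    by_stage = {}
    species = None
    for se in stages:
        if se.stage in by_stage:
            raise ValueError(f"duplicate stage {se.stage.value!r}")
        by_stage[se.stage] = se
        if species is None:
            species = se.species
        elif se.species != species:
            raise ValueError("all stage estimates must be for one species")
    missing = [s.value for s in _STAGE_ORDER if s not in by_stage]
    if missing:
        raise ValueError(f"missing stage estimate(s): {missing}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    for se in by_stage.values():
        est = se.estimate
        if not (np.isfinite(est.logit_mean) and np.isfinite(est.logit_se)):
            raise ValueError("stage estimates must have finite logit mean and SE")
        if est.logit_se < 0:
            raise ValueError("logit_se must be non-negative")

    rng = _species_rng(seed, species or "")
    # one z-matrix in canonical stage order -> CRN across parameter changes
    z = rng.standard_normal((len(_STAGE_ORDER), n_draws))
    draws = np.ones(n_draws)
    point = 1.0
    for row, stage in enumerate(_STAGE_ORDER):
        est = by_stage[stage].estimate
        draws *= expit(est.logit_mean + est.logit_se * z[row])
        point *= float(expit(est.logit_mean))
    lo, hi, _ = truncate_middle(draws)
    return SusceptibilityDistribution(
        species=species or "",
        n_draws=int(n_draws),
        seed=int(seed),
        draws=draws,
        median=float(np.median(draws)),
        lower_2_5=lo,
        upper_97_5=hi,
        point_product=point,
    )


def truncate_middle(
    draws: np.ndarray,
    lower_pct: float = 2.5,
    upper_pct: float = 97.5,
    method: str = "linear",
) -> tuple[float, float, np.ndarray]:
    """Empirical middle band of a draw distribution.

    Returns the two percentiles (linear interpolation between order
    statistics by default; ``method`` accepts any numpy percentile
    convention) and the draws strictly inside them.  With the defaults
    this is the middle 95%: the upper and lower 2.5% tails removed.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("no draws to truncate")
    if not 0 <= lower_pct < upper_pct <= 100:
        raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
    lo, hi = np.percentile(draws, [lower_pct, upper_pct], method=method)
    if lo == hi:  # degenerate (constant) distribution: keep everything
        return float(lo), float(hi), draws.copy()
    retained = draws[(draws > lo) & (draws < hi)]
    return float(lo), float(hi), retained


def summarize_susceptibility(dist: SusceptibilityDistribution) -> dict:
    """One summary row per species, suitable for a susceptibility table."""
    return {
        "species": dist.species,
        "median": dist.median,
        "lo95": dist.lower_2_5,
        "hi95": dist.upper_97_5,
        "point_product": dist.point_product,
        "n_draws": dist.n_draws,
        "seed": dist.seed,
    }
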