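"""Stage-wise binomial estimation for host-colonization trials.

Colonization of a pine by the mountain pine beetle proceeds through
discrete behavioral stages — entering the outer bark, tunneling into the
phloem, and establishing an ovipositional (brood) gallery.  Each assay
unit exposes a known number of female beetles to one stage and records
how many succeed, so the natural model is a binomial success probability
per species and stage.  This module provides pooled and per-species
estimates of those probabilities on the logit scale (where the sampling
distribution of the MLE is closest to normal), logistic regression for
covariates such as phloem thickness or host class, and likelihood-ratio
contrasts between nested fits.

Tree- and unit-level clustering is deliberately not modeled here: the
estimates are saturated/fixed-effects maximum-likelihood quantities,
which is exactly what the downstream Monte Carlo susceptibility
integrator consumes (a logit mean and standard error per species and
stage).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = [
    "Stage",
    "TrialRecord",
    "ProportionEstimate",
    "StageEstimate",
    "LogisticFit",
    "ChiSquareTest",
    "trials_to_frame",
    "proportion_estimate_from_counts",
    "pooled_proportion",
    "stage_estimate_from_probability",
    "species_logit_estimate",
    "per_tree_mean_proportion",
    "fit_logistic_regression",
    "lrt_nested",
    "host_class_contrast",
]

#: z quantile used for all Wald intervals on the logit scale.
Z_95 = 1.959963984540054

#: |coefficient| (logits) beyond which a fit is flagged as separated.
SEPARATION_LIMIT = 15.0


class Stage(str, enum.Enum):
    """The three scored colonization stages."""

    BARK = "bark"
    PHLOEM = "phloem"
    BROOD = "brood"

    @classmethod
    def coerce(cls, value: "Stage | str") -> "Stage":
        if isinstance(value, Stage):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"unknown colonization stage {value!r}; "
                f"expected one of {[s.value for s in cls]}"
            ) from None


@dataclass(frozen=True)
class TrialRecord:
    """One colonization assay unit (a caged cell or a drilled hole).

    ``n_exposed`` beetles were offered the stage transition and
    ``n_success`` completed it.  ``phloem_mm`` is the phloem thickness of
    the log, when measured; ``paired_male`` records whether a male was
    added to the gallery (relevant only at the brood stage).
    """

    stage: Stage
    year: int
    species: str
    host_class: str
    tree_id: str
    unit_id: str
    n_exposed: int
    n_success: int
    phloem_mm: float | None = None
    paired_male: bool | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage", Stage.coerce(self.stage))
        if not 0 <= self.n_success <= self.n_exposed:
            raise ValueError(
                f"need 0 <= n_success <= n_exposed, got "
                f"{self.n_success}/{self.n_exposed}"
            )
        if self.phloem_mm is not None and not self.phloem_mm > 0:
            raise ValueError("phloem_mm must be positive when present")
        if self.host_class not in ("historical", "novel"):
            raise ValueError(f"unknown host_class {self.host_class!r}")


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with its logit-scale MLE and Wald interval.

    ``logit_mean``/``logit_se`` are the saturated-binomial maximum
    likelihood estimate and delta-method standard error; the 95% CI is
    computed on the logit scale and back-transformed, which makes it
    asymmetric about ``p_hat`` except at 0.5.  ``correction_applied``
    flags the Haldane–Anscombe boundary adjustment (k = 0 or k = n).
    """

    k: int
    n: int
    p_hat: float
    logit_mean: float
    logit_se: float
    ci_low: float
    ci_high: float
    correction_applied: bool


@dataclass(frozen=True)
class StageEstimate:
    """A per-species, per-stage :class:`ProportionEstimate`."""

    species: str
    stage: Stage
    estimate: ProportionEstimate


@dataclass(frozen=True)
class LogisticFit:
    """A fixed-effects binomial GLM fit (logit link)."""

    params: Mapping[str, float]
    bse: Mapping[str, float]
    pvalues: Mapping[str, float]
    llf: float
    deviance: float
    aic: float
    nobs: int
    converged: bool
    n_iter: int
    formula: str = ""

    @property
    def n_coef(self) -> int:
        return len(self.params)


@dataclass(frozen=True)
class ChiSquareTest:
    """A chi-square statistic with its df and upper-tail p-value."""

    statistic: float
    df: int
    p_value: float
    name: str = ""


# ---------------------------------------------------------------------------
# record <-> frame plumbing


_TRIAL_COLUMNS = [
    "stage", "year", "species", "host_class", "tree_id", "unit_id",
    "n_exposed", "n_success", "phloem_mm", "paired_male",
]


def trials_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Convert trial records to a tidy DataFrame (one row per assay unit)."""
    rows = [
        {
            "stage": r.stage.value,
            "year": r.year,
            "species": r.species,
            "host_class": r.host_class,
            "tree_id": r.tree_id,
            "unit_id": r.unit_id,
            "n_exposed": r.n_exposed,
            "n_success": r.n_success,
            "phloem_mm": r.phloem_mm,
            "paired_male": r.paired_male,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_TRIAL_COLUMNS)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return trials_to_frame(records)


def _select_stage(df: pd.DataFrame, stage: Stage | str) -> pd.DataFrame:
    stage = Stage.coerce(stage)
    sub = df[df["stage"] == stage.value]
    if sub.empty:
        raise ValueError(f"no records at stage {stage.value!r}")
    return sub


# ---------------------------------------------------------------------------
# estimation


def proportion_estimate_from_counts(k: int, n: int) -> ProportionEstimate:
    """Logit-scale MLE for ``k`` successes out of ``n``.

    logit_mean = ln(k/(n-k)) and logit_se = sqrt(1/k + 1/(n-k)), the
    observed-information (delta method) standard error of the saturated
    binomial.  At the boundary (k = 0 or k = n) the Haldane–Anscombe
    adjustment adds 0.5 to each cell so all logit quantities stay finite,
    and the flag is set.  ``p_hat`` always reports the raw k/n.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    p_hat = k / n
    corrected = k == 0 or k == n
    if corrected:
        kk, nn = k + 0.5, n + 1.0
    else:
        kk, nn = float(k), float(n)
    logit_mean = math.log(kk / (nn - kk))
    logit_se = math.sqrt(1.0 / kk + 1.0 / (nn - kk))
    ci_low = float(expit(logit_mean - Z_95 * logit_se))
    ci_high = float(expit(logit_mean + Z_95 * logit_se))
    return ProportionEstimate(
        k=int(k), n=int(n), p_hat=p_hat,
        logit_mean=logit_mean, logit_se=logit_se,
        ci_low=ci_low, ci_high=ci_high,
        correction_applied=corrected,
    )


def stage_estimate_from_probability(
    species: str,
    stage: Stage | str,
    p: float,
    logit_se: float = 0.0,
) -> StageEstimate:
    """Build a stage estimate directly from a probability and logit SE.

    Useful for feeding published proportions (with or without
    uncertainty) into the susceptibility integrator; ``logit_se=0``
    gives the zero-variance (deterministic) limit.  Counts are not known
    here, so ``k``/``n`` are recorded as 0.
    """
    if not 0 < p < 1:
        raise ValueError("p must be strictly inside (0, 1)")
    if logit_se < 0:
        raise ValueError("logit_se must be non-negative")
    logit_mean = math.log(p / (1 - p))
    est = ProportionEstimate(
        k=0, n=0, p_hat=p, logit_mean=logit_mean, logit_se=logit_se,
        ci_low=float(expit(logit_mean - Z_95 * logit_se)),
        ci_high=float(expit(logit_mean + Z_95 * logit_se)),
        correction_applied=False,
    )
    return StageEstimate(species=species, stage=Stage.coerce(stage), estimate=est)


def pooled_proportion(records, stage: Stage | str) -> ProportionEstimate:
    """Pool successes and exposures over all records at one stage."""
    df = _select_stage(_as_frame(records), stage)
    k = int(df["n_success"].sum())
    n = int(df["n_exposed"].sum())
    if n <= 0:
        raise ValueError("total exposure is zero")
    return proportion_estimate_from_counts(k, n)


def species_logit_estimate(records, species: str, stage: Stage | str) -> StageEstimate:
    """Saturated logit-scale estimate for one species at one stage."""
    df = _select_stage(_as_frame(records), stage)
    sub = df[df["species"] == species]
    if sub.empty:
        raise ValueError(f"species {species!r} absent at stage {stage!r}")
    est = proportion_estimate_from_counts(
        int(sub["n_success"].sum()), int(sub["n_exposed"].sum())
    )
    return StageEstimate(species=species, stage=Stage.coerce(stage), estimate=est)


def per_tree_mean_proportion(records, species: str, stage: Stage | str) -> float:
    """Mean of per-tree success proportions (an alternative to pooling).

    Whether a display proportion should pool beetles or average tree-level
    proportions is a modeling choice; both are exposed and neither is
    privileged.
    """
    df = _select_stage(_as_frame(records), stage)
    sub = df[df["species"] == species]
    if sub.empty:
        raise ValueError(f"species {species!r} absent at stage {stage!r}")
    by_tree = sub.groupby("tree_id").agg(k=("n_success", "sum"), n=("n_exposed", "sum"))
    return float((by_tree["k"] / by_tree["n"]).mean())


# ---------------------------------------------------------------------------
# logistic regression


def fit_logistic_regression(records, formula: str) -> LogisticFit:
    """Fit a binomial GLM (logit link) to unit-level success/failure counts.

    ``formula`` is a right-hand-side patsy formula over the trial columns,
    e.g. ``"C(species)"``, ``"C(host_class) + phloem_mm"`` or ``"1"`` for
    an intercept-only fit.  The response is always the per-unit
    (success, failure) count pair, so the fit maximizes the grouped
    binomial log-likelihood via iteratively reweighted least squares.

    Separation (any coefficient beyond ``SEPARATION_LIMIT`` logits) is
    reported by ``converged=False`` rather than an exception.
    """
    df = _as_frame(records).copy()
    df["n_fail"] = df["n_exposed"] - df["n_success"]
    model = sm.GLM.from_formula(
        f"n_success + n_fail ~ {formula}", data=df, family=sm.families.Binomial()
    )
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("design matrix is rank deficient for formula " + repr(formula))
    with warnings.catch_warnings():
        # saturated fits legitimately hit zero residual df / perfect prediction
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        res = model.fit(maxiter=100, tol=1e-10)
    params = {name: float(v) for name, v in res.params.items()}
    separated = any(abs(v) > SEPARATION_LIMIT for v in params.values())
    return LogisticFit(
        params=params,
        bse={name: float(v) for name, v in res.bse.items()},
        pvalues={name: float(v) for name, v in res.pvalues.items()},
        llf=float(res.llf),
        deviance=float(res.deviance),
        aic=float(res.aic),
        nobs=int(res.nobs),
        converged=bool(res.converged) and not separated,
        n_iter=int(getattr(res, "fit_history", {}).get("iteration", 0)),
        formula=formula,
    )


def lrt_nested(full: LogisticFit, reduced: LogisticFit, name: str = "") -> ChiSquareTest:
    """Likelihood-ratio chi-square test of nested binomial fits."""
    df = full.n_coef - reduced.n_coef
    if df <= 0:
        raise ValueError("full model must have more coefficients than reduced")
    statistic = 2.0 * (full.llf - reduced.llf)
    if statistic < -1e-8:
        raise ValueError(
            f"negative LR statistic ({statistic:.3g}): models are not nested "
            "or a fit did not converge"
        )
    statistic = max(statistic, 0.0)
    return ChiSquareTest(
        statistic=statistic, df=df,
        p_value=float(stats.chi2.sf(statistic, df)), name=name,
    )


def host_class_contrast(records, stage: Stage | str) -> ChiSquareTest:
    """LRT for a historical-vs-novel host effect at one stage (df = 1)."""
    df = _select_stage(_as_frame(records), stage)
    if df["host_class"].nunique() < 2:
        raise ValueError("both host classes must be present for the contrast")
    full = fit_logistic_regression(df, "C(host_class)")
    reduced = fit_logistic_regression(df, "1")
    return lrt_nested(full, reduced, name=f"host_class@{Stage.coerce(stage).value}")
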