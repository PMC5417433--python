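"""Transforms, ANOVA, protected LSD and the Bonferroni outlier scan.

Trap catches and phloem-chemistry concentrations are compared across
pine species with classical fixed-effects ANOVA after the
variance-stabilizing transform appropriate to each response: square
root for trap counts and 4-allylanisole, log(y+1) for most monoterpene
concentrations, identity for alpha-pinene.  Site and week blocking in
the trap experiment is handled with additive fixed block effects;
treatment F is the partial F after removing the blocks.

Mean separation uses Fisher's protected LSD: pairwise t comparisons at
level alpha are performed only when the omnibus F is itself significant
at alpha, and results are rendered as a compact letter display (groups
sharing a letter are not significantly different).

Suspiciously large trap catches are screened with an indicator-variable
scan: refit the blocked model with a one-hot covariate for the candidate
observation, and flag it as an outlier when the indicator's p-value
falls below alpha divided by the total number of observations (a
Bonferroni correction over all points that could have been tested).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "TrapRecord",
    "ChemRecord",
    "AnovaResult",
    "PairwiseLetters",
    "OutlierReport",
    "MONOTERPENES",
    "TRANSFORM_REGISTRY",
    "apply_transform",
    "transform_for",
    "oneway_anova",
    "anova_from_summary",
    "blocked_anova",
    "protected_lsd",
    "compact_letter_display",
    "bonferroni_outlier_scan",
]


@dataclass(frozen=True)
class TrapRecord:
    """One funnel-trap catch: site x week x treatment -> beetle count."""

    site: str
    week: str
    year: int
    treatment: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")


@dataclass(frozen=True)
class ChemRecord:
    """One phloem-chemistry measurement (mg compound per g dry phloem)."""

    species: str
    tree_id: str
    compound: str
    mg_per_g: float

    def __post_init__(self) -> None:
        if self.mg_per_g < 0:
            raise ValueError("mg_per_g must be non-negative")


@dataclass(frozen=True)
class AnovaResult:
    """Omnibus F test with its mean squares and degrees of freedom."""

    F: float
    df_num: int
    df_den: int
    p_value: float
    ms_between: float
    ms_within: float
    transform_applied: str = "identity"
    note: str = ""


@dataclass(frozen=True)
class PairwiseLetters:
    """Protected-LSD mean separation rendered as compact letters."""

    letters: Mapping[str, str]
    alpha: float
    lsd_thresholds: Mapping[tuple[str, str], float]
    omnibus_significant: bool
    significant_pairs: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class OutlierReport:
    """Result of the Bonferroni indicator-variable outlier scan."""

    flagged: tuple = ()
    p_values: Mapping = field(default_factory=dict)
    threshold: float = 0.0
    n_total: int = 0
    model: str = ""


# ---------------------------------------------------------------------------
# transforms

#: the seven quantified monoterpenes (4-allylanisole is a phenylpropanoid)
MONOTERPENES = (
    "alpha-pinene", "beta-pinene", "3-carene", "myrcene",
    "limonene", "beta-phellandrene", "camphene",
)

#: per-response variance-stabilizing transform
TRANSFORM_REGISTRY: dict[str, str] = {
    "trap_count": "sqrt",
    "4-allylanisole": "sqrt",
    "alpha-pinene": "identity",
    "beta-pinene": "log1p",
    "3-carene": "log1p",
    "myrcene": "log1p",
    "limonene": "log1p",
    "beta-phellandrene": "log1p",
    "camphene": "log1p",
}

_TRANSFORMS = {
    "identity": lambda x: x,
    "sqrt": np.sqrt,
    "log1p": np.log1p,
}


def apply_transform(values, transform: str) -> np.ndarray:
    """Elementwise identity / sqrt / log(y+1) transform."""
    if transform not in _TRANSFORMS:
        raise ValueError(
            f"unknown transform {transform!r}; expected one of {sorted(_TRANSFORMS)}"
        )
    arr = np.asarray(values, dtype=float)
    if transform in ("sqrt", "log1p") and np.any(arr < 0):
        raise ValueError(f"{transform} transform requires non-negative values")
    return _TRANSFORMS[transform](arr)


def transform_for(analyte: str) -> str:
    """Registered transform for a trap/chemistry response."""
    return TRANSFORM_REGISTRY.get(analyte, "identity")


# ---------------------------------------------------------------------------
# ANOVA


def oneway_anova(groups: Mapping[str, Sequence[float]],
                 transform: str = "identity") -> AnovaResult:
    """Classical one-way fixed-effects ANOVA on raw per-group values."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: apply_transform(v, transform) for g, v in groups.items()}
    k = len(arrays)
    ns = {g: len(v) for g, v in arrays.items()}
    n_total = sum(ns.values())
    df_den = n_total - k
    if df_den < 1:
        raise ValueError("zero residual degrees of freedom")
    grand = np.concatenate(list(arrays.values())).mean()
    ssb = sum(n * (v.mean() - grand) ** 2 for (g, v), n in zip(arrays.items(), ns.values()))
    ssw = sum(float(np.sum((v - v.mean()) ** 2)) for v in arrays.values())
    ms_between = ssb / (k - 1)
    ms_within = ssw / df_den
    F = ms_between / ms_within
    return AnovaResult(
        F=float(F), df_num=k - 1, df_den=df_den,
        p_value=float(stats.f.sf(F, k - 1, df_den)),
        ms_between=float(ms_between), ms_within=float(ms_within),
        transform_applied=transform,
    )


def anova_from_summary(
    means: Sequence[float],
    ses: Sequence[float],
    n_per_group: int,
) -> AnovaResult:
    """Reconstruct a balanced one-way ANOVA from group means and SEs.

    With n observations per group, each group's within variance is
    n * se^2, so ms_within is their average and
    ms_between = n * sum((m_i - m_bar)^2) / (k - 1).  This reproduces
    the exact F a one-way ANOVA on the raw data would give — useful when
    only a published summary table is available.
    """
    means = np.asarray(means, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if means.shape != ses.shape:
        raise ValueError("means and ses must have equal length")
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    k = means.size
    if k < 2:
        raise ValueError("need at least two groups")
    ms_between = n_per_group * float(np.sum((means - means.mean()) ** 2)) / (k - 1)
    ms_within = float(np.mean(n_per_group * ses**2))
    df_num, df_den = k - 1, k * (n_per_group - 1)
    F = ms_between / ms_within
    return AnovaResult(
        F=float(F), df_num=df_num, df_den=df_den,
        p_value=float(stats.f.sf(F, df_num, df_den)),
        ms_between=ms_between, ms_within=ms_within,
        note="reconstructed from summary statistics",
    )


def blocked_anova(
    records: pd.DataFrame,
    response: str,
    treatment: str,
    blocks: Sequence[str] = (),
    transform: str = "identity",
) -> AnovaResult:
    """Treatment F test after removing additive block effects.

    Fits ``transform(response) ~ C(treatment) + C(block1) + ...`` by
    least squares and tests the treatment factor with a partial F
    against the reduced (blocks-only) model.  Blocking factors enter as
    additive fixed effects; with a balanced design this matches the
    treatment test of the corresponding randomized-block mixed model.
    """
    df = records.copy()
    for col in (treatment, *blocks):
        if col not in df.columns:
            raise ValueError(f"factor column {col!r} missing")
    df["_y"] = apply_transform(df[response].to_numpy(), transform)
    block_terms = " + ".join(f"C({b})" for b in blocks)
    rhs_full = f"C({treatment})" + (f" + {block_terms}" if block_terms else "")
    rhs_red = block_terms if block_terms else "1"
    full = smf.ols(f"_y ~ {rhs_full}", data=df).fit()
    red = smf.ols(f"_y ~ {rhs_red}", data=df).fit()
    df_num = int(red.df_resid - full.df_resid)
    df_den = int(full.df_resid)
    if df_den < 1:
        raise ValueError("zero residual degrees of freedom")
    if df_num < 1:
        raise ValueError("treatment factor adds no parameters (disconnected design?)")
    ms_between = (red.ssr - full.ssr) / df_num
    ms_within = full.ssr / df_den
    F = ms_between / ms_within
    return AnovaResult(
        F=float(F), df_num=df_num, df_den=df_den,
        p_value=float(stats.f.sf(F, df_num, df_den)),
        ms_between=float(ms_between), ms_within=float(ms_within),
        transform_applied=transform,
        note="additive fixed-block approximation"
        if blocks else "",
    )


# ---------------------------------------------------------------------------
# mean separation


def protected_lsd(
    anova: AnovaResult,
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    transform: str | None = None,
) -> PairwiseLetters:
    """Fisher's protected LSD with a compact letter display.

    Pairwise comparisons are attempted only when the omnibus F is
    significant at ``alpha`` (the protection step); otherwise every
    group shares one letter.  A pair differs when
    ``|m_i - m_j| > t(1-alpha/2, df_den) * sqrt(ms_within*(1/n_i+1/n_j))``
    using the pooled ``ms_within`` from the supplied ANOVA (unequal-n
    Fisher LSD).  ``transform`` defaults to the one recorded on the
    ANOVA so means are compared on the analysis scale.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    tr = anova.transform_applied if transform is None else transform
    arrays = {g: apply_transform(v, tr) for g, v in groups.items()}
    for g, v in arrays.items():
        if len(v) == 0:
            raise ValueError(f"group {g!r} has no observations")
    means = {g: float(v.mean()) for g, v in arrays.items()}
    ns = {g: len(v) for g, v in arrays.items()}
    order = sorted(means, key=means.get, reverse=True)

    protected = anova.p_value < alpha
    sig_pairs: list[tuple[str, str]] = []
    thresholds: dict[tuple[str, str], float] = {}
    if protected:
        tcrit = stats.t.ppf(1 - alpha / 2, anova.df_den)
        for i, gi in enumerate(order):
            for gj in order[i + 1:]:
                lsd = tcrit * np.sqrt(anova.ms_within * (1 / ns[gi] + 1 / ns[gj]))
                thresholds[(gi, gj)] = float(lsd)
                if abs(means[gi] - means[gj]) > lsd:
                    sig_pairs.append((gi, gj))
    letters = compact_letter_display(sig_pairs, order)
    return PairwiseLetters(
        letters=letters,
        alpha=alpha,
        lsd_thresholds=thresholds,
        omnibus_significant=protected,
        significant_pairs=tuple(sig_pairs),
    )


def compact_letter_display(
    significant,
    order: Sequence[str],
) -> dict[str, str]:
    """Assign letters so two groups share one iff they do not differ.

    ``significant`` is either an iterable of significantly-different
    pairs or a symmetric boolean matrix (DataFrame indexed by group).
    ``order`` fixes letter assignment (typically descending mean).
    Uses greedy insert-and-absorb: each significant pair splits every
    letter column containing both members, and dominated (subset)
    columns are absorbed.  The letter count is small but not guaranteed
    globally minimal.
    """
    if isinstance(significant, pd.DataFrame):
        mat = significant
        if not mat.equals(mat.T):
            raise ValueError("significance matrix must be symmetric")
        pairs = [
            (i, j)
            for ii, i in enumerate(mat.index)
            for j in mat.index[ii + 1:]
            if bool(mat.loc[i, j])
        ]
    else:
        pairs = [tuple(p) for p in significant]
    order = list(order)
    pos = {g: i for i, g in enumerate(order)}
    unknown = {g for p in pairs for g in p} - set(order)
    if unknown:
        raise ValueError(f"pairs mention groups not in order: {sorted(unknown)}")

    columns: list[set] = [set(order)]
    for a, b in pairs:
        expanded: list[set] = []
        for col in columns:
            if a in col and b in col:
                expanded.extend((col - {a}, col - {b}))
            else:
                expanded.append(col)
        # absorb: keep only maximal, distinct columns
        expanded.sort(key=len, reverse=True)
        columns = []
        for col in expanded:
            if not any(col <= kept for kept in columns):
                columns.append(col)
    columns.sort(key=lambda col: min(pos[g] for g in col) if col else len(order))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for idx, col in enumerate(columns):
        letter = alphabet[idx % len(alphabet)] * (idx // len(alphabet) + 1)
        for g in order:
            if g in col:
                letters[g] += letter
    return letters


# ---------------------------------------------------------------------------
# outlier scan


def bonferroni_outlier_scan(
    records: pd.DataFrame,
    response: str,
    treatment: str,
    candidates: Sequence,
    blocks: Sequence[str] = (),
    transform: str = "identity",
    alpha: float = 0.05,
    sequential: bool = True,
) -> OutlierReport:
    """Indicator-variable outlier scan with a Bonferroni threshold.

    For each candidate row index, the (transformed, blocked) linear
    model is refit with a one-hot indicator for that observation; the
    candidate is flagged when the indicator's two-sided p-value is below
    ``alpha / N_total`` with N_total the total number of observations
    (including the candidate).  With ``sequential=True`` (default) a
    flagged observation is removed before testing the next candidate,
    so a single gross point cannot mask later ones; candidates are
    visited in the order given.
    """
    missing = [c for c in candidates if c not in records.index]
    if missing:
        raise ValueError(f"candidate ids not in records: {missing}")
    n_total = len(records)
    threshold = alpha / n_total
    work = records.copy()
    work["_y"] = apply_transform(work[response].to_numpy(), transform)
    block_terms = "".join(f" + C({b})" for b in blocks)
    rhs = f"C({treatment})" + block_terms
    p_values: dict = {}
    flagged: list = []
    for cand in candidates:
        if cand not in work.index:  # removed by an earlier flag
            continue
        work["_ind"] = 0.0
        work.loc[cand, "_ind"] = 1.0
        fit = smf.ols(f"_y ~ {rhs} + _ind", data=work).fit()
        if fit.df_resid < 1:
            raise ValueError(
                f"no residual df left when testing candidate {cand!r}"
            )
        p = float(fit.pvalues["_ind"])
        p_values[cand] = p
        if p < threshold:
            flagged.append(cand)
            if sequential:
                work = work.drop(index=cand)
    return OutlierReport(
        flagged=tuple(flagged),
        p_values=p_values,
        threshold=threshold,
        n_total=n_total,
        model=f"{transform}({response}) ~ {rhs} + indicator",
    )
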