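"""End-to-end orchestration: simulate -> estimate -> integrate -> test.

A run either loads CSV inputs (trials/traps/chem) or simulates them from
the packaged default parameters, then produces:

* ``stage_estimates.csv`` — per species x stage: counts, p_hat, logit
  mean/SE and the back-transformed 95% CI;
* ``susceptibility.csv`` — per species: Monte Carlo median, middle-95%
  band and the zero-variance point product;
* ``ranktest.json`` — between-year attraction-ranking concordance;
* ``anova.json`` — blocked trap ANOVA with protected-LSD letters;
* ``outliers.json`` — Bonferroni indicator-variable scan of trap counts;
* ``report.txt`` — a human-readable summary.

Every artifact is stamped with the master seed and a hash of the
configuration.  One master seed spawns named substreams (simulation, MC
integration, permutation test) so each module's output is independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anova as anova_mod
from . import io as pio
from . import ranktest as rank_mod
from . import synthetic
from .proportions import (
    Stage,
    StageEstimate,
    pooled_proportion,
    proportion_estimate_from_counts,
)
from .susceptibility import integrate_susceptibility, summarize_susceptibility

logger = logging.getLogger("pinebeetle")

__all__ = ["RunConfig", "run_full_pipeline", "stage_estimates_frame",
           "fixture_stage_estimates"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "pinebeetle_out"
    trials_csv: str | None = None   # None -> simulate
    traps_csv: str | None = None    # None -> simulate (two years)
    n_draws: int = 100_000
    n_reps: int = 999
    alpha: float = 0.05
    trap_transform: str = "sqrt"
    use_fixtures: bool = False      # analyse packaged summary tables instead

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_draws < 1 or self.n_reps < 1:
            raise ValueError("n_draws and n_reps must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        # out_dir is a location, not an analysis parameter: runs into
        # different directories must stamp the same hash
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode("utf8")).hexdigest()[:12]


def _substream(seed: int, name: str) -> int:
    """Named 31-bit substream seed derived from the master seed."""
    h = hashlib.sha256(f"{seed}:{name}".encode("utf8")).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# stage estimation helpers


def stage_estimates_frame(trials: pd.DataFrame) -> pd.DataFrame:
    """Per species x stage saturated logit estimates, one row each."""
    rows = []
    for (species, stage), grp in trials.groupby(["species", "stage"]):
        est = proportion_estimate_from_counts(
            int(grp["n_success"].sum()), int(grp["n_exposed"].sum())
        )
        rows.append({
            "species": species, "stage": stage, "k": est.k, "n": est.n,
            "p_hat": est.p_hat, "logit_mean": est.logit_mean,
            "logit_se": est.logit_se, "ci_low": est.ci_low,
            "ci_high": est.ci_high,
        })
    order = {s.value: i for i, s in enumerate(Stage)}
    return (pd.DataFrame(rows)
            .sort_values(["species", "stage"],
                         key=lambda c: c.map(order) if c.name == "stage" else c)
            .reset_index(drop=True))


def fixture_stage_estimates() -> pd.DataFrame:
    """Stage estimates from the packaged pooled counts (all species pooled)."""
    fx = synthetic.load_fixture_tables()
    rows = []
    for stage in Stage:
        k = fx["pooled_stages"][stage.value]["k"]
        n = fx["pooled_stages"][stage.value]["n"]
        est = proportion_estimate_from_counts(k, n)
        rows.append({
            "species": "pooled", "stage": stage.value, "k": est.k, "n": est.n,
            "p_hat": est.p_hat, "logit_mean": est.logit_mean,
            "logit_se": est.logit_se, "ci_low": est.ci_low,
            "ci_high": est.ci_high,
        })
    return pd.DataFrame(rows)


def _estimates_from_frame(df: pd.DataFrame) -> dict[str, list[StageEstimate]]:
    out: dict[str, list[StageEstimate]] = {}
    for _, row in df.iterrows():
        est = proportion_estimate_from_counts(int(row["k"]), int(row["n"]))
        out.setdefault(row["species"], []).append(
            StageEstimate(species=row["species"], stage=Stage.coerce(row["stage"]),
                          estimate=est)
        )
    return out


# ---------------------------------------------------------------------------
# the full run


def run_full_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis; returns the report dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.digest()}
    logger.info("run %s -> %s", stamp["config_hash"], out)

    # --- inputs -----------------------------------------------------------
    if config.use_fixtures:
        est_frame = fixture_stage_estimates()
        trials = None
    elif config.trials_csv:
        trials = pio.read_trials(config.trials_csv)
        _check_trials(trials, config.trials_csv)
        est_frame = stage_estimates_frame(trials)
    else:
        params = synthetic.default_colonization_params()
        records = []
        for stage in Stage:
            records.extend(
                synthetic.generate_colonization_dataset(
                    params, stage, _substream(config.seed, f"sim-{stage.value}")
                )
            )
        pio.write_trials(records, out / "trials.csv")
        trials = pio.read_trials(out / "trials.csv")
        est_frame = stage_estimates_frame(trials)

    est_frame = est_frame.assign(**stamp)
    est_frame.to_csv(out / "stage_estimates.csv", index=False)

    # --- Monte Carlo susceptibility --------------------------------------
    mc_seed = _substream(config.seed, "mc")
    sus_rows = []
    for species, stages in _estimates_from_frame(est_frame).items():
        if len(stages) != 3:
            logger.warning("species %s lacks all three stages; skipped", species)
            continue
        dist = integrate_susceptibility(stages, n_draws=config.n_draws, seed=mc_seed)
        sus_rows.append(summarize_susceptibility(dist))
    sus_frame = pd.DataFrame(sus_rows).assign(**stamp)
    sus_frame.to_csv(out / "susceptibility.csv", index=False)

    # --- traps: ANOVA, outliers, rank concordance -------------------------
    if config.traps_csv:
        traps = pio.read_traps(config.traps_csv)
    elif not config.use_fixtures:
        tp = synthetic.default_trap_params()
        recs = []
        for year in (2013, 2014):
            recs.extend(
                synthetic.generate_trap_dataset(
                    dataclasses.replace(tp, year=year),
                    _substream(config.seed, f"traps-{year}"),
                )
            )
        pio.write_traps(recs, out / "traps.csv")
        traps = pio.read_traps(out / "traps.csv")
    else:
        traps = None

    report: dict = {**stamp, "outputs": {}}
    if config.use_fixtures:
        bark = est_frame[est_frame["stage"] == "bark"].iloc[0]
        report["pooled_bark_entry_pct"] = round(100 * bark["p_hat"], 1)
    point_products = dict(zip(sus_frame.get("species", []),
                              sus_frame.get("point_product", [])))
    report["point_products"] = point_products

    if traps is not None:
        res_anova, letters, rank_result, outliers = _trap_analyses(traps, config)
        _dump_json(out / "anova.json", {**stamp, **res_anova,
                                        "letters": letters.letters,
                                        "omnibus_significant": letters.omnibus_significant})
        _dump_json(out / "outliers.json", {**stamp, "flagged": list(outliers.flagged),
                                           "threshold": outliers.threshold,
                                           "n_total": outliers.n_total,
                                           "p_values": {str(k): v for k, v in
                                                        outliers.p_values.items()}})
        if rank_result is not None:
            _dump_json(out / "ranktest.json", {**stamp,
                                               "d_obs": rank_result.d_obs,
                                               "k": rank_result.k_items,
                                               "n_reps": rank_result.n_reps,
                                               "p_value": rank_result.p_value,
                                               "method": rank_result.method})
            report["rank_p_value"] = rank_result.p_value
        report["trap_anova_F"] = res_anova["F"]
        report["trap_anova_p"] = res_anova["p_value"]
        report["outliers_flagged"] = list(outliers.flagged)

    report["outputs"] = sorted(p.name for p in out.iterdir() if p.is_file())
    _dump_json(out / "report.json", report)
    with open(out / "report.txt", "w", encoding="utf8") as fh:
        fh.write(_render_report(report, sus_frame))
    return report


def _check_trials(trials: pd.DataFrame, path) -> None:
    bad = trials[trials["n_success"] > trials["n_exposed"]]
    if not bad.empty:
        rows = [int(i) + 1 for i in bad.index[:5]]
        raise ValueError(f"{path}: n_success > n_exposed at data row(s) {rows}")


def _trap_analyses(traps: pd.DataFrame, config: RunConfig):
    """Blocked ANOVA + letters, outlier scan, and between-year rank test."""
    res = anova_mod.blocked_anova(
        traps, response="count", treatment="treatment",
        blocks=[b for b in ("site", "week") if traps[b].nunique() > 1],
        transform=config.trap_transform,
    )
    groups = {t: g["count"].to_numpy() for t, g in traps.groupby("treatment")}
    letters = anova_mod.protected_lsd(res, groups, alpha=config.alpha)

    candidates = _suspicious_catches(traps)
    outliers = anova_mod.bonferroni_outlier_scan(
        traps, response="count", treatment="treatment",
        candidates=candidates,
        blocks=[b for b in ("site", "week") if traps[b].nunique() > 1],
        transform=config.trap_transform, alpha=config.alpha,
    )

    rank_result = None
    years = sorted(traps["year"].unique())
    if len(years) == 2:
        rankings = []
        for y in years:
            means = traps[traps["year"] == y].groupby("treatment")["count"].mean()
            rankings.append(rank_mod.rank_treatments(means.to_dict(),
                                                     source_year=str(y)))
        rank_result = rank_mod.permutation_pvalue(
            rankings[0], rankings[1], n_reps=config.n_reps,
            seed=_substream(config.seed, "ranktest"),
        )
    return dataclasses.asdict(res), letters, rank_result, outliers


def _suspicious_catches(traps: pd.DataFrame, z: float = 3.0) -> list:
    """Candidate outliers: counts > z SDs above their treatment mean (sqrt scale)."""
    y = np.sqrt(traps["count"].to_numpy(dtype=float))
    out = []
    for _, grp in traps.groupby("treatment"):
        g = np.sqrt(grp["count"].to_numpy(dtype=float))
        if len(g) < 3 or g.std(ddof=1) == 0:
            continue
        zscores = (g - g.mean()) / g.std(ddof=1)
        out.extend(grp.index[zscores > z].tolist())
    return sorted(out)


def _dump_json(path, payload: dict) -> None:
    with open(path, "w", encoding="utf8") as fh:
        json.dump(payload, fh, indent=2, default=float)


def _render_report(report: dict, sus_frame: pd.DataFrame) -> str:
    lines = [
        "pinebeetle pipeline report",
        f"seed: {report['seed']}  config: {report['config_hash']}",
        "",
        "integrated susceptibility (probability a landing female leaves brood):",
    ]
    for _, row in sus_frame.iterrows():
        lines.append(
            f"  {row['species']:>14}: median {row['median']:.3f} "
            f"[{row['lo95']:.3f}, {row['hi95']:.3f}] "
            f"(point product {row['point_product']:.3f})"
        )
    if "pooled_bark_entry_pct" in report:
        lines.append("")
        lines.append(f"pooled bark entry: {report['pooled_bark_entry_pct']}%")
    if "rank_p_value" in report:
        lines.append(f"between-year ranking concordance p = {report['rank_p_value']:.4g}")
    if "trap_anova_F" in report:
        lines.append(
            f"trap ANOVA F = {report['trap_anova_F']:.3f} (p = {report['trap_anova_p']:.4g})"
        )
    lines.append("")
    return "\n".join(lines)
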