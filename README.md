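# pinebeetle

Statistical machinery for multi-stage host-colonization studies of bark
beetles, built around the mountain pine beetle (*Dendroctonus
ponderosae*) and its historical (lodgepole, ponderosa) and novel (jack,
red, eastern white, Scots) pine hosts.

Colonization of a pine proceeds through discrete behavioral stages:
a female enters the outer **bark**, tunnels into the **phloem**, and
establishes a **brood** gallery. Each stage is scored as a binomial
outcome per assay unit (beetles caged on a log cell, or introduced into
a pre-drilled hole). The package estimates the per-stage success
probabilities on the logit scale, propagates their uncertainty into an
overall **susceptibility** distribution, and provides the supporting
analyses for the attraction and chemistry arms of such a study:

- **Stage estimation** — for k successes out of n, the saturated
  binomial MLE gives `logit p̂ = ln(k/(n−k))` with delta-method standard
  error `SE = sqrt(1/k + 1/(n−k))`; 95% Wald intervals are formed on the
  logit scale and back-transformed (asymmetric about p̂). Binomial GLMs
  (logit link, IRLS) handle covariates such as phloem thickness or
  historical-vs-novel host class, tested by likelihood ratio.
- **Susceptibility integration** — with stage estimates
  (μ_bark, σ_bark), (μ_phloem, σ_phloem), (μ_brood, σ_brood), each Monte
  Carlo draw samples `p_s = logistic(μ_s + σ_s·z_s)` independently per
  stage and multiplies the three; 100,000 draws per species give a
  distribution whose middle 95% (2.5th–97.5th percentiles) summarizes
  how likely a landing female is to leave live progeny.
- **Rank concordance** — treatments (pine species as trap baits) are
  ranked by mean catch within each year; the statistic
  `D = Σᵢ (r1ᵢ − r2ᵢ)²` measures between-year agreement (0 = identical,
  k(k²−1)/3 = reversed). Its null distribution comes from random
  permutations (Monte Carlo with `p = (1+m)/(n_reps+1)`, m the number of
  null statistics ≤ D_obs) or exact enumeration for k ≤ 8.
- **ANOVA tools** — variance-stabilizing transforms (sqrt for trap
  counts and 4-allylanisole, log(y+1) for the other monoterpenes),
  one-way and additive-block ANOVA, exact reconstruction of a balanced
  one-way F from published group means/SEs, Fisher's protected LSD with
  compact letter displays, and a Bonferroni indicator-variable outlier
  scan (flag when the indicator's p < α/N).
- **Synthetic data** — seeded generators reproducing the experimental
  hierarchy (beetles in units in logs/trees; overdispersed
  site×week×treatment trap counts; lognormal phloem chemistry), plus
  packaged summary tables from the motivating study for offline runs.

## Worked example

Integrate the pooled stage outcomes of the motivating study
(532/840 bark entries, 951/1123 phloem entries, 590/840 brood
establishments) into an overall susceptibility distribution:

```python
from pinebeetle import (load_fixture_tables, proportion_estimate_from_counts,
                        integrate_susceptibility)
from pinebeetle.proportions import StageEstimate, Stage

fx = load_fixture_tables()
stages = []
for s in ("bark", "phloem", "brood"):
    d = fx["pooled_stages"][s]
    est = proportion_estimate_from_counts(d["k"], d["n"])
    stages.append(StageEstimate("pooled", Stage(s), est))
    print(f"{s:>7}: p_hat={est.p_hat:.3f}  logit={est.logit_mean:.3f} "
          f"(SE {est.logit_se:.3f})  95% CI ({est.ci_low:.3f}, {est.ci_high:.3f})")

dist = integrate_susceptibility(stages, n_draws=100_000, seed=1)
print(f"susceptibility: median={dist.median:.3f}  "
      f"middle 95% ({dist.lower_2_5:.3f}, {dist.upper_97_5:.3f})  "
      f"point product={dist.point_product:.3f}")
```

prints

```
   bark: p_hat=0.633  logit=0.547 (SE 0.072)  95% CI (0.600, 0.665)
 phloem: p_hat=0.847  logit=1.710 (SE 0.083)  95% CI (0.825, 0.867)
  brood: p_hat=0.702  logit=0.859 (SE 0.075)  95% CI (0.671, 0.732)
susceptibility: median=0.376  middle 95% (0.349, 0.404)  point product=0.377
```

i.e. a beetle that lands on the bark has about a 38% chance (middle 95%:
35–40%) of completing all three stages — well under half, even though
each individual stage succeeds more often than not.

The same fixture bundle reconstructs the published tree-diameter ANOVA
from its printed means and standard errors:

```python
from pinebeetle import anova_from_summary
col = fx["table1"]["2013"]
res = anova_from_summary([col[s]["dbh_mean"] for s in col],
                         [col[s]["dbh_se"] for s in col], n_per_group=4)
print(f"2013 DBH ANOVA: F({res.df_num},{res.df_den}) = {res.F:.2f}, "
      f"p = {res.p_value:.2f}")
# 2013 DBH ANOVA: F(5,18) = 1.46, p = 0.25
```

## Command line

```sh
pinebeetle simulate --seed 1 --out sim/        # trials.csv, traps.csv, chem.csv
pinebeetle stages sim/trials.csv               # per species x stage estimates
pinebeetle ranktest sim/traps.csv --reps 999 --seed 2
pinebeetle anova sim/traps.csv --response count --treatment treatment \
    --blocks site,week --transform sqrt
pinebeetle run --seed 1 --out results/         # full pipeline
```

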