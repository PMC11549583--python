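# pnavax — personal-network analysis of vaccination status

`pnavax` is a reusable pipeline for egocentric (personal-network) studies of
health behavior, built around the question of how a respondent's
health-information media diet relates to the COVID-19 vaccination status of
the people in their social circle. It is aimed at social-epidemiology and
network-science researchers who collect ego-network interview data (egos,
their nominated alters, and ego-reported alter–alter ties) and want a tested,
scriptable path from raw tables to multilevel model estimates.

## What it computes

**Per-alter vaccination assortativity.** For alter *i* in the personal
network of ego *j*, with *i* excluded from both proportions,

```
s_i = (vaccinated fraction of i's network neighbors)
    − (vaccinated fraction of j's other alters)
```

so `s_i > 0` means *i*'s direct contacts are vaccinated above the network's
own leave-one-out base rate. Alters with unknown status are excluded from
numerator and denominator on both sides; isolates have no score (missing,
never zero).

**Structure.** On the binarized alter–alter graph (ego removed): density
m/C(n,2), connected-component counts (isolates are components), and Freeman
shortest-path betweenness normalized by C(n−1,2).

**Two-level models.** A random-intercept logistic regression
Pr(y_ij = 1 | b_j) = logit⁻¹(x_ijᵀβ + b_j), b_j ~ N(0, σ²_ego), fitted by
maximum likelihood with adaptive Gauss–Hermite quadrature. Reported indices:
odds ratios with Wald 95% CIs, the latent-threshold ICC σ²/(σ² + π²/3), and
Nakagawa–Schielzeth marginal/conditional R². A four-model suite (null,
attributes-only, network-only, full) plus a population-averaged logistic GLM
with ego-clustered sandwich SEs (including the leave-one-out vaccinated
proportion as predictor) round out the inferential stage.

**Synthetic studies.** A seeded generator emulates the field design — 15–25
alters per ego, dense cohesive alter graphs, attribute marginals, missing
data, trait-homophilous ties, and assortative link-tracing referral chains —
and records the generating ground truth so estimator recovery is testable.

## Worked example

```python
from pnavax import (GeneratorConfig, generate_study, filter_networks,
                    model_frame, model_suite)
from pnavax.assortativity import assortativity_table

study, truth = generate_study(GeneratorConfig(n_egos=64, seed=42))
kept, report = filter_networks(study, min_alters=15)
print(f"networks: {report.n_networks_in} collected -> {report.n_networks_out} retained")
frame = model_frame(kept)
print(f"model frame: {frame.n_obs} alters in {frame.n_groups} ego networks")
scores = assortativity_table(kept)["score"].dropna()
print(f"mean vaccination assortativity: {scores.mean():+.3f} (SD {scores.std():.3f})")
m4 = model_suite(frame)["m4"]
t = m4.coef_table.set_index("term")
for term in ("media_online", "media_both", "ego_vaccinated"):
    r = t.loc[term]
    print(f"{term:15s} OR {r['or_']:.2f} (95% CI {r['ci_low']:.2f}-{r['ci_high']:.2f}), p={r['p']:.3f}")
print(f"sigma2_ego={m4.sigma2_ego:.2f}  ICC={m4.icc:.2f}  "
      f"R2_marginal={m4.r2_marginal:.3f}  R2_conditional={m4.r2_conditional:.3f}")
```

With this seed the run prints:

```
networks: 64 collected -> 63 retained
model frame: 1320 alters in 63 ego networks
mean vaccination assortativity: +0.008 (SD 0.128)
media_online    OR 0.38 (95% CI 0.15-0.92), p=0.033
media_both      OR 0.87 (95% CI 0.40-1.89), p=0.724
ego_vaccinated  OR 4.96 (95% CI 2.42-10.17), p=0.000
sigma2_ego=0.78  ICC=0.19  R2_marginal=0.825  R2_conditional=0.858
```

Reading this: one network fell below the 15-eligible-alter cohort rule;
alters of egos who rely exclusively on online media for health information
have roughly a third the odds of being vaccinated relative to
traditional-media egos (that is the generator's planted −1.0 log-odds effect
being recovered); alters of vaccinated egos are far likelier to be
vaccinated; and about a fifth of the residual latent variance sits between
egos (ICC 0.19, generated from σ_ego = 0.9).

The same flow is available from the shell:

```
pnavax simulate --profile lerestilike --seed 42 --out data/
pnavax run --egos data/egos.csv --alters data/alters.csv \
           --ties data/ties.csv --referrals data/referrals.csv --out artifacts/
```

`artifacts/` then holds the descriptive summary, per-alter assortativity and
betweenness tables, the filter funnel, tidy model-coefficient CSVs, model
indices (σ², ICC, R²), a forest-plot table, and a manifest of content hashes
(reruns on identical inputs are hash-identical).

## Layout

```
src/pnavax/
  network_model.py   three-table CSV interchange + domain types
  derive.py          media categorization, tie binarization, z-scoring
  structure.py       density, components, normalized betweenness
  assortativity.py   per-alter score, network means, referral concordance
  filtering.py       eligibility, cohort funnel, model frame
  models.py          GLMM (adaptive GH quadrature), ICC, R², robust GLM
  synthetic_data.py  seeded study generator with ground truth
  cli_reporting.py   pipeline orchestration and summary tables
  cli.py             `pnavax` command-line entry point
docs/methods.md      model and generator documentation
```
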