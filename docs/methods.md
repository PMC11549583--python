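# Methods

This note documents the statistical procedures, the synthetic-data
generator, and the numerical choices behind `pnavax`, including where the
design was genuinely open and what the shipped defaults do and do not
capture.

## Data model and derived variables

A study is three linked CSV tables (egos; alters with ego–alter tie
attributes; alter–alter ties) plus an optional referral edge list. Ordinal
answers are canonical lowercase tokens with 1-based numeric codes accepted on
read; missing values are empty cells on disk and `None` in memory, and are
never imputed by the I/O layer. Duplicate undirected ties (both orientations
present) are collapsed with a warning rather than rejected, since interview
data plausibly records both.

Derived variables follow the questionnaire's codings:

* **media category** — `traditional` if the ego's health-information sources
  are a nonempty subset of {central TV, local press}; `online` if a nonempty
  subset of {search engines, social media, influencers}; `both` if the
  sources straddle the two groups; `missing` when no source was recorded.
  `traditional` is the modeling reference level.
* **tie binarization** — any reported alter–alter relationship
  (acquaintance, casual friend, close friend) becomes an edge; absence of a
  report is absence of an edge.
* **ego–alter intensity** — the product of "feels very close" (closeness at
  its top level) and "meets at least twice a month" (every-2-weeks, weekly
  or daily). The boundary places "once a month" at 0.
* **standardization** — z-scores with the sample (n−1) SD by default
  (population SD available via `ddof=0`). Alter-level numerics (age,
  education, betweenness, assortativity) are standardized over the alter
  rows of the final model frame; ego/network-level numerics (age, education,
  size, density, components) over the distinct retained egos, then broadcast.
  Standardizing after cohort filtering matches the modeled sample. Education
  enters as numeric 1–13. Binary indicators and the outcome are never
  standardized. A column with no spread in a given sample (commonly the
  component count when every retained network is connected) has no z-scale;
  it is set to 0 with a warning, and model fits drop constant predictors.

## Structural measures

All structural quantities are computed on the binarized alter graph with the
ego removed (its presence is uninformative by construction). Density is
m/C(n,2) and undefined below two nodes. Components are ordinary connected
components — the alter graph is undirected, so "strong" and weak components
coincide — and isolates count as components. Betweenness is Freeman
geodesic betweenness on the possibly disconnected graph (unreachable pairs
contribute nothing), normalized by C(n−1,2) so scores are comparable across
network sizes; graphs with ≤2 nodes score 0. By default structure is
computed on the full nominated network, before eligibility filtering.

## The per-alter assortativity score

For focal alter *i* of ego *j*: the vaccinated proportion of *i*'s network
neighbors minus the vaccinated proportion of *j*'s other alters, with *i*
excluded from both proportions. Scores live in [−1, 1]; under an exchangeable
(permutation-null) assignment of statuses on a fixed graph the expected score
is 0, and if every known status is equal every defined score is exactly 0.

Open choices resolved here:

* Alters with unknown vaccination status are excluded from the numerator and
  denominator of **both** proportions — this keeps both proportions
  well-defined and unbiased under missingness that is unrelated to position.
* An isolate, an alter whose neighbors all have unknown status, or an alter
  in a network with fewer than two known statuses has a *missing* score with
  a recorded reason — never a silent zero.
* Scores use the binarized graph regardless of tie strength.

Referral-chain concordance treats the chain as directed (referrer →
referred), classifies status-complete dyads into the four ordered status
pairs, and reports the vaccinated→vaccinated share of the complete dyads;
dyads with either status unknown are excluded from the denominator and
counted separately.

## Cohort construction

The analysis sample keeps networks with at least `min_alters` (default 15,
inclusive) alters that have known vaccination status *and* at least one tie.
Eligibility is evaluated once on the original graph; degrees are not
recomputed after removals (no iterative peeling). The model frame is
complete-case: egos with a missing media category are dropped, then any
remaining row missing a model variable. Every dropped row carries a reason,
and retained + dropped rows reconcile exactly with the raw counts. The
leave-one-out vaccinated proportion is computed over the frame's own rows.

## Models

**Random-intercept logistic regression.** The likelihood integrates a
scalar normal ego intercept out of a Bernoulli-logit model. Integration is
adaptive Gauss–Hermite quadrature (default 15 nodes): per group, the mode of
the log-integrand is found by Newton's method (the integrand is log-concave,
so this converges fast), the quadrature grid is recentered at the mode and
rescaled by the local curvature, and group log-likelihood contributions are
combined by log-sum-exp for numerical stability. Optimization is L-BFGS-B
over (β, log σ) from a fixed deterministic start (β = 0, σ = 1) with
tolerance 1e−8, so repeated fits are bit-stable; log σ is bounded in
[−7, 3], and the σ → 0 boundary reduces smoothly to ordinary logistic
regression (verified against `statsmodels.Logit` to < 0.02 on the log-odds
scale, and against `lme4::glmer` with nAGQ = 15 in a cross-check test).
Standard errors come from the inverse observed information (central-difference
Hessian); CIs are Wald on the log-odds scale, exponentiated to odds ratios
(no profile likelihood). Non-convergence is flagged on the result rather
than raised; complete separation of the outcome by a binary predictor (a
zero cell in its 2×2 table with the outcome) raises a diagnostic naming the
predictor. No multiple-testing correction is applied; p-values are
per-coefficient Wald tests.

**ICC and R².** The ego-level intraclass correlation uses the
latent-threshold convention ICC = σ²/(σ² + π²/3), the logistic residual
variance being π²/3. Variance explained follows Nakagawa–Schielzeth:
marginal R² = var(x'β)/(var(x'β) + σ² + π²/3); conditional R² adds σ² to the
numerator, so conditional ≥ marginal always.

**Model suite.** m1 null (intercept + random intercept), m2 attributes only
(alter and ego sociodemographics and media use), m3 network only (intensity,
betweenness, assortativity, size, density, components), m4 the union.

**Cluster-robust GLM.** An ordinary logistic GLM with ego-clustered
sandwich SEs via statsmodels (`cov_type="cluster"` with its default
small-sample degrees-of-freedom scaling; disable with
`small_sample_correction=False`), by default adding the leave-one-out
vaccinated proportion as the fixed-effect stand-in for the random intercept.

**Bivariate companions.** Pearson chi-square tests (alter vaccination ×
ego vaccination; × ego media; ego vaccination × media at the ego level;
assortativity quartiles × media-by-vaccination groups) with exact fallbacks
for sparse tables (Fisher for 2×2; a seeded Monte-Carlo permutation p
otherwise), and two-sided pooled-variance t tests of the unstandardized
assortativity score by alter and by ego vaccination.

## Synthetic-data generator

The generator draws whole studies from one seeded NumPy generator, so a
config is a complete, reproducible description of the conditions. Defaults
(the `lerestilike` profile — entirely synthetic) mirror the emulated field
study's marginals: 83 egos; alter counts concentrated at 24–25 with a tail
at 15–23 (mean ≈ 24.4); ego age N(53.33, 15.86²) truncated to ≥18; 52%
female; education a discretized normal on the 1–13 grid (mean 9.70,
SD 1.78); 78% of egos vaccinated; media categories 17/34/49% for
traditional/online/both among respondents, ~3.6% missing; alter marginals
analogous; alter vaccination missing at 11.3%; per-network edge probability
Beta-distributed with mean 0.65 and SD 0.21.

Alter vaccination is assigned by the two-level logistic model itself —
intercept, attribute and media coefficients, plus an ego intercept
b_j ~ N(0, σ²_ego) with σ_ego = 0.9 — so estimator recovery can be scored
against known truth. Numeric covariates enter the generating linear
predictor standardized by their configured marginal mean/SD, making
generating and fitted coefficients directly comparable.

**Assortativity mechanisms.** Two are provided:

* *Tie homophily* (default, Δ = 0.22): concordant alter pairs get tie
  probability d + Δ(1−w) and discordant pairs d − Δw, where w is the
  realized share of concordant pairs, holding expected density at d. This is
  a planted-partition-by-trait graph and is the mechanism that produces a
  positive per-alter score at the study's density.
* *Contagion* (off by default): synchronous rounds that add
  strength × (neighbor vaccinated fraction − ½) to the linear predictor and
  redraw. Implementation experiments show this mechanism moves the
  per-alter score only in sparse networks with an imbalanced base rate; at
  density 0.65 an alter's neighborhood nearly coincides with the whole
  network and the score's leave-one-out construction cancels the shift.
  The property tests therefore exercise contagion at density 0.2 with a 70%
  base rate, where its positive effect is Monte-Carlo separable from zero.

With Δ = 0.22 the default profile yields a mean per-alter score ≈ +0.008
(SD ≈ 0.13): positive and small, the same sign and order as the emulated
study's 0.02 (SD 0.11). The residual gap traces to the wide spread of
network-level base rates (ego intercepts and media effects push many
networks toward extreme vaccination shares where the score compresses).
Because homophily ties the score directly to the focal alter's own status,
the fitted assortativity odds ratio under the default profile is much larger
than in typical field data; the profile is a test harness for the pipeline's
statistical machinery, not a calibrated digital twin.

**Link tracing.** Recruitment starts from 6 seeds (seeds always refer, even
when refusing, as field seeds sometimes do); each participant nominates 1–3
not-yet-approached egos, concordant with the referrer's vaccination status
with probability 0.76; nominees refuse with probability 0.458 (chosen so the
simulated response rate sits near 54%). Chains truncate, with a flag, when
the population is exhausted.

What the generator does **not** emulate: joint dependence between ego
attributes (attributes are drawn independently), name-generator behavioral
biases (e.g. egos projecting their own status onto alters), alters shared
between egos (alters are ego-scoped), and any within-community geography.
Passing tests on synthetic data therefore demonstrate the pipeline's
correctness and the estimators' statistical behavior under the stated
conditions, not the faithfulness of any particular field dataset.

## Problem sizes in the test suite

Property tests use exhaustive enumeration where cheap (all labeled graphs on
≤5 nodes; all 31 media-source subsets) and seeded sampling elsewhere
(n = 6–7 graphs against a path-enumeration oracle; 3000 label permutations
for the assortativity null). Parameter recovery runs 50 replicates of 200
egos × 25 alters with a planted online-media log-odds of −1.0 and
σ_ego = 0.9, asserting mean absolute bias < 0.15; marginal-fidelity checks
run one study of 500 egos within 3·SE bands. These sizes were chosen to give
stable Monte-Carlo margins while keeping the full suite around a minute.

## Known limitations

* The GLMM supports a single scalar random intercept (no random slopes,
  crossed or nested designs) — sufficient for the two-level design it serves.
* Wald inference only; profile-likelihood or bootstrap CIs are not provided.
* The exact-test fallback for r×c tables is Monte-Carlo, not network
  permutation; it conditions on one margin only.
* Structural measures are computed on the full nominated network and
  eligibility on the original graph; the alternative orderings (recomputing
  structure or degrees after dropping ineligible alters) are not implemented,
  as nothing downstream requires them.
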