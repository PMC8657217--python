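# Methods

`ahmdisparity` implements a county-level analysis of Black/African-American
(BAA) vs non-Hispanic-White (nHW) disparities in antihypertensive-medication
(AHM) non-adherence and their relation to heart-disease (HD) and stroke (ST)
mortality. It has three analytic layers — a prevalence-rate-ratio (PRR)
disparity index, a hierarchical-linear-model (HLM) sequence with a
variance-component pseudo-R², and a Bayesian shared-component factor model —
plus a synthetic-data generator that produces county tables with known ground
truth so every layer can be validated by parameter recovery.

## Data model

One row per county, keyed by a 5-digit FIPS string, with state and census
region membership; race-specific AHM non-adherence prevalence in percent
(non-adherence defined as proportion of days covered below 80%); four
determinants-of-health composite scores (health behaviors `hb`, clinical care
`cc`, social & economic `se`, physical environment `pe`); demographic
confounders (% BAA, % ≥ 65, % female, % rural); and four race-specific
mortality rates per 100,000 (BAA-HD, BAA-ST, nHW-HD, nHW-ST), strictly
positive so logs are defined. Rates of exactly zero are rejected with an
error naming the county — no continuity correction is invented.

## Disparity index

The county PRR is BAA prevalence divided by nHW prevalence; values above 1
disadvantage BAAs. The overall and per-region summary is, by default, the
geometric mean of county PRRs with a t-interval on mean log-PRR. The
aggregation is a genuinely open design choice — a reported overall PRR could
equally be an arithmetic mean of ratios or a ratio of pooled prevalences, and
the CI analytic or bootstrap — so `method="arithmetic"` and `"pooled"` are
selectable; the geometric default is preferred for its log-scale symmetry
(swapping the race columns inverts every estimate exactly) and defensible
interval. Counties are unweighted. Counties missing either prevalence are
excluded and counted, never silently dropped.

## Hierarchical linear models

The county PRR (natural scale by default; log-PRR available) is regressed on
county covariates with a state random intercept:

    y_i = x_i' β + u_{s(i)} + ε_i,   u_s ~ N(0, σ²_state),  ε ~ N(0, σ²_resid)

in the four-model sequence M1 (one domain score), M2 (+ % ≥ 65), M3 (all four
domain scores), M4 (all four + the demographic confounders). Estimation is
maximum likelihood (not REML) so variance components are comparable across
nested fixed-effect rosters; REML is an option. Covariates are standardized
(sample sd, ddof = 1) by default. The pseudo-R² is the Snijders–Bosker-style
proportional reduction in total variance against the intercept-plus-random-
intercept null:

    R² = 1 − (σ²_state + σ²_resid)_full / (σ²_state + σ²_resid)_null.

Numerical notes: the backing optimizer matters — L-BFGS can spuriously park
σ²_state at the zero boundary, so fits try BFGS, then Powell, then CG; if all
fail with a singular information matrix the variance component is a true
boundary case and the fit falls back to OLS (σ²_state = 0) with a warning.
Exactly collinear designs raise an error naming the offending columns. A
noise-free outcome (exact linear fit) is detected up front and reported with
zero variance components. Significance stars follow a two-level convention
(* p < 0.05, ** p < 0.001).

## Bayesian shared-component factor model

The four log mortality rates are modeled jointly:

    y_{i,r,d} = x_{i,r,d}' β_{r,d} + λ_{r,d} f_{i,r} + κ_{r,d} g_{s(i)} + ε_{i,r,d}

* `f_{i,r}` — county-level latent factor per race, shared by that race's two
  disease outcomes, bivariate normal across races with sds σ_{f,r} and
  correlation ρ (unmeasured county conditions that races may experience
  differently, but correlated within a county);
* `g_s` — state-level latent factor shared by all four outcomes, N(0, σ²_g);
* loadings scale each factor per outcome, with λ_{r,HD} = 1 per race and
  κ on the BAA-HD outcome fixed at 1 for identifiability (the factors are
  scaled to the heart-disease outcome); the remaining loadings are free.
  An alternative reading — both loadings free with the factor variance
  fixed — is not the default but can be emulated via the prior settings;
* ε — outcome-specific Gaussian residuals. These are retained alongside the
  factors deliberately: with only two latent factors per observation the
  four-outcome likelihood would otherwise be degenerate.

Covariates: the race-matched non-adherence prevalence (no cross-race terms),
the four domain scores, and the four demographic confounders, all
standardized to mean 0 / sd 1. The moderation (interaction) variant adds
non-adherence × domain-score products; each product is built from the
standardized mains and then itself standardized, so reported moderation
effects are per 1-sd increase of the interaction column (the raw-product
alternative is selectable).

Priors (weakly informative at log-rate scale, all exposed in config):
coefficients and free loadings N(0, 10²); all sds half-normal(1);
ρ uniform(−1, 1).

### Posterior computation

Inference is by a purpose-built MCMC sampler (numpy): coefficients, factors
and the translation directions below have conjugate Gaussian full
conditionals; scales, loadings and ρ are updated by stepping-out/shrinkage
slice sampling. Three structural devices — all exact MCMC moves — are
essential for mixing in this model class:

1. **Partially collapsed updates.** Integrating the county factors out gives
   each county's residual 4-vector an iid N(0, V) law with
   V = LΣ_fL' + diag(σ²) shared across counties; integrating the state factor
   out as well needs only per-state residual sums. All scale, loading and
   correlation parameters are slice-sampled under this collapsed likelihood
   (sufficient statistics E'E and state sums, so each evaluation is O(S)),
   and the latent factors are redrawn afterwards. Naive Gibbs on the
   uncollapsed conditionals stalls in the classic variance–latent funnel and
   can let the correlated county factors swallow the state signal.
2. **Translation moves** between the intercepts and the latent-factor means
   (exact Gaussian conditional along a likelihood-invariant direction).
3. **Scale-group moves** (generalized Gibbs with the Haar-measure
   correction) along the σ_g/κ and σ_f/λ ridges, where the likelihood
   depends mainly on products of a scale and its loadings.

Coefficients for all four outcomes are drawn jointly with the county factors
integrated out (block precision W[o,q]·X_o'X_q, W = V⁻¹), which decouples
them from the factor draws. Scale parameters are floored at 1e-6 so
noise-free degenerate inputs remain tractable. Chains are initialized from
per-outcome ridge OLS with small multiplicative jitter; defaults are 4 chains
× 2000 retained draws after 1000 warm-up iterations. Determinism: every
chain's generator derives from the user seed via `SeedSequence.spawn`, so the
same spec and seed reproduce draws bit-for-bit.

The sampler's correctness is checked by simulation-based calibration in the
test suite: 50 datasets drawn from the model's own (tightened) priors are
refit and the posterior ranks of the generating values are tested for
uniformity (χ², rejection level 0.01), alongside recovery tests at the
default scenario and a factorization check (with ρ = 0 and no state factor
the joint fit must match independent per-race fits).

### Summaries and diagnostics

Each parameter is reported as posterior mean, central 95% credible interval
(2.5/97.5 percentiles) and P(effect > 0), which is by construction the exact
fraction of retained draws above zero. Per county × race the latent-factor
posterior mean and P(> 0) are accumulated during sampling (running sums, not
stored draws); per county and disease the BAA−nHW difference in the estimated
log rate (linear predictor including factors, excluding residual noise) is
summarized the same way — these tables are the data behind choropleth-style
disparity maps, whose rendering is out of scope. Convergence: split-R̂ and
bulk ESS per sampled parameter via arviz; a fit is flagged converged when
max R̂ < 1.05 and min ESS > 200, and flagged non-converged (returned, never
suppressed) when any R̂ exceeds 1.1. Constrained loadings are reported as
constants and excluded from the diagnostics.

## Synthetic-data generator

The generator emulates the linked county surveillance/health-rankings schema
at realistic scale: 38 states, 875 counties (split as evenly as possible
across states), region quotas weighted toward the South (53/21/13/13% of
states for South/Midwest/Northeast/West) to mimic where race-specific rates
are releasable. Domain scores are multivariate normal with means
(0.06, 0.02, 0.21, 0.18) and sds (0.68, 0.56, 0.69, 0.39); the inter-domain
correlation (0.4) is a generator choice — composite-score construction is
out of scope here, so only the means/sds anchor the marginal laws.
Demographics are independent clamped normals at the same descriptive
means/sds. Non-adherence is linear-Gaussian on the percent scale (BAA
intercept 34.6 = 25.5 + gap 9.1) with domain-score coefficients, a state
random intercept and county noise, clamped to (1, 99)%; a logit-scale option
exists. The generative law for prevalence is a modeling choice — only the
observed quantity (PDC < 80% prevalence) is defined in the source data — and
the linear-Gaussian default keeps the PRR truth analytically computable.
Log mortality rates are generated from exactly the factor model above
(Gaussian on the log-rate scale, not Poisson counts, matching the modeled
quantity), with covariates standardized by the realized sample mean/sd so
generator truth and fitted coefficients share a scale. Mortality defaults:
intercepts (5.45, 3.95, 5.20, 3.70) on the log rate-per-100,000 scale
(≈ 233/52 HD/ST per 100,000 for BAAs, 181/40 for nHWs), non-adherence effect
0.05 per sd on every outcome, σ_f = 0.3 per race, ρ = 0.5, σ_g = 0.2, free
loadings (0.8, 0.8) county / (0.7, 0.9, 0.6) state, residual sd 0.1.

What the generator does *not* emulate: spatial adjacency beyond the state
factor (no CAR structure), heavy-tailed or skewed score distributions,
missingness, population-size-dependent rate noise, and the construction of
composite scores from raw indicators. Passing recovery tests therefore show
the estimators are correct under the model's own assumptions at realistic
scale — not that those assumptions hold in any real linkage.

## Pipeline

`pipeline.run` drives simulate → prr → hlm → jointmodel → report from a
single config (YAML-loadable), writing each stage's outputs plus a
`manifest.json` with SHA-256 hashes, the config echo, seed and version.
Reruns with the same config and seed reproduce every output, MCMC included.
The report embeds the disparity table, the M1–M4 coefficient table with
pseudo-R², the main-effect and moderation posterior tables, convergence
diagnostics, and — for synthetic runs — a truth-vs-estimate recovery table
flagging any generating value outside its 95% credible interval. The exact
standardization constants are recoverable from the fitted model
(`standardization_`), since coefficients are only interpretable relative to
them. In strict mode the CLI exits nonzero if any stage fails or a
convergence flag trips.

## Problem sizes used in the checks

The shipped validation uses 875 counties / 38 states for the disparity and
HLM stages (200 replicates for interval coverage; 2000–5000 counties for
variance-share checks), 400 counties / 20 states for joint-model recovery,
800 counties for moderation recovery, and 40-county replicates for
simulation-based calibration. These sizes were chosen so each check's
Monte-Carlo error is small relative to the tolerance it asserts.

## Known limitations

* County-level (ecological) associations only; nothing here supports
  individual-level inference.
* The state factor is the only spatial structure; adjacency-based smoothing
  is out of scope.
* The HLM outcome is the PRR on its natural scale by default; the source
  tables do not state the scale, and log-PRR is provided as an option.
* Aggregated PRR intervals assume independent counties; with a strong state
  component in prevalence the t-interval is anticonservative.
* MCMC defaults are tuned for hundreds of counties; for thousands, expect
  runtimes of minutes and consider fewer chains for exploration.
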