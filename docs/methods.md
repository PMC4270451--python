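# Methods

This note documents the statistical models implemented in `hetmeta`, the
algorithms used to fit them, the synthetic data the tests run on, and the
design decisions taken where more than one reasonable choice existed.

## Effect sizes

Each study contributes a standardized mean difference (arm 1 minus
arm 2, arm 1 experimental) with Hedges' small-sample correction
J = 1 − 3/(4(n₁+n₂−2) − 1) and sampling variance

    v = (n1+n2)/(n1 n2) + g^2 / (2 (n1+n2−3.94)),

the convention used by Cochrane's RevMan software.  Cohen's unadjusted d
(variance denominator 2(n₁+n₂−2)) is available via
`bias_correction=False`; for the study sizes typical of this domain the
two differ by a few percent.  Studies with a missing or zero SD, or an
arm with fewer than two participants, are excluded at load time (the SMD
and its variance are undefined for them), then within-meta-analysis
duplicates (studies repeated across non-exclusive subgroups) are dropped,
then meta-analyses reduced to fewer than two studies, then meta-analyses
with an unclassifiable ("other") outcome type.  The order matters for the
exclusion accounting and is fixed; the load report proves each input row
is attributed to exactly one rule.

## Conventional analysis

`hetmeta.classical` implements Cochran's Q, the DerSimonian–Laird moment
estimator τ̂² = max(0, (Q − (k−1))/C), the pooled SMD with normal-theory
CI under weights 1/(v + τ̂²), I² = max(0, (Q−(k−1))/Q)·100, and the
Q-profile interval for τ²: the bounds solve Q_gen(τ²) = χ²_{k−1}
quantiles by bisection.  Numerical choices: the bracket for the upper
bound starts at τ² = 100 (far beyond anything plausible on the SMD
scale) and doubles until it straddles the root; the bisection stopping
rule is |Δτ²| < 10⁻⁸·max(1, τ²) — the relative term matters because for
k = 2 the upper bound can exceed 10⁷, where an absolute 10⁻⁸ is finer
than float64 spacing.  One test cross-checks Q, τ̂², I², the pooled
estimate and the Q-profile interval against R's `metafor` as an
independent reference implementation.

## Hierarchical model for heterogeneity

The core model couples a random-effects meta-analysis within each
meta-analysis *j* to a regression across meta-analyses:

    y_ij     ~ N(theta_ij, v_ij)          (v_ij treated as known)
    theta_ij ~ N(mu_j, tau^2_j)
    log tau^2_j = alpha + x_j' b + u_k(j) + eps_j
    eps_j ~ t5(0, sigma^2_o(j)),   u_k ~ N(0, kappa^2_c(k))

x_j holds 0/1 indicators with reference categories *general
health-related* (outcome), *nonpharmacologic vs any* (comparison) and
*cardiovascular* (area); categories absent from a collection get no
coefficient.  Heavy-tailed t₅ residuals absorb occasional extreme
heterogeneity; residual scale varies by outcome type and the
comparison-level random effect u_k has a variance per comparison type.
The comparison-level effects are given a *normal* distribution — the t₅
is reserved for the residual — an interpretive choice.
Review-level clustering beyond u_k is not modelled.

Priors: all regression coefficients N(0, sd 10) — read as "vague
normal(0,10)" with 10 the *standard deviation*; `coef_prior_interpretation`
offers variance-10 and precision-10 readings for sensitivity.  Each
variance component (κ²_c, σ²_o) gets inverse-gamma(0.1, 0.1) applied to
the variance.  Summary effects μ_j get N(0, sd 10) — SMDs essentially
never exceed ±5.

### Sampling

Everything is conjugate (θ, μ, coefficients, u_k, the Gamma(5/2, 5/2)
mixture weights λ_j representing the t₅, κ², σ²) except log τ²_j, which
is updated by slice sampling (step-out width 2 on the log scale, no
tuning parameters, reproducible under a seed).  Two points matter in
practice:

* **Blocked update for (log τ²_j, θ).**  The naive Gibbs pair is a
  funnel: small τ² shrinks θ to μ, which keeps τ² small.  The sampler
  instead draws log τ²_j from its conditional with θ integrated out
  (y_ij | μ_j, τ²_j ~ N(μ_j, v_ij + τ²_j)) and then redraws θ — a valid
  partially collapsed scheme that removes the stickiness (observed R̂
  dropped from ~2 to <1.1 at equal chain lengths).
* **Support window.**  log τ² is truncated to [−60, 60].  In regions
  where the likelihood is flat (τ² far below every v_ij) an unbounded
  random walk can underflow exp(); the truncation is numerically
  necessary and statistically inert at e^±60.

Defaults follow the reference analysis (2 chains, 10,000 burn-in, 50,000
kept); the pipeline's desk-scale default is 2 × (2,000 + 2,000).
Convergence is monitored with the Brooks–Gelman–Rubin statistic on all
top-level parameters; the pipeline fails fast at R̂ ≥ 1.05 unless
overridden.

If a factor's designated reference category is absent from a collection
(common at desk scale: cardiovascular reviews are ~7% of reviews), the
design is releveled to the most frequent observed category, with a
warning and a record in `DesignInfo.factor_references`; genuinely
confounded designs still raise an error naming the offending columns.

### Outputs

* **Variance ratios** per category: median and central 95% interval of
  exp(coefficient draws); the reference category is reported as 1.
* **DIC** with study-level likelihood focus: deviance
  −2 Σ log N(y_ij | θ_ij, v_ij), pD = D̄ − D(θ̄).  Model comparison uses
  the same focus across models.  Two comparators are provided: the same
  regression with normal residuals (the log-normal model), and an
  inverse-gamma model τ²_j ~ IG(a, b) shared across meta-analyses with a
  conjugate update for b and a slice update for a.  The IG comparator is
  deliberately minimal: its purpose is the directional contrast (a log-t
  data-generating process should favour the log-t model), not a faithful
  reconstruction of any particular alternative.
* **Predictive draws** of τ²_new for a setting: per posterior draw,
  log τ²_new = α + x_s'b + N(0, κ²_c) + t₅(0, σ²_o), exponentiated.

## Parametric prior approximations

`fit_log_t` matches quantiles: location = median of log τ² samples,
scale = central 95% width / (2 t₅,₀.₉₇₅), df fixed at 5.  Quantile
matching is used instead of moments because t₅ has no finite fourth
moment and predictive samples of log τ² are heavy-tailed.  `fit_inverse_gamma`
minimises the squared error between model and empirical (0.025, 0.5,
0.975) quantiles (Nelder–Mead on log parameters from several starts,
tolerance 10⁻⁸), normalised by the empirical median so the objective is
scale-free.  On this raw-quantile scale the upper tail dominates, so the
fitted IG reproduces the 97.5% quantile closely even for heavy-tailed
log-t input (within ~20% in tests) at some cost to the lower quantile —
the right trade-off for a prior meant to control how much mass is given
to large heterogeneity.

The shipped registry contains the published log-t parameters for all 24
outcome × comparison cells plus the general setting, with per-row
annotations: printed medians were derived from MCMC predictive samples
and can differ from exp(location) in the third decimal (`median_tol`
records by how much), one cell's scale was printed with a stray negative
sign (stored positive), and the mental-health/nonpharmacologic cell
prints a median (0.058) inconsistent with its own location
(exp(−3.85) ≈ 0.021); that row carries a `discrepant` flag and is
excluded from the registry-consistency test.  Cancer and
respiratory-disease settings raise an explicit use-with-caution error
rather than silently serving a prior.

## Single meta-analysis Bayesian model

`hetmeta.bayes` fits y_i ~ N(θ_i, v_i), θ_i ~ N(μ, τ²), μ ~ N(0, sd 10),
with τ² priors: log-t (location, scale, df 5), inverse-gamma (conjugate
update), uniform(0, U) on τ, half-normal on τ.  "Half normal (0, 10)" is
interpreted with 10 as the *variance* of the underlying normal
(sd ≈ 3.16); the sd reading is selectable.  The same collapsed slice
update is used for the non-conjugate priors.  Reported quantiles pool
all post-burn-in draws across chains; a run is flagged converged when
all BGR values are below 1.05.

## Synthetic data

The generator emulates the source database's structure: reviews contain
1 + Geometric(0.46) comparisons; comparisons contain 1 + Geometric(0.30)
meta-analyses; meta-analyses contain 2 + Geometric(0.30) studies (median
3, IQR 2–5); total sample sizes are lognormal with median 61 and log-sd
1.07 (IQR ≈ 30–125), split binomially between arms with at least 4 per
arm.  Settings are sampled from the observed marginal frequencies
(area per review, comparison type per comparison, outcome per
meta-analysis).  Heterogeneity follows the hierarchical model itself with
defaults α = −3.4, contrasts 0, κ²_c = 0.6 and σ²_o = 3.6 — calibrated
once so the marginal sd of log τ² (≈ 2.57) matches the general-setting
predictive scale 2.59.  Summary effects are N(0, 0.4²).  Arm-level data
are simulated with unit true SDs (sampled SDs are χ²-scaled), so the
computed SMD is a noisy estimate of the true θ_ij; 2.4% of studies lose
an SD at random, exercising the filtering rules.  Under these defaults
the DerSimonian–Laird estimate is zero for ~43% of meta-analyses,
matching the descriptive behaviour of the real database.

What the generator does *not* emulate: editorial clustering of reviews
within review groups, publication bias, correlated outcomes within a
review, and non-normal raw outcome data.  Passing recovery tests
therefore demonstrate correctness of the machinery under the model's own
assumptions, not robustness to their violation.

## Identifiability at desk scale

With a median of 3 studies per meta-analysis and within-study variances
around 0.07, the likelihood for an individual log τ²_j has essentially
only an upper edge: values far below log v are indistinguishable.  The
full hierarchy is still calibrated — across 20 replicate fits of
200-meta-analysis collections, 95% credible intervals for the regression
coefficients covered the generating values 94.9% of the time — but
posteriors for the intercept are wide and left-skewed, so point
recovery of the predictive median at that scale is poor (roughly a
factor of two).  Tests that check the *wiring* of
generate → fit → predict → approximate therefore use a better-identified
design (150 homogeneous-setting meta-analyses with ~14 larger studies
each), where the recovered predictive median lands within a few percent
of truth.  The same identifiable design is used for the DIC model
comparison, since at the weakly-identified default scale the study-level
deviance barely distinguishes heterogeneity models.

## Known limitations

* Within-study variances v_ij are plugged in as known, as is standard;
  for very small studies this understates uncertainty.
* The inverse-gamma comparator is a single shared IG(a, b) without
  covariates; the DIC contrast with it is directional evidence only.
* The registry covers the SMD scale only; converting a prior to the
  mean-difference scale requires an external estimate of a typical
  within-study SD and is out of scope.
* Appendix-only prior sets (cancer, respiratory, the published IG
  library) are not shipped; requesting them raises an explicit error.
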