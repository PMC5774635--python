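# Methods

## Scope and data structure

The package operates on the canonical limited-IPD evidence structure:
one two-arm *AB* trial with patient-level data (arm label, outcome,
covariates; complete cases enforced at load with dropped rows logged)
and one *AC* trial known only through published aggregates — per-arm
sample sizes and summary outcomes (event counts or means with SEs) and
trial-level covariate summaries (mean/SD for continuous covariates,
proportions for binary ones). Covariate *roles* (effect modifier,
prognostic, or both) and the moments to match (mean only, or mean and
variance for continuous covariates) are declared a priori in
configuration, never inferred from data: effect-modifier status is a
clinical judgement specific to the chosen scale.

All relative effects live on a declared linear-predictor scale with
link `g` ∈ {identity, log, logit}. The fitted and comparison scales are
forced equal — mixing them breaks additivity and makes the contrast
uninterpretable — and every result object carries its scale, its
anchoring status and an explicit target-population label.

## MAIC weights

With covariate moments centered at the aggregate targets
(`z_i = x_i − x̄_target`, plus `x_i² − (x̄² + sd²)` columns for
variance-matched covariates, using `E[X²] = μ² + σ²`), the
method-of-moments coefficient is the minimiser of the strictly convex
`Q(α) = Σᵢ exp(αᵀzᵢ)`, pooled over both AB arms. At the optimum the
weighted mean of every matched moment equals its target exactly; the
intercept of the log-linear enrolment model is never estimated because
it cancels from all weighted averages. Weights are reported normalised
to sum to N.

Numerics: columns are standardised to unit scale before optimisation
(mixed-unit covariates otherwise condition the Hessian badly) and the
coefficient is transformed back afterwards. The solver is damped Newton
with analytic gradient and Hessian and backtracking line search, with a
BFGS pass on the bounded dual `log Σ exp` plus full-Newton polishing as
fallback; convergence requires the balance residual (the weighted mean
of each centered column) below 1e-11 in infinity norm, and failure
raises a diagnostic including the coefficient-norm trajectory, which
grows without bound when the target sits at the edge of the covariate
support. Targets outside the observed support are refused up front — no
weight set can balance them — and collinear moment columns are dropped
by rank-revealing QR with a warning naming them.

Entropy balancing ("keep weights as close to uniform as possible
subject to the same moment constraints") is implemented independently
through its Lagrangian dual, `min_λ log Σᵢ exp(λᵀzᵢ)`. Both programs
characterise the same exponential-family weight set, so their solutions
coincide; the agreement (checked to 1e-6 against each other and against
a primal constrained optimiser) is used as a correctness check rather
than treated as two methods. Since the weight vectors are identical,
both share the same variance machinery.

Diagnostics report the weight distribution (quantiles, top-5 shares,
histogram), the Kish effective sample size `(Σw)²/Σw²` pooled and per
arm, and the caveat that this approximation assumes fixed, known
weights and is likely to underestimate the true ESS. An ESS below 10%
of N is flagged. Weights are reported, never trimmed.

Anchored weighting matches *all* declared effect modifiers (imbalanced
or not) and *no* purely prognostic covariates — matching prognostics is
over-matching that costs precision without removing bias — while
unanchored weighting must match everything. These rules are enforced as
warnings, with covariate selection always visible in the output. When
no covariate qualifies for matching, the weights are uniform and the
anchored comparison reduces exactly to the standard one, the designed
"no adjustment" null behaviour.

## STC outcome regression

The interaction model
`g(μ_t(X)) = β₀ + β₁ᵀX + (β_B + β₂ᵀX_EM)·1{t=B}` is fitted by maximum
likelihood (OLS for continuous outcomes on the identity scale; binomial
GLM with logit, log or identity link for binary outcomes, via
statsmodels), with the full covariate vector in the prognostic term and
interactions on the declared effect modifiers only. Separation and rank
deficiency are hard errors naming the offending structure; AIC,
deviance and the coefficient covariance are retained. An optional
`center_at_target` mode recenters covariates at the target means so the
fitted B-main-effect is directly the target-population effect; the
default keeps the raw parameterisation.

Two prediction routes produce `Ŷ_A(AC), Ŷ_B(AC)`:

* **plug-in** substitutes mean covariate values. Under a non-identity
  link this is systematically aggregation-biased (the mean outcome
  depends on the whole covariate distribution, not its mean), so the
  result always carries a mandatory bias warning on such scales.
* **simulation** draws `X*` from a Gaussian copula with the target
  marginals (normal for continuous, thresholded-normal Bernoulli for
  binary) and a correlation matrix, by default the AB Pearson
  correlations — the aggregate publication reports no correlations, so
  they are imputed from the IPD. Predictions are averaged over draws
  (default 1e5, floor 1e4, seed required). The Monte-Carlo SE of the
  average is printed so the user can verify it is negligible but is not
  folded into the comparison SE; treating simulation noise as
  statistical uncertainty would double-count what more draws remove.

Tetrachoric-versus-Pearson treatment of binary-covariate correlations
is deliberately not modelled; the copula uses Pearson correlations
throughout.

## Comparisons, transport, absolute effects

Within-trial effects are `g(ȳ₁) − g(ȳ₀)` with delta-method SEs
(`dg(ȳ)·se(ȳ)` per arm, arms independent); binary arms at 0 or n events
receive a logged 0.5 continuity correction. The standard (Bucher)
comparison subtracts the AB effect from the AC effect and sums
variances; its population label is set to `assumed-constant` to keep
the constancy assumption visible. Anchored population-adjusted
comparisons replace the AB effect with the predicted-in-AC effect, with
the AB-side SE supplied by the sandwich (MAIC) or the coefficient
covariance (STC) and the AC-side SE from the published summaries,
treated as independent across trials. Unanchored comparisons are
refused while an anchored route is declared available, and always carry
the conditional-constancy-of-absolute-effects warning with the note
that residual bias is unquantified.

Transport relabels a contrast to another population only under the
shared effect modifier assumption for a declared treatment set
containing both treatments of the contrast (`d_tu(P) = d_tu(Q)`); the
operation is idempotent and attaches a justification-required warning,
since the assumption is a clinical claim (plausible within a treatment
class), not a testable one. Absolute effects back-calculate
`Ŷ_t(P) = g⁻¹(g(Ȳ_A(P)) + Δ̂_At(P))` from a user-supplied baseline for
A in the target population; the baseline's SE is user-supplied (how to
quantify registry baselines is out of scope) and treated as independent
of the contrasts.

Normal-theory 95% CIs are formed on the linear-predictor scale and
back-transformed endpoint-wise for natural-scale reporting.

## Variance estimation

Weights estimated from the data are not fixed constants. The MAIC
sandwich stacks the estimating equations — moment balance for the
weight coefficients (arms pooled, matching the fitting convention) and
weighted-mean equations for the two AB arm means — and applies
M-estimation: `Var = A⁻¹ B A⁻ᵀ` with `A` the Jacobian and `B` the
outer-product matrix of the per-patient scores, then the delta method
for `g(μ̂_B) − g(μ̂_A)`. With zero matched moments it reduces exactly to
the classical robust SE of each arm mean. Whether the two arms' weight
models should be stacked jointly or separately is a convention; the
pooled form matches the pooled fitting objective used here.

The bootstrap resamples AB patients with replacement within arm,
redraws the AC summaries parametrically (binomial counts for binary
outcomes, normal for continuous summaries), and reruns the entire
pipeline per replicate, with per-replicate RNG streams spawned from the
master seed so results are independent of execution order. Replicates
whose weight fit fails are dropped and counted; more than 10% failures
aborts. Percentile and normal CIs are both reported (default 1000
replicates, floor 200). Sandwich and bootstrap agree within ~10% at
N=1000/arm in the calibration study, and 95% CIs achieve nominal
coverage there.

## Simulation harness

Scenarios draw both trials from
`g(μ) = β₀ + β₁ᵀX + (d_t(0) + γ_tᵀX_EM)·1{arm=t}` with per-population
covariate means, Gaussian-copula correlations, Gaussian residuals
(continuous) or Bernoulli outcomes (binary). The AC trial is simulated
at finite size and reduced to aggregates, so AC sampling noise is
present as in practice. Truths are analytic on the identity scale
(`d_AB(pop) = d_AB(0) + γ_Bᵀ E[X_EM|pop]`) and obtained by 1e6-draw MC
integration of arm-average outcomes on other scales, with the
integration error reported.

The replication engine reruns each estimator (Bucher, anchored MAIC
by moments or entropy, anchored STC by plug-in or simulation, and the
unanchored variants including deliberately mis-specified
"omit" versions) across replicates and reports bias with its MC error,
empirical SE, mean reported SE, CI coverage, mean ESS and failure
counts. Unbiasedness assertions use `|bias| < max(0.02, 2·MC error)`:
the floor acknowledges that weighted (ratio) estimators carry an
O(1/N) finite-sample bias — measured around 0.01–0.02 at 500 patients
per arm — which is not evidence of inconsistency.

Default study sizes were fixed at design time: 500 patients/arm for
bias studies (1000/arm for variance calibration), 1000 replicates for
bias and coverage (500 for the transport check), 1e4 copula draws per
replicate inside simulation-based STC, and 1e6 draws for integration
oracles. Canonical scenario generators cover effect-modifier imbalance
(modifier mean 0.2 vs 0.6, γ_B=1, γ_C=0, giving the standard
comparison an analytic 0.4 bias), a no-effect-modifier null, shared
effect modifiers (γ_B=γ_C), prognostic imbalance for unanchored
fragility, and a logit-scale binary-outcome setting for aggregation
bias.

What the generator does *not* emulate: real trials have non-normal and
skewed covariates, measurement error, missingness, unobserved effect
modifiers, within-trial covariate-arm imbalance and survival endpoints.
Passing tests therefore demonstrate the estimators' algebraic and
asymptotic properties under their stated assumptions, not robustness to
violations beyond the ones deliberately constructed (omitted
prognostics/modifiers).

## Known limitations

* Two trials, three treatments; no multi-study synthesis or larger
  networks, and no arm-"splitting" weighting variants.
* No survival/time-to-event outcomes; continuous outcomes are
  identity-scale Gaussian only.
* Risk differences are expressed as the identity link on binary
  outcomes rather than as a separate scale object.
* Published SDs are assumed to be sample SDs (denominator n−1); no
  toggle is exposed.
* The ESS approximation understates precision loss when weights
  correlate with outcomes; it is reported with that caveat rather than
  corrected.
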