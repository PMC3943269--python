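# Methods

This note documents the statistical models implemented in `neighwalk`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish.

## Outcome models

Both walking outcomes are modeled with the same convolution
random-effect structure at the neighborhood level.

**Binary outcome** (any recreational walking): Bernoulli with
logit P(y=1) = x′β + u_j + v_j.

**Ordinal outcome** (neighborhood walking time in 5 ordered categories,
category 1 reserved for exactly zero minutes): proportional-odds
cumulative logit, P(y ≤ k) = σ(κ_k − x′β − u_j − v_j), identified by
four strictly ordered cutpoints and no intercept. If categories are
declared but unobserved, the corresponding cutpoints are informed by
the prior alone and a support warning is raised.

**Random effects.** u_j ~ N(0, σ_u²) is exchangeable
("unstructured"); v is intrinsic CAR with binary contiguity weights:
p(v | τ_v) ∝ exp(−Σ_{j~k}(v_j − v_k)²/(2τ_v²)), an improper prior made
proper on the sum-to-zero subspace. The sum-to-zero constraint is
enforced by recentering every iteration, with the shift absorbed into
the intercept (binary) or the cutpoints (ordinal) so the likelihood is
unchanged. Disconnected graphs are rejected: the ICAR prior is
undefined across islands.

**Priors** (configurable; the defaults are declared choices, not
reconstructions of the original analysis, which did not report them):
N(0, 10²) on regression coefficients and cutpoints, half-N(0, 1) on
σ_u and τ_v.

## Sampler

Adaptive Metropolis-within-Gibbs, chosen because no exact conjugate
data-augmentation sampler for the Bernoulli/cumulative logit is
available in the installed stack:

- β moves as one block: random-walk Metropolis with a Haario-style
  empirical proposal covariance, global scale tuned toward ~23%
  acceptance;
- u is updated at all sites simultaneously (its full conditionals are
  independent across neighborhoods), per-site scales tuned toward ~44%;
- v is updated within graph-coloring classes — sites of one color are
  mutually non-adjacent, so simultaneous single-site Metropolis moves
  do not interact through the ICAR prior (a rook lattice needs 2
  colors; general graphs use greedy coloring);
- cutpoints move one at a time with an ordering rejection;
- σ_u and τ_v are drawn by exact slice sampling on the log scale.

All adaptation happens during burn-in and is frozen afterwards, so the
retained draws come from a fixed-kernel chain. Chains are initialized
at a penalized-MAP fit (jittered), and every saved iteration satisfies
Σv_j = 0 and σ_u, τ_v > 0. Default settings: 2 chains × 6000
iterations, 2000 burn-in, thinning 2; the tests and the packaged
demonstration configuration use shorter chains (≈1500–4000 iterations)
sized to desk-scale problems of 36–144 neighborhoods and 1–10 k
individuals. Convergence is summarized by rank-normalized split-R̂ and
bulk ESS (arviz); the run report flags any fitted model failing R̂ ≤
1.1.

Correctness evidence: an intercept-only posterior matches exact grid
integration to Kolmogorov–Smirnov distance < 0.02 on 10 000 thinned
draws; with the CAR term disabled, posterior means agree with an
independent variational multilevel-logistic implementation; cutpoint
and slope recovery match an independent proportional-odds fit; 95%
credible intervals cover generator truth at nominal rates over 20
simulation replicates.

## Variance decomposition

Between-neighborhood variation is expressed as interquartile odds
ratios, IqOR(σ) = exp(2kσ), k = φ(z₀.₇₅)/0.25 ≈ 1.27110 — the mean
log-odds contrast between the top and bottom quartiles of a Normal
random-effect distribution. The published source cites the IqOR
without printing a formula; the quartile-mean-contrast form is adopted
here because it operationalizes the verbal definition (top 25% vs
bottom 25% of neighborhoods), and a 10⁷-draw Monte-Carlo oracle in the
test suite confirms it to 0.5%. All table-consistency results are
invariant to the choice of k, which cancels when IqORs are combined.

Per MCMC iteration: s_u = the σ_u draw; s_v = the *empirical*
across-neighborhood SD of the v draw (the ICAR conditional SD τ_v is
not the marginal spread — the empirical-variance convention for ICAR
effects is used instead); total = √(s_u² + s_v²); % structured =
100·s_v²/(s_u² + s_v²). Summaries are posterior medians with
equal-tailed 2.5/97.5 percentile intervals.

## Ecometric scoring

Neighborhood constructs measured by resident questionnaires are scored
with multilevel cumulative-logit measurement models: item fixed
effects (first item as reference), individual random intercepts
(3-level variant; omitted in the 2-level single-item variant),
neighborhood random intercepts, shared cutpoints, fixed logistic
residual scale. The same MCMC machinery is used as for the outcome
models — no second inferential framework. Scores are posterior means
of the neighborhood intercepts (logit scale), shrunken toward zero
where data are thin, and are quartile-categorized by the preprocessing
rules before entering outcome models.

The leave-one-out variant guards against same-source bias (the same
residents supplying both the aggregated exposure and the outcome). An
exact LOO would refit per individual; instead an empirical-Bayes
approximation is used at posterior-mean hyperparameters: each
individual's responses are condensed to a working latent value (the
closed-form truncated-logistic conditional mean given the response
category, item effect removed) with precision 1/(σ_e² + (π²/3)/m) for
m items, and the neighborhood score is the precision-weighted shrinkage
estimate excluding the focal individual. The approximation error
vanishes as respondent counts grow; tests confirm that the LOO-full
deviation shrinks with respondent count and that an injected
same-source artifact is attenuated under LOO scoring.

## Preprocessing rules

- Quartile categorization is rank-based with average-rank ties going to
  the lower category: reproducible, order-independent, and category
  sizes differ by ≤ 1 absent ties. The fitted cutoffs are stored so new
  data can be coded with the training thresholds; a tie block that
  empties a lower category stores a below-data cutoff so re-application
  reproduces training exactly.
- Walking-time coding: zero minutes → category 1; positive minutes
  quartiled into categories 2–5.
- Weather summaries average the recruitment day plus the 7 previous
  days (an 8-day window, deliberately not 7); any missing window day is
  an error, never imputed.

## Synthetic cohort generator

The generator is the package's study-conditions definition, not a test
dial. Defaults emulate the cohort the analysis was designed for: a
26 × 26 lattice (676 contiguous tracts ≈ the several hundred of the
original study), Poisson(10.5) residents per tract (n ≈ 7 100),
marginal prevalence 69% for the binary outcome, ordinal category 1 at
≈ 49% (non-walkers plus walkers active only outside their
neighborhood), published odds ratios as true effects for both outcomes
(re-referenced to each covariate's lowest level), covariate frequencies
from the published sample description, σ_u = 0.175 and τ_v = 0.40 so
the unstructured and structured IqORs sit near the published age-sex
model values. The fixed-effect contribution is centered so the
intercept (or cutpoints) control the marginal outcome distribution
whatever effects are switched on. Both outcomes share one (u, v) pair —
one spatial process drives both, a generator choice. Exposure fields
are i.i.d. node noise averaged over k-hop neighborhoods (k =
`env_spatial_range`, default 2) and are mutually independent: the
original exposures' joint distribution is unspecified, so the
generator's correlation structure is a modeling choice, not a
reconstruction. Outcome missingness (default 2.5%) is
missing-at-random given education and income, mirroring the reported
exclusion pattern.

What passing tests show: the estimators recover the structure the model
assumes. What they do not show: robustness to real-data features the
generator omits — correlated exposures, measurement error in recalled
walking time, non-random participation, irregular tract geometries and
population sizes, and neighborhood self-selection.

## Five-step workflow and risk score

The pipeline mirrors the published strategy: (1) age-sex models with
decomposition; (2) joint individual+weather screening, retaining
variables whose 95% interval excludes the null ("independently
associated" is operationalized this way; threshold configurable);
(3) one-at-a-time environmental pretests on the stage-2 model;
(4) forward combination in descending pretest evidence (|estimate|/SE;
the original combination order is unstated), pruning variables whose
association vanishes under mutual adjustment; (5) weather × environment
product-term tests. Screening steps use a fast penalized-MAP fitter
(ridge fixed effects + exchangeable neighborhood intercepts, no CAR
term, L-BFGS, Wald intervals) as the credible-interval analog; the
stage models feeding decompositions and the final models are full MCMC
fits. No multiple-testing correction is applied, matching the original
analysis.

The environmental risk score is the per-individual sum of final-model
environmental posterior-median coefficients times exposure values,
split at its quartiles; the outcome models are refitted with the score
categories replacing all environmental terms. Bootstrap intervals
(2000 replicates by default; the packaged demonstration uses 100)
resample individuals with replacement — a neighborhood-block bootstrap
is available — and refit each replicate with the penalized-MAP
approximation for tractability; whether the original bootstrap re-ran
the spatial random effects per replicate is unknown, so the headline
non-bootstrap ORs should come from the full MCMC refit
(`refit_with_score`).

## Numerical choices and limitations

- ICAR sampling in the generator goes through the eigendecomposition of
  the graph Laplacian (exact, cheap at a few hundred nodes; O(J³)
  beyond that).
- The cumulative-logit likelihood floors category probabilities at
  1e-300 before the log; cutpoint proposals violating the ordering are
  rejected outright.
- σ_u and τ_v mix more slowly than β (the classic convolution-model
  confounding between u and v); decomposition summaries use medians,
  which are robust to this, but very short chains will understate
  interval widths for the variance parameters.
- The null ("no signal") posterior medians of both IqORs do not shrink
  to 1 at small per-neighborhood samples under the default priors —
  with ~30 residents per tract they sit near 1.2, dropping below 1.15
  only with ~150 residents per tract. This is prior-driven behavior,
  not a defect.
- Percentages in the published decomposition table are printed as
  integers; recombining the printed IqOR components can therefore
  differ from the printed percentage by up to ~1 point, which is the
  tolerance the consistency tests use.
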