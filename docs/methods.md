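# Methods

## Model

Each subject i is observed on a weekly grid t = 1..T with J ordinal
symptom ratings y_itj ∈ {1, …, C} (default J = 10, C = 3: absent,
subclinical, clinical).  A latent first-order Markov chain z_it ∈ {1..K}
drives the ratings:

* transitions: P(z_i,t+1 = l | z_it = k) = Γ_i[k, l];
* emissions: P(y_itj = c | z_it = k) = θ_i[k, j, c], symptoms
  conditionally independent given the state;
* initial state: the stationary distribution of Γ_i (the model is applied
  to a process already under way, so the stationary start is the natural
  choice; it is also the default in the likelihood functions and can be
  overridden).

Both parameter sets are subject-specific.  Every probability row is
parameterised as baseline-category multinomial logits (first
category/state of the row as baseline), and subject logits are independent
normal random effects around group-level means with state-specific
variances:

η_i,km ~ N(μ_km, σ²_trans,k),  λ_i,kjc ~ N(ν_kjc, σ²_emis,k).

No cross-correlations among random effects are modelled, and covariates do
not enter the HMM; demographic and comorbidity analyses are post hoc
(below), mirroring the two-stage design of the analysis the package
reimplements.

Priors: N(0, 5²) on every group logit (diffuse on the probability scale)
and conjugate inverse-gamma(2, 0.5) on each random-effect variance (prior
mean 0.5 on the logit scale — weakly informative for weekly panels whose
plausible subject spread is a few tenths of a logit).  Both are
overridable through `PriorSpec`.

## Estimation

A Metropolis-within-Gibbs sampler (`fit_mhmm`) alternates:

1. **Latent paths** by forward-filtering backward-sampling per subject,
   vectorised across subjects.  The paths are sampled over the *full*
   weekly grid: a week with no usable ratings contributes emission factor
   1, which is exactly the marginalisation that bridging removed weeks
   with Γ^(g+1) performs in the observed-data likelihood
   (`hmm_core.forward_loglik` implements the explicit bridging and the
   equivalence is asserted in the tests).  Augmenting over the grid keeps
   the complete-data transition counts simple lag-1 counts.
2. **Subject logits** by random-walk Metropolis on the complete-data
   likelihood — one joint proposal per transition row and per
   (state, symptom) emission block.  Proposal scales adapt during burn-in
   toward a 23–44% acceptance band (Robbins–Monro on the log scale,
   target 0.35) and are frozen afterwards to preserve detailed balance.
3. **Group means and variances** by conjugate normal / inverse-gamma
   updates, followed by an *interweaving* (non-centred) move: a proposal
   shifts a group mean and all subject logits by the same amount, holding
   the subject deviations fixed.  The random-effect density is invariant
   under this shift, so the acceptance ratio involves only the
   complete-data likelihood and the group prior.  Without this move the
   group means mix very slowly whenever the random-effect variances are
   small (effective sample sizes of ~8 per 1,000 draws in our checks;
   ~80 with it).

Initialisation assigns states by severity quantiles of the smoothed weekly
mean rating (a 3-point kernel removes spurious switching caused by rating
ties) and adds diagonal pseudo-counts so the transition logits start in
the persistent regime weekly panels typically occupy; this matters because
the path/parameter Gibbs coupling can otherwise trap short chains in a
high-switching mode.

Determinism: all randomness flows from `McmcConfig.seed`; multiple chains
run sequentially with seeds seed, seed+1, … and are concatenated.

**Label switching.**  The likelihood is invariant to permuting state
labels.  `relabel_states` canonicalises every draw by sorting states on
the mean over symptoms of P(rating ≥ subclinical | state); ties keep their
incoming order (stable sort).  For K = 3 the canonical labels are
(low, cognitive_physical, elevated).

**Model selection.**  AIC = −2·ℓ̂ + 2p, where ℓ̂ evaluates the forward
likelihood at the posterior-median *group* parameters applied to all
subjects and p = K(K−1) + K·J·(C−1) counts group-level logits only.
Counting only population-level parameters reflects model complexity at the
level at which states are interpreted; subject random effects are shared
machinery across all K and alternative counts (conditional AIC) are out of
scope.  `select_num_states` fits each candidate K and marks the minimiser.

**Diagnostics.**  Split-chain scale reduction and effective sample size
(via arviz) on the group logits, plus acceptance-rate summaries.
Thresholds are logged, never enforced — a high scale reduction flags a run
for longer chains rather than aborting it.

## Markov dynamics

From each subject's posterior-mean transition matrix:

* inertia = diag(Γ);
* stationary occupancy π solves πΓ = π, Σπ = 1 (linear solve; reducible
  matrices raise an error naming the communicating classes);
* mean first-passage times solve m_ij = 1 + Σ_{k≠j} Γ_ik m_kj per target
  column; the diagonal is reported as NA (recurrence is reported
  separately, avoiding the m_ii/r_i ambiguity);
* mean recurrence r_i = 1/π_i (ergodic-chain identity).  An empirical
  decoded-path alternative (`empirical_recurrence_time`) is provided; the
  analytic 1/π is the default.

Group summaries are unweighted means of the per-subject quantities, *not*
the dynamics of the group-mean matrix: these differ for nonlinear
functionals, and by convexity of 1/π the subject-averaged recurrence time
is never smaller than the recurrence time of the averaged matrix (asserted
on synthetic ensembles).  Occupancy is the proportion of Viterbi-decoded
weeks per state and sums to 1 by construction; reporting decoded-state
proportions is a deliberate choice where other occupancy definitions
(e.g. averaging per-state posterior probabilities, or per-subject
any-time-in-state rates) would not be constrained to sum to 1.

## Post hoc association analyses

**Demographics.**  Each of the K² subject-level transition probabilities
is regressed (OLS) on female, age, and ethnoracial-minority status
jointly, on the raw probability scale — matching the convention in which
an unstandardised coefficient of ~0.02 means "2 percentage points more
likely per week" (a logit-scale option exists).  Standardised
β = b·sd(x)/sd(y) is reported alongside b, 95% CI, t, and p.  Per-outcome
OLS with identical design matrices yields the same coefficients as the
seemingly-unrelated multivariate system, which is why the table is
computed per transition.

**Comorbidity.**  Per disorder, weekly severity (1–6) is modelled as

severity ~ I(state = elevated) + I(state = cognitive-physical) + female +
age + inertia_elevated + inertia_low + inertia_cogphys,

with a subject random intercept and AR(1) within-subject residual
correlation, fitted by maximum likelihood (low state is the reference;
decoded states come from Viterbi under posterior-mean subject parameters,
with posterior-probability weighting available).  statsmodels' MixedLM
does not support AR(1) residual correlation, so the fitter is implemented
directly: β is profiled out by GLS given (σ², τ², ρ), and the profiled
−2·log-likelihood is minimised by Nelder–Mead over (log σ², log τ²,
atanh ρ).  The AR(1) correlation uses actual week indices (ρ^|t−s|), so
gaps from removed weeks decay the correlation correctly.  The
implementation reproduces `nlme::lme(..., correlation = corAR1,
method = "ML")` to ~4 decimals on a frozen fixture (see
`tests/test_association.py`).  Fixed-effect SEs come from the GLS
information matrix with t reference on n−p degrees of freedom (a pragmatic
choice; Satterthwaite-type corrections are out of scope).  Significance
across the five disorders uses exactly `bonferroni_adjust(0.05, 5)` = 0.01.

## Synthetic cohort generator

The generator is the package's study stand-in and defines the conditions
under which everything is tested.  Defaults:

* 120 subjects × 90 weeks × 10 symptoms (three-point scale), matching the
  target design; recovery checks and the acceptance script use a
  40-subject × 90-week cohort so a full MCMC fit runs in seconds.
* three states in generator order (low, elevated, cognitive-physical)
  with self-transition probabilities 0.887 / 0.865 / 0.870 — the printed
  group inertias — and the off-diagonal mass split equally within each row
  (the source reports off-diagonals only graphically; the equal split is a
  declared convention, not a claimed match).
* emission profiles are invented numbers reproducing the qualitative
  pattern of the three states: the low state rarely endorses anything
  (P(≥subclinical) = 0.10 per symptom), the elevated state endorses
  everything (0.85), and the cognitive-physical state matches the elevated
  state on worthlessness/guilt, psychomotor, appetite/weight and sleep
  (0.80), matches the low state on irritable mood and fatigue (0.12), and
  is intermediate elsewhere (0.45).  These are configuration, not ground
  truth about any real cohort.
* random-effect SDs 0.4 (transition logits) and 0.3 (emission logits);
* a +0.3 logit female effect on the low→elevated and low→cognitive-
  physical transitions, ≈ +0.017 on the probability scale — the magnitude
  of the significant unstandardised coefficients in the reference table —
  giving >80% detection power at N = 120;
* cell-level MCAR missingness 0.003: with 10 symptoms per row and
  whole-row removal of incomplete rows, ≈3% of subject-weeks are lost,
  matching the reported preprocessing loss; 1/30 of subjects additionally
  get >80% of their weeks masked to exercise the subject-level exclusion;
* five comorbidity series with intercepts 1.5–2.2, subject-intercept SDs
  0.4–0.8, AR(1) correlation 0.5, noise SD 0.5–0.6, and state
  coefficients mirroring the sign pattern of the reported associations
  (elevated-state effect +0.5 for ODD, −0.3 for CD, ≈0 elsewhere).

Randomness flows from one seed through named substreams in a fixed order
(covariates → subject parameters → paths → emissions → missingness →
comorbidity), so enabling a later stage never changes an earlier one.

What the generator does *not* emulate: informant disagreement processes
(ratings are generated post-combination), non-MCAR missingness,
interview-interval boundary effects, developmental non-stationarity, and
cross-correlated random effects.  Tests passing on this generator
therefore demonstrate that the estimation machinery recovers the model it
assumes at realistic sizes — not that real panels satisfy those
assumptions.

## Known limitations and numerical notes

* The covariate-free HMM treats subjects as exchangeable, so when the
  generator's sex effect is active, the group-mean logit estimates the
  *population mean* (group value plus ~0.53 × the female shift on the
  affected low-state logits), about 1.7 percentage points below the
  generator's nominal low-state inertia.  The ±3-point recovery checks
  absorb this; the credible-interval coverage test disables the sex effect
  because coverage of the nominal constant is undefined under
  misspecification.
* At 40 subjects the realised cohort-mean inertia itself varies by ±1–2
  percentage points across seeds (random-effect SD 0.4 / √40 ≈ 0.06
  logits); recovered values inherit that spread.
* Viterbi ties break toward the lowest state index; exact relabelling ties
  keep their incoming order.  Both rules are deterministic and logged.
* Forward recursions use scaled (normalised) variables with per-week log
  scaling factors; a week impossible under every state yields −inf with a
  warning rather than an exception in the likelihood, and an error in the
  smoothing functions.
* Monte-Carlo validations of the passage/recurrence formulas compare
  z-ensembles against their nominal calibration (≥99% within 3 SE, none
  beyond 4 SE, ensemble mean within 3/√n SE) rather than gating every one
  of ~180 simultaneous comparisons at 3 SE, which would reject an exact
  implementation ~40% of the time by multiplicity alone.
* The mixed-model optimiser is Nelder–Mead on a 3-parameter profiled
  surface; it is robust for the panel sizes used here but provides no
  analytic standard errors for the variance parameters (not reported).
* MCMC problem sizes used by the test suite and acceptance script
  (40 × 90 cohort, 1,500 iterations / 500 burn-in; selection over
  K ∈ {2..5} at 800/300) were chosen so each fit completes in seconds
  while keeping split-chain scale reduction near 1 and group-logit
  effective sample sizes in the tens; longer chains simply sharpen the
  same posteriors.
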