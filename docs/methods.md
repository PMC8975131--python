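# Methods

## Model

`fctbn` implements a continuous-time Bayesian network (CTBN) over binary
condition nodes in which every conditional transition intensity is a
log-linear function of subject covariates.  Writing z̃ = (1, z) for the
intercept-augmented covariate vector, the rate at which node x transitions
(absent→present or present→absent) given the set u of currently active
parents is

    q_{x|u,z} = exp( z̃·β_base(x,dir) + Σ_{p ∈ u} z̃·β_p(x,dir) ).

Assumptions baked into this parameterization:

- **Markov dynamics, time-homogeneous rates.** Sojourn times are exponential;
  rates depend on the current joint state and covariates only, not on time
  since entry or history (no semi-Markov effects, no time-varying covariates).
- **Multiplicative (noisy-OR-like) parent effects.** Each active parent
  multiplies the child's rate independently; there are no interaction terms
  between parents.  This reduces the coefficient count from
  n·(m+1)·2·2^maxparents (one regression per parent configuration) to
  n·(m+1)·2·(maxparents+1) — `parameter_count` reports both.
- **Binary states downstream.** The `ctmp` layer supports arbitrary finite
  state spaces, but the network model, learner and simulator commit to
  present/absent coding, where a node's exit rate in a state equals its
  single transition rate.
- **Complete observation with right-censoring.** Every transition inside the
  observation window is recorded; the final sojourn of each subject is
  censored at the horizon and contributes exposure but no event term.
  Partially observed trajectories (interval censoring, missed transitions)
  are out of scope.

The likelihood of a dataset decomposes over sojourn records: during a sojourn
of length t_d every node accrues exposure q·t_d at its interval-start
(state, parent configuration), and the transitioning node of an uncensored
record contributes log q.  Each (child, direction) therefore forms an
independent Poisson regression with per-row exposure; the penalty is the only
coupling across blocks.  Both the objective and its analytic gradient are
evaluated on a compiled design (one matrix per block), which is what makes
cross-validation at cohort scale cheap.

Remission can be modeled (its own coefficient groups per node) or frozen at a
constant — zero by default — for progressive diseases; the frozen direction
contributes a likelihood constant and no parameters.

## Learning

Structure and parameters are learned jointly by minimizing

    −ℓ(β) + Σ_j k_j · λ · w_j · ‖β_j‖₂

over penalized groups β_j, one group per candidate (child, parent) edge
spanning both transition directions, so an edge lives or dies as a unit (a
per-direction grouping is available via `group_by_direction`).  Baseline
groups are never penalized: zeroing them would remove a node's base rate, not
an edge.  Intercepts of parent groups are penalized together with their
slopes.

- **Adaptive weights** w_j = 1/max(‖β̃_j‖, 10⁻⁴) come from the unpenalized
  maximum-likelihood fit β̃ (per-block L-BFGS plus a damped-Newton polish to a
  gradient norm below 10⁻⁶·(1+|ℓ|)).  The floor avoids infinite penalties
  when a pilot group estimate is essentially zero.  Cross-validation refits
  β̃ inside each training fold with a 10⁻⁸ ridge to stabilize nearly
  separated folds; the final full-data fit is exact ML.
- **Group-size factor** k_j defaults to √(group size) — the standard group
  lasso normalization — with literal size available via
  `size_correction="linear"`.
- **Solver**: monotone FISTA with backtracking line search (the Poisson
  likelihood has unbounded curvature, so no global Lipschitz constant
  exists).  The monotone variant keeps the best iterate, making the objective
  trace non-increasing by construction and hence testable.  Convergence is
  declared when the relative objective change stays below 10⁻⁷ for 10
  consecutive iterations (both configurable; the λ-limit checks in the tests
  tighten the tolerance to 10⁻¹¹), with a cap of 50,000 iterations.
- **Path and tuning**: the regularization path is fit warm-started from small
  to large λ over the decade grid {0, 10⁰, …, 10⁶}; λ is selected by
  subject-level k-fold cross-validation (default 5 folds; the recovery
  experiment and the acceptance script use 3) on the mean held-out negative
  log-likelihood per record, with ties broken toward the sparser model.
  Held-out covariates are standardized with the training fold's scaler.
- **Standardization**: covariates are centered/scaled internally before
  fitting so the penalty treats all slopes comparably;
  `CoefficientTable.to_original_scale()` converts fitted coefficients back,
  and converted rates are exactly invariant to the reparameterization.

## GMM sparsification and early stopping

Late FISTA iterations mostly inch near-zero coefficients toward exact zero.
Instead, the run can be stopped once the objective stalls; the pooled
penalized coefficients (including parent-group intercepts) are clustered with
a 2-component univariate Gaussian mixture (EM, best of 5 restarts, variance
floor 10⁻¹⁰), every coefficient within ±3σ of the component whose mean is
closest to zero is set to exactly zero, and one refinement FISTA pass is run
from the zeroed table.  On the built-in fixture this reproduces the fully
converged run's active-edge set — the property the acceptance suite checks.
K=2 follows the empirically bimodal shape of the pooled estimates
(signal vs shrinkage debris); BIC selection over K is deliberately not
automated to keep the step deterministic.

## Inference

Exact only: the node-wise rates are amalgamated into the joint intensity
matrix over all 2ⁿ configurations (capped at 4,096 states = 12 nodes;
nonzero rates only between configurations differing in one node), and
distributions are propagated as p(t) = p₀·exp(Qt) via `scipy.linalg.expm`
(cross-checked against a uniformization implementation in the tests).  The
risk trajectory of a condition is its marginal P(present at t), the curve a
clinician would read as cumulative onset risk.
Multi-year predictions use the ever-in-year convention matching annual
diagnosis coding: P(present during year y) is computed by propagating to
year y−1 with the true generator and then for one year with the condition's
remission transitions removed, which makes the condition-present set
absorbing and turns occupancy into hitting probability.  Predictions
propagate from the baseline configuration only; re-conditioning on each
observed year is a possible alternative not taken here.

## Simulator and fixtures

Cohorts are drawn with the competing-exponentials (Gillespie) scheme: one
rng stream per cohort, fixed draw order (total-time exponential, then a
node pick proportional to rates), final record censored at the horizon.
Covariates come from declared normal or categorical distributions.

The default truth is a 5-condition network — TBI, back pain (BaPa), PTSD,
depression (Depr), substance abuse (SuAb) — with one standardized age-score
covariate and six true edges (TBI→PTSD, TBI→SuAb, PTSD→Depr, PTSD→SuAb,
Depr→SuAb, BaPa→Depr).  Baseline acquisition rates are 0.06–0.15 per year,
parent effects are hazard ratios of 2–3, age slopes 0.1–0.3 on the log rate,
and the reversible variant adds a flat remission rate of ≈0.2/year (a
progressive variant freezes remission at zero).  These values were chosen
once as realistic chronic-condition scales producing a few events per
subject per decade.  The standard recovery experiment uses 5,000 subjects
observed for 10 years; unit tests use a 3-node, 400-subject analogue.

What the simulator does *not* emulate: real EHR phenomena such as
informative dropout, diagnosis recording delays, covariate measurement
error, cohort demographics, or interval-censored observation.  Passing
recovery tests therefore demonstrate correctness of the estimator under the
model's own assumptions, not robustness to their violation on real claims
data.

## Numerical choices and degenerate inputs

- Inestimable rate cells (zero exposure) are flagged, not raised, and
  excluded from likelihood-based comparisons.
- `group_prox` returns the exact zero vector when ‖v‖ ≤ threshold, so active
  sets are exact, not thresholded.
- If the FISTA momentum step lands on a non-finite objective, momentum is
  restarted at the best accepted iterate; a non-finite accepted objective
  raises with the trace attached.
- Cross-validation ties on the error are broken toward larger λ.
- A GMM pool with zero spread short-circuits to a single component at that
  value with the variance floor.
- Rank-deficient covariate matrices reduce the PCA output with a warning.
- The dataset reader validates durations, event/censor consistency and
  state-vector continuity, reporting offending row numbers.

## Known limitations

- Joint-state inference is exponential in the number of nodes; the 4,096
  state cap keeps `expm` tractable and rules out networks beyond 12 binary
  conditions (approximate inference is out of scope).
- Kernel PCA is not provided; feature reduction is linear.
- The AUC harness evaluates a fitted model against simulated outcomes from a
  known generator; it is a consistency check, not a clinical validation.
- Coefficients of rarely active parent configurations are weakly identified
  in small cohorts; the cross-validation ridge masks, but does not solve,
  separation in tiny folds.
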