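# Methods

## Model

A participant's latent health state `X(t)` evolves in continuous time
as a Markov jump process on `S` states with generator (rate matrix)
`Q`: off-diagonal entries are nonnegative transition intensities and
rows sum to zero.  At each clinic visit, at age `a_t`, the three islet
autoantibodies (GADA, IAA, IA-2A) are observed as conditionally
independent Bernoulli variables with state-specific positivity
probabilities `E[s, j]`; a missing antibody measurement contributes a
vacuous factor 1 (missing-at-random).  Transition probabilities over an
inter-visit gap `Δt` are `P(Δt) = expm(Q Δt)`, so arbitrarily irregular
visit schedules are handled without discretisation.  Diagnosis of type
1 diabetes is an *outcome*, not an emission: the model is learned
unsupervised from the antibody panels alone, and diagnosis enters only
the downstream survival analyses.

## Estimation

Parameters `(π, Q, E)` are estimated by EM:

* **E-step.** A scaled forward–backward pass per participant yields
  per-visit state posteriors, per-interval endpoint-pair posteriors and
  the log-likelihood.  For each inter-visit interval the expected time
  spent in every state and the expected count of every jump,
  conditioned on the interval's endpoint states, are accumulated.  The
  per-interval conditional moments come from the integral
  `∫₀^Δt expm(Qs) B expm(Q(Δt−s)) ds`, evaluated two ways: the public
  per-interval API uses the augmented (block) matrix-exponential
  construction, while the batched EM path uses the equivalent closed
  form through the eigendecomposition of `Q` (Hadamard product with
  `J_pq = (e^{λ_p Δt} − e^{λ_q Δt})/(λ_p − λ_q)`); a unit test asserts
  the two routes agree.  Because visit ages carry 3-decimal precision,
  kernels are computed once per distinct gap and weights are pooled per
  gap, which keeps an EM iteration at a few tens of milliseconds for
  ~6,000 intervals and 11 states.  A time-discretised EM is rejected:
  visit gaps vary by years.
* **M-step.** Closed forms: `q_kl = E[jumps k→l]/E[dwell k]` (floored
  at 1e-8 when a state accrues no dwell time, keeping the kernel
  well-defined), `π` from normalised first-visit posteriors, and
  emissions from posterior-weighted positive fractions.  Emissions
  receive a symmetric Beta pseudo-count `a = 0.5` (MAP-EM with a
  Jeffreys-style prior): without it, fits at desk scale regularly spend
  a state pinning emissions at 0/1 to reproduce a handful of visits
  exactly, a degenerate local optimum.  The pseudo-count moves a
  well-populated state's estimate by under 0.3% while making such
  degenerate states unattractive.  The reported `loglik_trace` is the
  objective EM maximises (data log-likelihood plus emission log-prior)
  and is therefore monotone; BIC and held-out scores always use the raw
  data log-likelihood, recomputed separately.
* **Initialisation and restarts.**  5 restarts by default.  Each
  restart seeds the emission rows from a k-means clustering of the
  visit observation vectors (missing values imputed by column mean for
  the clustering only), jittered so restarts differ; rates start
  row-constant with a log-uniform scale in [0.05, 1]/S and `π` is drawn
  Dirichlet(1).  Pure uniform-random emission initialisation is
  available (`init="random"`) but lands in structurally merged local
  optima noticeably more often at n≈500.  The restart with the best
  final objective wins.
* **Convergence.** Relative objective change below `tol = 1e-6`
  (default), capped at `max_iter = 500`.  The model-order search uses
  `tol = 1e-4`, `max_iter = 200`, 2 restarts per cell — score rankings
  across orders stabilise well before full convergence, and the search
  fits 35 models.
* Visits recorded at identical ages are merged; conflicting duplicate
  observations are an error.  The rate matrix is kept dense during
  learning — chain structure is discovered, not imposed.

Labeling uses Viterbi decoding by default (ties toward the lower state
index); maximum-posterior-marginal decoding is available.  BIC uses the
visit-count convention `−2·loglik + k·ln(n_visits)` with
`k = (S−1) + S(S−1) + 3S`; whether the original analysis counted
visits or participants is not stated, so the visit convention is this
package's documented choice, as is the per-visit normalisation of the
held-out predictive log-likelihood.

## Model-order selection

For each candidate order and replicate, participants are split 70/30
(a participant's entire history is train or test, never both), the
model is fit on the training split, BIC is computed on the training
split and predictive log-likelihood per visit on the held-out split.
Candidates within 1% (of the BIC range across orders) of the minimal
mean BIC form the short-list; the short-list member with the highest
mean held-out log-likelihood wins and is refit on the full dataset.
The 1% band is a free parameter of this package; only the selection
outcome, not the band, is reported in the source analysis.

## Trajectory decomposition

Edges with fitted rate above 1% of the largest off-diagonal rate are
kept; weakly connected components of the thresholded graph are the
chains.  Within a chain, states are ordered topologically (ties broken
by median entry age of labeled visits); the chain's start is its least
antibody-positive state.  Chains are named TR1/TR2/TR3 by descending
probability that the state immediately after the start is
multiple-antibody positive, which reproduces the
multiple-first/IAA-first/GADA-first naming on fits shaped like the
published model.  A cyclic thresholded graph (possible in poor fits)
falls back to entry-age ordering and is reported.  Participants whose
labeled path touches two chains are flagged ambiguous and excluded from
the downstream statistics, with counts reported.

Seroconversion age is the first of two consecutive visits at which the
*same* antibody is positive (the persistence reading of "at least one
IAb persistently positive"); an `any_antibody` switch implements the
laxer reading.  Pattern-by-age tables bin ages as `[k, k+1)` for
k = 2..7.

## Downstream statistics

Pearson chi-square without continuity correction (the HLA-DR test
excludes the sparse "Unknown" category, giving the 4×6 table and 15
degrees of freedom); one-way ANOVA with Tukey HSD (studentized-range
adjustment, no further correction); Kaplan–Meier with Greenwood
variance and log-log 95% intervals (the interval method is a package
choice); overall and pairwise two-sided log-rank tests, pairwise
p-values reported unadjusted.  Survival time runs from first entry into
a reference state (each chain's first antibody-positive state, or the
GADA+/IA-2A+ states) to diagnosis or censoring at last observation;
participants never entering their reference state are excluded and
counted.

## Synthetic cohort generator

The generator emulates the published 11-state model so the pipeline is
testable without protected data:

* **Structure**: three forward chains of sizes 3/5/3; no cross-chain
  transitions; chain weights 739/530/876 out of 2145 (the published
  trajectory sizes).
* **Emissions**: every probability quoted in the source results is used
  verbatim (e.g. TR1-1 = (0.93, 0.62, 0.94), IAA 0.86 in TR2-1); the
  remaining entries are explicit defaults — 0.03 per antibody in the
  three start states, 0.90 for an antibody persisting from an earlier
  state, 0.05 for one not yet acquired.  The full table is
  `DEFAULT_EMISSIONS`.
* **Sojourns**: exponential, with start-state means (3.6, 1.9, 4.8
  years) set so median entry ages into the first positive states
  reproduce the published 2.5 / 1.3 / 3.3 years; mid-chain means are
  plausibility choices (TR2 passes its early states briefly); chain-end
  states have zero exit rate.
* **Visits**: first visit uniform in [0.25, 1.0] y, gaps uniform in
  [0.25, 1.0] y — the source pools five studies with heterogeneous
  protocols, so one simple configurable schedule is used.  Follow-up is
  capped at 15 years.
* **Outcome**: diagnosis is generated as a state-dependent hazard
  outside the latent process (0 in antibody-negative states), with
  rates calibrated so 5-year diabetes-free survival from the first
  positive state is approximately 40% / 62% / 88% for TR1/TR2/TR3; the
  *ordering* is the assertable property.  Loss to follow-up is an
  independent exponential dropout (rate 0.05/y).
* **Covariates**: sex and HLA-DR category drawn per (chain, outcome)
  from the published cohort composition table.
* **Reproducibility**: one pseudorandom stream per participant derived
  from `(seed, index)`.
* Antibody values are missing completely at random (5% per
  measurement).  Ground-truth paths are returned alongside the cohort
  for tests and calibration checks only.

What the generator does *not* emulate: participant-level antibody
persistence within a state (emissions are i.i.d. per visit, exactly the
fitted model's assumption), inter-study protocol heterogeneity, assay
thresholds or titres, age-dependent hazards within a state, and
covariate effects on dynamics.  Passing tests therefore demonstrate
correctness of the machinery under the model's own assumptions, not
robustness to the ways real cohort data violate them.

## Numerical choices

Eigendecomposition of a fitted (dense, nonsymmetric) rate matrix may be
complex; computations stay in complex arithmetic and take real parts at
the end, with negative round-off clipped at zero.  Nearly defective
matrices are jittered by a tiny relative perturbation until the
decomposition reconstructs `Q` (never needed in practice at default
settings).  Per-visit scaling prevents underflow in forward–backward;
emissions are clipped to [1e-6, 1−1e-6] so held-out likelihoods stay
finite.  Conditioned dwell times per interval sum to the interval
length to 1e-6.

## Known limitations

* The three all-negative start states are distinguished only by their
  dynamics.  At desk scale (500 participants) the maximum-likelihood
  fit sometimes merges two of them and spends the freed state
  elsewhere; the likelihood difference between the merged and the
  generating structure is a few nats.  This is a small-sample
  identifiability limit, not an optimiser artefact — EM initialised at
  the truth reaches no better an objective.
* Recovered emissions of short-sojourn states bordering the negative
  states (TR2-1 in particular) show a finite-sample upward selection
  bias of ~0.03: visits contradicting the state's profile are softly
  reassigned to the neighbour, inflating the positive fraction.  The
  effect shrinks with cohort size.
* The emission table contains only 8 distinct profiles (three identical
  all-negative start states, and TR2-4 nearly equal to TR3-2); the
  duplicated states are distinguishable only through jump timing.  With
  per-visit-independent emissions that timing information is weak, so
  at desk scale the training log-likelihood plateaus around 8–10 states
  and the minimal-BIC band settles on 8 rather than 11 — under either
  the visit- or the participant-count BIC convention.  The held-out
  predictive curve peaks near 11–13 but the band rule never reaches it.
  Selecting the full 11-state order requires data whose dynamics are
  more informative than this generator produces (larger cohorts, denser
  early sampling, or participant-persistent antibody patterns).
* For the same reason the trajectory decomposition of a desk-scale
  *fitted* model often reports joined chains: the fit shares one
  antibody-negative hub among chains.  Decomposition of the generating
  model itself always yields the three chains of sizes 3/5/3.
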