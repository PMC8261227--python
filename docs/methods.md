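# Methods

## Data model

The atomic observation is a dyadic competitive event: a winner, a loser,
one of five behavioural categories (contact intrude `ci`, no-contact
intrude `ni`, contact defend `cd`, no-contact defend `nd`, waiting
`wait`), a night index and a time in minutes since the start of the
nightly recording window (0–900 min, i.e. 17:30–08:30). Events whose
actors could not be identified carry the label `ambig`; they stay in the
table but are excluded from every win–lose matrix. The win–lose matrix
`W[i, j]` counts the events i won against j; its axes always follow
roster order, so results are stable across runs and invariant to input
shuffling.

## Group-level metrics

**Landau's h.** Each dyad is scored 1 for the individual with strictly
more wins; tied and never-interacting dyads contribute 0.5 to both.
With `V_i` the number of individuals i dominates,
`h = [12/(N³−N)] Σ_i (V_i − (N−1)/2)²` ∈ [0, 1].

**de Vries h′.** Defined as the mean of h over random assignments of a
direction to every tied/unobserved dyad. Because each undecided dyad
contributes an independent Bernoulli(½) to the two V's, the mean has a
closed form: `E[h] = [12/(N³−N)] Σ_i [(d_i + u_i/2 − (N−1)/2)² + u_i/4]`,
where `d_i` is decided wins and `u_i` the number of undecided dyads of
i. The exact form is the default (and is used inside permutation nulls);
a Monte-Carlo path with `n_assign` draws and a standard error is kept
for comparison, switching to full enumeration whenever `2^u ≤ n_assign`.
Equality of the three routes is tested.

**Triangle transitivity.** Among triads whose three dyads are all
directed (strict win majority), `P_t` is the transitive fraction and
`t_tri = 4(P_t − 3/4)`: 1 when fully transitive, ≈0 under random
direction, −3 when every triad is cyclic. Counting uses the adjacency
trace identities (cyclic = tr(D³)/3, fully-directed = tr((D+Dᵀ)³)/6) and
is verified against a brute-force triad census. Matrices with no fully
directed triad raise an explicit undefined-metric error rather than
returning a number.

**Directional consistency.** Pooled index `Σ(H−L)/Σ(H+L)` over dyads
with at least one event (H/L = larger/smaller directional count); an
unweighted per-dyad mean is available by flag because the verbal
definition ("mean frequency") admits both readings.

**Null model.** Significance of all four metrics comes from randomizing
the *direction* of every event independently with probability ½.
Conditional on dyad totals this is exactly per-dyad Binomial(n_ij, ½)
resampling, which is how replicates are generated (vectorized at the
dyad level). p-values are one-tailed toward more structure, with the
add-one correction `(1 + #{null ≥ obs})/(1 + n_perm)`, so they are never
exactly 0. Replicates where a metric is undefined (e.g. no directed
triad) are dropped from that metric's null. Default 5000 permutations.

## David's scores, steepness, shape

`P_ij = W_ij/n_ij` (dyads that never interacted contribute nothing; an
optional dyadic correction `D_ij = P_ij − (P_ij − ½)/(n_ij + 1)` shrinks
small-sample proportions toward ½). `w = ΣP`, `w2 = Pw`, with `l, l2`
the symmetric loss terms; `DS = w + w2 − l − l2` (ΣDS = 0 is asserted in
tests), `NormDS = (DS + N(N−1)/2)/N`. Steepness is the absolute OLS
slope of NormDS on rank 1..N — near 1 for despotic, near 0 for
egalitarian hierarchies — with a direction-randomization p-value. The
shape curve bins events by absolute score difference and reports the
proportion won by the higher-scored participant with exact
Clopper–Pearson 95% CIs; events between equally-scored individuals are
excluded from the curve and counted separately.

Rank-difference matrices for the network tests use David's scores by
default (higher score = higher rank; `signed[actor, receiver] =
score_receiver − score_actor`), integer ranks by flag.

## Sequential ratings

Elo: winner expectation `E = 1/(1+10^((R_l−R_w)/400))`, winner gains
`k(1−E)`, loser loses the same (zero-sum; asserted). Defaults k=100,
start=1000. Glicko follows the single-game update (g, E, d², r′, RD′)
with q = ln10/400, r0=1500, RD0=350; RD never exceeds RD0 (no
between-period inflation — each event is its own rating period) and is
floored at 30 to keep ratings responsive. These constants are exposed
because published analyses rarely print them and rank correlations can
be sensitive to them. Full trajectories are returned so users can judge
burn-in; no automatic truncation is applied.

Rank uncertainty: *repeatability* shuffles the event order `n_reps`
times and summarizes the mean pairwise Spearman correlation among
replicate final-Elo vectors; *splitting* halves the events uniformly at
random, ranks each half, and correlates the halves (individuals missing
from a half are excluded from that replicate and reported). Note that
repeatability replicates share the same events, so its no-structure
baseline is positive (~0.2 at study scale), not 0; both measures
increase monotonically with the generator's β (tested over {0, 1, 2, 4}).

## Dyadic-matrix inference

Behaviour rates are transformed as `ln(x + 1)` with x = seconds of
interaction per trial before any regression. Symmetric matrices are
vectorized as unordered dyads, directed ones as all ordered off-diagonal
pairs; the diagonal is always excluded.

**Mantel**: Pearson r between two matrices, null from simultaneous
row/column permutations of one matrix; two-tailed. When `N! ≤ n_perm`
all node permutations are enumerated, giving the exact p (this also
makes the p-value strictly invariant to relabeling, which is only true
in distribution for sampled permutations).

**MRQAP-DSP**: OLS with intercept on the vectorized system; for each
predictor, the predictor is residualized on the others, the residual
matrix's node labels are permuted, the model refit, and the permuted
term's coefficient collected (double semi-partialling); two-tailed per
predictor. Collinear predictors raise an error naming the offending
pair. Observed coefficients are verified against the normal equations,
and the engine's type-I error is calibrated by simulation
(conditionally independent predictor, 500 replicates).

**Helping and rank**: help symmetry `|H_ij−H_ji|/(H_ij+H_ji)` (masked
where no help flowed; the absolute form is used since a signed version
depends on an arbitrary dyad orientation); per-individual proportion of
help directed up the hierarchy and up-minus-down mean rate difference,
with percentile-bootstrap 95% CIs over individuals (default 5000
resamples). The feeding-time test regresses event time on actor rank —
one observation per identified participant per event (so each event
contributes two) — with a null that re-assigns rank labels among
individuals consistently across all their observations; two-tailed.

## Synthetic generator

Defaults emulate the motivating colony: 24 adult females (two source
populations, ≈7:17) plus 5 young females and 4 young males; 1023 events
across 70 nights with type probabilities proportional to
224:250:214:109:219; times uniform on the 900-minute window; dyads drawn
uniformly (a Gamma-weighted option models heterogeneous encounter
rates; the uniform default is why synthetic dyad coverage, ~86%, exceeds
what sparse field data show). Latent scores are equally spaced on [0, 1]
(spacing configurable); winners follow the logistic model with β = 2 by
default, chosen once as a weakly structured hierarchy in the spirit of
the study system — at study scale it yields h′ ≈ 0.23–0.29 and DC ≈ 0.6,
detectable against the null but far from linear. Kinship is
Gamma(0.5, 0.15)-distributed (mean 0.075 — low but highly variable, as
reported for this species); grooming/sharing are log-normal seconds per
trial around medians of 10 and 5 s with configurable kinship slope,
give/receive reciprocity correlation, and rank bias (all 0 by default,
so the cooperation networks are rank- and kinship-independent unless a
study design requires otherwise); co-observation counts are Poisson(20).

What passing tests show — and what they don't: the generator has
independent events, exchangeable individuals and no winner–loser or
temporal dynamics, so calibration results (type-I error in [0.03, 0.08]
at α = 0.05 for every permutation engine; monotone recovery of β)
certify the inference machinery, not robustness to autocorrelated or
state-dependent real data.

## Numerical and design choices

* Permutation p-values use the add-one correction everywhere except
  exact enumeration (where the identity permutation plays that role).
* Direction nulls flip individual events, not dyad outcomes.
* Exact-score ties get average ranks; event-order ties are processed in
  file order (a randomized-order option feeds the uncertainty module).
* The Poisson-based dyad-coverage null allocates the observed number of
  events i.i.d. uniformly over the N(N−1)/2 dyads and reports the mean
  and 2.5/97.5 percentiles of the proportion of dyads hit; a
  Gamma–Poisson overdispersed variant (configurable shape) is provided
  because field data typically show far fewer dyads interacting than the
  uniform null predicts.
* All stochastic procedures take explicit seeds; the pipeline spawns and
  records per-stage seeds from one master seed, so any stage can be
  reproduced in isolation and reruns are byte-identical.
* Simulation-based tests use reduced sizes chosen for statistical
  adequacy: calibration runs use 500 replicate datasets with 200
  permutations each at N = 10–12 (small enough to be quick, large enough
  that the discrete permutation distributions are close to nominal);
  recovery runs use 50 replicates per β at N = 30 with 1000 events.

## Known limitations

* h′ is reported as the randomization average only; no closed-form
  chi-squared linearity p-value is provided (the direction null covers
  significance).
* Glicko is the original single-game formulation — no Glicko-2, no
  rating-period batching, no RD inflation between observation periods.
* The feeding-time test treats each identified participant as one
  observation; studies that log partially identified actors will have
  larger n than twice the usable event count.
* MRQAP assumes a linear model on the (transformed) rates; count models
  are out of scope.
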