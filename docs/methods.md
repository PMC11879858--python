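# Models and methods

## The contagion model

Nodes are binary: susceptible (0) or infected (1), and infection is
absorbing. Three mechanisms can flip a susceptible node, and every node is
pre-assigned one of the two network mechanisms:

* **Simple contagion (Sm)** — at every synchronous step each infected
  neighbour transmits independently with probability β ∈ [0, 1]; the ego's
  per-step hazard with n infected neighbours is b(n) = 1 − (1−β)ⁿ.
* **Complex contagion (Cx)** — the deterministic Watts threshold: the ego
  adopts at the step *after* its infected-neighbour count first satisfies
  n > kφ. We use the strict Heaviside inequality throughout, so the minimal
  adopting count is m* = ⌊kφ⌋ + 1 (identical to ⌈kφ⌉ unless kφ is an
  integer; the strict form is what the simulator implements, so the
  closed-form accuracy below uses m* as well).
* **Spontaneous adoption (St)** — Bernoulli(r) per susceptible step,
  independent of the network.

Updates are fully synchronous: states at t+1 are computed from states at t.
When a mechanism event and a spontaneous event fire in the same step, the
adoption is labelled with the network mechanism. This matches the likelihood
bookkeeping, in which the spontaneous scenarios carry the factor requiring
the network event *not* to fire; the residual joint-fire mass r·b(n) is not
claimed by any scenario and we assign its realisations to the mechanism
label. The tie-break lives in one place in `simulate.run_static_contagion`.

## Trajectory likelihoods

The process is Markovian, so the likelihood of an ego trajectory under a
mechanism hypothesis is the product of per-step transition probabilities
conditioned on the previous neighbour states. In the isolated ego-star
setting two hypotheses compete (Sm vs Cx; the ego cannot adopt
spontaneously). In the network setting four generative scenarios are
evaluated — Sm, Sm→St, Cx, Cx→St — and the two spontaneous scenarios are
collapsed to one reported St class by taking their maximum before the
argmax. Ties are broken deterministically Cx > Sm > St; the Cx-before-Sm
order is forced by the model itself (a true threshold adopter's Cx
likelihood is exactly 1, and for β = 1 the Sm likelihood can tie it), and
the rest of the order only matters in degenerate corners. All arithmetic is
in log space with an explicit −∞ sentinel; an instance whose every
hypothesis is impossible is reported `unclassifiable`, never dropped
silently.

Because states are absorbing, a trajectory's log-likelihood depends only on
the adoption time t_a, the total pre-adoption stimulus count, and the
infected-neighbour counts at the last two pre-adoption steps.
`likelihood.summary_logliks` evaluates these closed forms vectorised over
instances; the generic per-step implementation (`trajectory_loglik`) is kept
as the reference path and the test-suite asserts their equality on simulated
observations.

## Closed-form accuracy on ego stars

With leaves adopting spontaneously at rate r, a true-Cx ego is always
classified correctly, so the two-class accuracy is 1 − P(Cx-perfect | Sm)/2.
Conditioned on n infected neighbours, the steps until a new neighbour
infection and until the ego's own adoption are competing geometric variables
with success probabilities p(n) = 1−(1−r)^(k−n) and b(n); multiplying the
first-passage probabilities up the exposure ladder and the final immediate
adoption b(m*) gives the approximation. It neglects simultaneous neighbour
infections. That neglect is not always small: at r = 0.05 and mean degree 4
the chance that an infection step infects two or more leaves at once is a
few per cent, and a jump from below the threshold count straight past it
creates a Cx-perfect trajectory the formula cannot count. An exact
Markov-chain enumeration (dynamic programming over the infected-leaf count
and a threshold-history flag, `tests/conftest.exact_misclassification_dp`)
quantifies the error: up to ≈0.03 in accuracy at high β and moderate φ,
largest where a two-leaf jump is both likely and decisive. Simulation,
enumeration and the formula are compared explicitly in the test-suite, and
the phase-space comparison reports the difference as measured (≈0.02 at its
maximum) rather than hiding it.

## Parameter estimators (unknown-parameter classification)

When β, φ, r are unknown they are replaced per instance by:

* β̂ = 1 / (total stimuli before adoption), where one stimulus is one
  infected neighbour during one pre-adoption step; a zero-stimulus adopter
  gets β̂ = 1 with a flag (such instances cannot fit either network
  hypothesis anyway);
* φ̂ = (infected neighbours at adoption) / k, using the state at the last
  pre-adoption step — neighbours adopting simultaneously with the ego are
  excluded, as they cannot have influenced a synchronous update;
* r̂ = the population average, over nodes, of the fraction of susceptible
  time spent with at least one infected neighbour.

Since φ̂ equals exactly the adoption-step proportion, a strict threshold
test could never be satisfied at that step; with estimated parameters the
Watts indicator therefore uses the non-strict count m̂ = max(⌈kφ̂⌉, 1). The
max(·, 1) guard prevents a zero-exposure adoption from trivially satisfying
a φ̂ = 0 threshold, keeping such instances in the spontaneous class. A
consequence of these definitions is that every adoption occurring one step
after a new infected neighbour is Cx-perfect under its own φ̂, so the
unknown-parameter classifier systematically over-predicts Cx in fast
corners of the phase space; the measured grid mean (≈0.59) reflects this
and is reported as computed. The r̂ definition yields values far above any
plausible spontaneous rate (0.25–0.49 on these dynamics); we evaluated a
spontaneous-adoption MLE alternative (which recovers r almost exactly) and
an adoption-step φ̂ variant, found no reading that improves the overall
behaviour without degrading it elsewhere, and froze the definitions above.

## Eight ego features and the random forest

Features, all evaluated at the ego's adoption: degree; proportion and number
of infected neighbours; sum, per-neighbour mean and per-neighbour population
standard deviation of received stimuli (over all k neighbours, including
zero-stimulus ones); time since the first and since the last infected
neighbour. On pure threshold adopters the last feature is a point mass at 1
in the synchronous model — the signature the temporal model deliberately
destroys.

Forests use 100 trees of unlimited depth; the split criterion is chosen
between gini and entropy on an internal 80/20 validation split (the split
ratio is our choice; results are insensitive to it); training and test sets are
class-balanced and disjoint. When a class has fewer instances than the
nominal 6000/2000 per class, counts are scaled down proportionally to the
minority class with a warning — unavoidable, since spontaneous adoptions at
r = 0.005 are rare (tens to hundreds per thousand-node epidemic).
Classification certainty is the fraction of trees voting for the assigned
class, bounded below by 1/3 for a three-class plurality.

## The temporal (activity-driven) model

Each node carries an activity â ∈ [0, 1]; at every event step one node posts,
chosen with probability proportional to its activity. States are susceptible
→ aware → detected: awareness is the (latent) adoption, detection its first
observable expression — the node's next own post. The waiting time t_w
between the two is geometric in the node's selection probability, hence
broad and right-skewed under heterogeneous activities. A susceptible poster
adopts spontaneously with probability r (default 0.005, matching the static
networks; the empirical rate is not identifiable from the data the model
emulates); its post influences nobody. Aware and detected nodes post the
spreading content, and each such post is one stimulus to every neighbour:
simple nodes run one Bernoulli(β̂) trial per received stimulus, threshold
nodes become aware once the fraction of neighbours with at least one
influencing post exceeds φ̂. The detecting post itself is the neighbour's
first influencing event.

Feature snapshots are taken at the ego's *detection* (the observable
adoption) in ego-local event time — the ego's clock counts all posts by its
neighbours, content or not, and the adoption index is one past the last
observed neighbour post. The degree feature is the observable one: the
number of neighbours that posted at least once before the ego's detection,
mirroring the active-followee definition used for timeline data.

Node parameters come from `ParamDistributions`: per-degree-group truncated
normals for activity, per-group log-normals for β̂, an empirical sample for
φ̂, all cut at their lowest 80% (empirical samples at the order statistic,
log-normals at the analytic 0.8 quantile). The synthetic stand-in used for
building and testing emulates the qualitative empirical patterns — mean
activity increasing with degree, β̂ medians decreasing with degree
(log-normal, σ = 0.8), a broad Beta(2, 4) threshold sample — and makes no
claim of matching any particular dataset; results on it demonstrate the
pipeline, not real-data accuracy. What passing tests show is therefore:
the machinery is correct and the qualitative phenomena (broad waiting
times, above-chance classification everywhere, the dominant-class pattern
over the inferred-parameter grid) are reproduced; they do not show that
real timelines would be classified with any particular accuracy.

## Timeline adapter

`timelines.build_ego_observations` converts ordered per-user post streams
with content flags into event-time ego observations: the degree counts
followees active in the lookback window, every followee content post before
the ego's first own content post is a stimulus, and a neighbour's first such
post marks it infected. The heuristic pre-classifier labels an adoption St
if no neighbour was infectious at the transition, Cx if the last influencing
event was a neighbour's first content post, and Sm otherwise; β̂
distributions are then fitted on Sm-labelled and φ̂ samples on Cx-labelled
instances (log-normal per degree group, groups under 10 instances falling
back to the global fit). The synthetic timeline generator
(`synthesize_timelines`) inverts the temporal simulator's post log, and the
round-trip — simulator bookkeeping vs adapter reconstruction — is asserted
exactly in the tests.

## Problem sizes and numerical conventions

* Ego-star sweeps: 10,000 contagions per (β, φ) cell over the
  {0.1, 0.3, 0.5, 0.7, 0.9}² grid, degrees from the zero-truncated
  Binomial(1000, 0.004) (truncation by rejection), leaf rate r_nb = 0.05.
  The batch simulator is event-driven (geometric leaf times, segment-wise
  geometric ego adoption) and exactly equivalent to the step-wise dynamics,
  including simultaneous leaf infections.
* Network sweeps: giant components of ER(1000, ⟨k⟩ = 4), r = 0.005, run to
  full infection; 5 realisations per cell; forests at 3,000/1,000 balanced
  instances per class before minority scaling, 2 repetitions. These scales
  were chosen as the package's desk defaults; all drivers accept larger
  values.
* Temporal runs: neighbour-walk reductions (~1,500 nodes) of ER(4,000)
  graphs, stopped at 90% infection. The reduction is a tree by
  construction — each accepted step adds one node and its connecting edge;
  when the walk selects an already-included node it moves there and
  reselects, which guarantees progress and connectivity.
* Expectations over the degree distribution are exact sums over the support
  with probability mass below 1e−12 dropped.
* All randomness flows through explicit `numpy.random.Generator` instances;
  no global RNG state is touched anywhere.

## Known limitations

* The closed-form ego-star accuracy is only as good as its
  simultaneous-infection neglect (see above); treat it as an approximation
  with error up to a few hundredths at high β.
* The unknown-parameter likelihood inherits the estimator pathologies
  documented above; the pooled random forest is the more reliable tool in
  that regime.
* The temporal model ignores content, directionality, retweet mechanics and
  circadian rhythm; its parameter distributions are stand-ins unless fitted
  to real timelines via `timelines.infer_param_distributions`.
* Networks are static and undirected; temporality enters through node
  activity only.
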