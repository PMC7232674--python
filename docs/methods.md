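# Methods

## Model

A Bayesian network over variables `X1..Xp` is a directed acyclic graph (DAG)
together with the factorization

    P(X1, ..., Xp) = prod_i P(Xi | pa(Xi))

where `pa(Xi)` is the parent set of node i. Nodes are typed: continuous or
discrete (with a declared level count). Mixed networks obey one structural
constraint throughout the package — a discrete child may only have discrete
parents; continuous children may have parents of either kind. Without the
constraint, adding continuous parents to a discrete child would require a
discretization or logistic model the benchmark does not define, and discrete
conditional tables would not stay finite.

The per-node conditional families are:

- **Linear Gaussian** (continuous child, continuous parents):
  `Xi ~ Normal(b0 + sum_j beta_ji Xj, sigma_i^2)`.
- **Multinomial** (discrete child, discrete parents): one probability row per
  parent-level configuration (a CPT).
- **Conditional Gaussian** (continuous child, mixed parents): a linear
  Gaussian regression on the continuous parents whose intercept (and noise
  variance, in the generator) varies with the discrete-parent configuration;
  marginally the child is a Gaussian mixture.

## Scoring

Structure quality is the decomposable BIC in the **maximized** convention

    score(G) = sum_i [ loglik_i - (k_i / 2) ln n ]

evaluated at per-family parameter estimates. One convention is used
everywhere; the classic failure mode here is mixing the `-2 loglik + k ln n`
form into half the code, so the identity `bic = loglik - (k/2) ln n` is
asserted in tests.

- Gaussian families: ordinary least squares with an intercept; the
  log-likelihood at the MLE variance; `k = #parents + 2` (slopes + intercept
  + variance). Families with (numerically) zero residual variance are
  *degenerate*: they carry an infinite sentinel and a flag, and search skips
  them instead of propagating infinities.
- Multinomial families: CPT rows estimated by the Dirichlet(alpha)
  posterior mean, alpha = 1 by default (add-one smoothing; alpha is
  configurable, alpha = 0 recovers the MLE). `k = (levels(child) - 1) *
  prod levels(parents)`; rows with no observations contribute zero
  log-likelihood.
- Conditional-Gaussian families: slopes shared across discrete
  configurations, one intercept per observed configuration,
  `k = #continuous parents + #intercept groups + 1`. Sharing slopes keeps
  the family estimable at n = 50 with several configurations; full
  per-configuration slopes are available behind a flag. Configurations with
  fewer rows than (#continuous parents + 1) are pooled into one fallback
  intercept group and flagged.

Scores depend only on (child, parent set, data values): the scorer assembles
all Gaussian quantities from a Gram (moment) matrix whose columns are sorted
by *name*, so results — and everything downstream — are exactly invariant to
the dataset's column order. Score equivalence across Markov-equivalent DAGs
is a property of the Gaussian likelihood, not an assumption the search
relies on.

## Two-phase search

**Phase 1 — family enumeration.** For every child, all type-admissible
parent subsets up to `max_parents` are scored (batched normal-equation
solves against the Gram matrix for continuous families). When the subset
count exceeds `enumeration_budget` (default 50 000), enumeration is staged:
all subsets of size <= 2, then one-parent extensions of the current top-K
only — feasibility for large p at the price of exhaustiveness, and the run
log says so. Each node keeps its K best families (`candidates_per_node`,
default 20) ranked by BIC, ties broken by fewer parents then
lexicographically; the empty family is always retained.

**Phase 2 — acyclic assembly.** Two assemblers maximize the summed family
BIC subject to acyclicity:

- `greedy_repair` (default): start from every node's best family; while the
  union has a directed cycle, apply the cheapest repair — demote one cycle
  member to its next-ranked family that drops the offending parent, choosing
  the repair that loses the least global BIC. Termination is guaranteed
  (every repair advances a node down its finite list; the empty family
  breaks any cycle) and the score is monotone over repairs. Repair alone,
  however, systematically stalls: at n = 1000 the best local families of
  upstream nodes are Markov-blanket sets full of their own descendants, so
  *no* good acyclic assignment exists inside the top-K lists. The repair
  result therefore seeds an **order refinement** pass: hill climbing over
  topological orders (adjacent transpositions plus single-node relocations,
  plus a few seeded restart orders), where each node takes its best phase-1
  family among its order predecessors. This is standard ordering-based
  search over the full phase-1 score table; it is greedy, monotone in the
  same objective, and in testing reaches the exact-DP optimum on most small
  instances and the true network's score at the benchmark scale. Refinement
  uses bitmask tables and so runs for p <= 64; beyond that the repair result
  is returned as-is.
- `exact_dp`: the order-based dynamic program over node subsets,
  `best(S) = max_{v in S} best(S\{v}) + bestfam(v, S\{v})`, exact over the
  candidate lists, exponential in p (capped at p = 20). It serves as the
  oracle for the greedy assembler in tests and as an exact option for small
  problems.

A classic single-edge add/delete/reverse hill climber over the same score is
included as an internal baseline (`hill_climb_baseline`).

**Tunable parameters.**

| parameter | default | meaning |
|---|---|---|
| `max_parents` | 6 | enumerated parent-set cap per node |
| `candidates_per_node` | 20 | ranked families carried into cycle repair |
| `enumeration_budget` | 50 000 | per-child subset count before staged enumeration |
| `restarts` | 2 | extra seeded starting orders for refinement |
| `alpha` | 1.0 | Dirichlet pseudo-count for CPT estimation |

The cap of 6 matches the customary per-node search-space limit for this
class of learners and, more importantly, covers the in-degree tail of the
bundled generator: at p = 20 and a mean of 1.5 parents per node, individual
nodes regularly draw 5–6 parents, and with a cap of 4 even the exact global
optimum is forced away from the true structure (measured: directed recovery
drops from ~0.95 to ~0.6 TPR because unrepresentable families induce
compensating false edges). Raising the cap costs enumeration time
(C(19, <=6) ≈ 28 000 subsets per node at p = 20, still ~1 s with batched
solves).

## Simulator

The generator reproduces a linear-SEM benchmark design:

- **Topology.** `random`: fix a uniformly random topological order, include
  each forward pair independently with probability `2 * mean_parents /
  (p - 1)` (expected in-degree = `mean_parents`, default 1.5). `scale_free`:
  preferential attachment with edges oriented old -> new (acyclic by
  construction), continuous networks only — discrete hubs would inflate
  their conditional tables without bound, which is also why discrete
  children cap their in-degree at `max_discrete_parents` (default 3; the
  cap keeps CPT rows <= levels^3).
- **Parameters.** Coefficient magnitudes `|b|` with `b ~ Normal(2, 0.8)` and
  an independent sign, positive with probability 0.5 — applying the sign to
  `|b|` makes `sign_prob` *exactly* the probability of positive regulation.
  Noise variances `sigma^2 ~ Normal(1, 0.01)` truncated below at 1e-3, so
  positivity is an invariant rather than a probability (at sd 0.1 the
  truncation is essentially never active). The second arguments are read as
  standard deviations by default; `scale_as_variance=True` flips the
  convention. Intercepts are 0 for purely continuous families.
- **CPTs.** Rows are Dirichlet(1, ..., 1) draws, rejection-sampled (cap
  1000 attempts) until every pair of rows whose parent configurations
  differ in one coordinate is at total-variation distance >= 0.1. This
  operationalizes "the child depends on every single parent" as a testable
  criterion.
- **Mixed families.** Continuous children with discrete parents get shared
  slopes over continuous parents and per-configuration intercepts drawn like
  coefficients — a conditional-Gaussian (mixture-of-Gaussians) child in a
  standard identifiable form.
- **Column shuffle.** Output column order is permuted (seeded) so learners
  cannot read the generative order; the permutation is stored and exactly
  invertible.

Datasets are sampled ancestrally in topological order. Everything is
reproducible from `(config, seed)`; replicate seeds are derived
deterministically and stay below 2^31.

**What the simulator does not emulate:** nonlinear or non-Gaussian
relationships, interventions, missing values, measurement error beyond the
Gaussian noise term, latent confounders, or sample-to-sample dependence.
Passing recovery tests therefore demonstrates correctness of the method
under its own generative assumptions — linear effects of magnitude ~2
against noise sd ~1 are a strong-signal regime — and says nothing about
model-misspecified real data.

## Evaluation

Directed-edge confusion counts with the strict convention: a learned edge is
a true positive only when endpoints *and* direction match; a reversed true
edge is a false positive (and the missed true edge a false negative).

    TPR = TP / (TP + FN)
    precision = TP / (TP + FP)      (reported as 0 and flagged when TP+FP=0)
    FPR = FP / (p (p - 1) - |E_true|)

The FPR denominator counts *ordered* non-true pairs; the choice (ordered vs.
unordered) is ambiguous in common usage, so it is fixed here, stated in the
output metadata, and a skeleton (direction-agnostic) panel is available as a
secondary view. Learner comparisons use the two-sided paired-sample t-test
per metric and setting, replicate-matched; no multiple-testing correction is
applied to the raw p-values, but a Holm-adjusted column is emitted
alongside. Zero-variance difference vectors are flagged rather than
producing NaNs.

Because the Gaussian BIC is score-equivalent, only *compelled* edges
(v-structures and their logical consequences) are orientable from
observational data; the orientation of reversible edges falls to
deterministic tie-breaking and is right about half the time. At the
benchmark's density roughly 85% of true edges are compelled, which is what
makes directed TPR ~0.9 reachable at n = 1000; at lower densities or weaker
signal the directed metrics are ceiling-limited below 1 even for an exact
maximizer.

## Numerical choices

- Degenerate (zero residual variance) fits: relative threshold 1e-12 against
  the child's variance scale; inf sentinel + flag; excluded from search.
- Rank-deficient designs are fit by pseudoinverse and flagged, not errored.
- Batched and single-family Gaussian scoring agree to ~1e-9 relative; tests
  pin both paths against an independently coded closed form.
- All tie-breaks (ranking, repair, refinement restarts, hill-climb moves)
  are deterministic: higher BIC, then fewer parents, then lexicographic.
  Fixed (data, config, seed) gives byte-identical serialized output.
- The refinement tolerance for accepting a move is 1e-9 in score.

## Known limitations

- Reversible-edge orientation is tie-broken, not inferred (see above).
- Staged enumeration (large p) is not exhaustive and can miss families that
  only score well at sizes >= 3 without a good size-2 prefix.
- Order refinement is a local search; no optimality guarantee beyond the
  p <= 20 exact-DP cross-checks.
- The conditional-Gaussian score's shared-slope assumption mismatches
  generators with per-configuration slopes (not the bundled one).
- No missing data, no latent variables, no equivalence-class (CPDAG)
  output.
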