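# Methods

## The decision model

`amvoi` values information in sequential management of a natural resource
whose dynamics are *structurally uncertain*. The system occupies one of `S`
discrete states `x`; each year the manager picks one of `A` actions `a` and
earns a return `R(a, x)` (benefits net of action cost). Dynamics follow a
Markov transition kernel, but which kernel is unknown: `K` rival models
`P_k(x' | x, a)` encode competing hypotheses, and a *model state* (belief)
`q` — a probability vector over the models — carries the current weight of
evidence. Transitions realized under management are themselves data: after
observing `x → x'` under `a`, the belief updates by Bayes' rule,

    q'(k) = q(k) P_k(x'|x,a) / Σ_j q(j) P_j(x'|x,a),

and expected dynamics at belief `q` are model-averaged,
`P̄(x'|x,a,q) = Σ_k q(k) P_k(x'|x,a)`. External investigations (experiments
conducted outside the managed unit) produce a datum `z` with model-specific
law `P_k(z)` and update `q` the same way.

Optimal management is a dynamic program over the joint (system state,
belief) space:

* **active** adaptive management anticipates learning — the future value in
  the Bellman backup is evaluated at the posterior belief implied by each
  successor state:
  `V[x,q] = max_a { R(a,x) + λ Σ_x' P̄(x'|x,a,q) V[x', q'(x')] }`;
* **passive** adaptive management evaluates the future at the current
  belief (`V[x', q]`): learning still happens when the policy is applied
  but is not sought.

Value-of-information metrics are defined against these optima:

* **EVPI** `= Σ_k q(k) V_k[x] − V[x,q]`, with `V_k` the single-model
  optimum — the worth of resolving model uncertainty outright. It is
  nonnegative: the adaptive optimum can never beat the belief-weighted
  average of best-case values.
* **EVSI (external)** `= Σ_z P̄(z|q) V[x, q'(z)] − V[x,q]` — a preposterior
  average over the predictive law of a not-yet-seen datum. It is zero for
  uninformative signals, equals EVPI for perfectly informative ones, and
  lies between those extremes otherwise.
* **monitoring EVSI** compares annual observation against observation every
  `m` years. A periodic solve commits each block's action sequence at the
  observation year (out-year actions may condition on the observed state,
  belief and earlier actions of the block — never on unobserved states).
  The averaged out-year value
  `V̄[x,q,a*] = Σ_x' P̄(x'|x,a*,q) V[x', q'(x')]` (with `a*` the periodic
  policy's in-year action and `V` the annual optimum) is what the manager
  attains without the out-year observation; `V[x,q] − V̄[x,q,a*]` is the
  marginal value of observing. Because an *average* of optimal values is
  compared against the optimum of one particular state that may enter that
  average, the quantity can be negative as well as positive.

## Numerical treatment

**Belief grid.** The belief simplex is discretized on the regular lattice
with spacing `h` (all probability vectors whose entries are multiples of
`h`). Values stored at lattice points are extended to arbitrary beliefs by
barycentric interpolation over the Freudenthal/Kuhn triangulation computed
in cumulative-sum coordinates, which keeps every interpolation vertex inside
the simplex, is exact at lattice points and reproduces affine functions of
`q`; for `K = 2` it reduces to piecewise-linear interpolation in `q(1)`.
Posterior beliefs inside backups are computed exactly and then interpolated
— never snapped to the nearest lattice point, which would bias learning
dynamics. Successor states of zero probability are skipped: their posterior
is undefined but carries zero backup weight. Impossible observations
(zero marginal likelihood) raise errors rather than returning a default
belief, because a silent fallback would corrupt valuation.

**Solvers.** Finite horizons use exact backward induction (λ = 1 allowed);
infinite horizons use value iteration with sup-norm tolerance `1e-8` and an
iteration cap of `10^6`, requiring λ < 1. Argmax ties break toward the
lowest action index, so policies are reproducible (and "do nothing" wins
ties where it is listed first). Periodic (`m`-year) solves enumerate the
`A^m` open-loop block sequences, propagate beliefs exactly along every
realized state path (pruning zero-probability branches), and iterate the
block operator — a contraction with modulus `λ^m`; `m = 1` reproduces the
annual solve to machine precision. Probability rows must sum to one within
`1e-10` on input; violations are rejected rather than renormalized, to
catch transcription errors in data files.

**Interpolation error.** Piecewise-linear interpolation of a convex value
surface overestimates between nodes, so grid values upper-bound the exact
values; consequently EVPI computed on the grid stays nonnegative up to
rounding, and EVSI can undershoot zero only at the scale of the local
interpolation error (measured in the tests by the largest second difference
of the value surface along the grid). Halving `h` shrinks that scale
quadratically where the surface is smooth.

**Monte-Carlo consistency checks** compare mean simulated returns of a
solved policy with the solved value. These use discounted infinite-horizon
problems, where the optimal policy is stationary — under a finite horizon
the time-`0` policy is not optimal for later stages, and simulating it
stationarily would bias the comparison. Trajectories are truncated once
`λ^t` has decayed below ~`1e-5`, far under the Monte-Carlo standard error
at `10^4` replicates. During simulation, actions are looked up at the
highest-weight lattice vertex of the manager's (generally off-lattice)
belief; the belief itself is never rounded.

## The scrub-jay example and the synthetic stand-in

The motivating application is prescribed-fire management of Florida scrub
for scrub-jay habitat: five height/openness classes (short-open,
short-closed, optimal-open, optimal-closed, tall-mix; optimal-height scrub
is the demographic source, the rest are sinks), three actions (do nothing,
routine burn, intensive burn) and two models — a null model under which
routine and intensive burns are interchangeable (making the dearer
intensive burn never optimal when the null model is certain) and an
alternative under which the intensive burn sets back succession harder in
the fire-resistant classes. The published per-class transition
probabilities and returns live in the original study's supplementary
material and are not redistributable here; `load_scrubjay()` loads a
user-supplied transcription and refuses to guess values in its absence.
The reference comparisons that need those numbers (the published
monitoring-comparison table at horizon 2000, λ = 1, grid step 0.001; the
sub-1% EVPI bound; the published policy-structure thresholds) are encoded
in `tests/test_acceptance.py` and fail at the fixture-loading step until a
transcription is supplied.

`load_scrubjay_synthetic()` ships a clearly-labelled **synthetic** stand-in
constructed once to exhibit the same qualitative structure: succession
advances under do-nothing, burns set vegetation back with open classes
responding well and closed/tall classes resisting, null-model burn kernels
identical, alternative-model intensive burn strongly more effective in the
resistant classes, and returns that favour optimal-open scrub net of burn
costs (intensive costing more than routine). On this fixture the active
policy uses the intensive burn only for short-closed, optimal-closed and
tall-mix and never when the null model is certain, and maximal EVPI is a
fraction of a percent of the objective — the structural signatures of the
real analysis. Its numbers are constructed, not estimated: quantitative
results on it are illustrative only, and passing tests on it demonstrate
solver correctness, not agreement with field data. The packaged external
signal is the one-year response of a short-closed unit elsewhere to an
intensive burn, `P_k(z) = P_k(z | short-closed, intensive)` — the minimal
construction of "observe an experimental burn at another site"; the
observed unit's state is configurable in principle by building a
`SignalModel` from any other kernel row.

The random-scenario generator draws each transition row from a symmetric
Dirichlet (concentration 1 by default — diffuse rows; large concentrations
approach uniform rows) and rewards uniformly on a configurable range, fully
reproducible per seed. The signal generator interpolates between one shared
outcome law (informativeness 0) and disjoint per-model supports
(informativeness 1). Neither emulates serial habitat correlation, spatial
structure, or estimated demographic rates, so property tests on generated
data validate the mathematics, not ecological realism.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| grid step `h` | 0.01 (CLI), 0.001 for published-table comparisons | belief | published policy threshold at 0.002 requires `h ≤ 0.002`; 0.01 suffices for the synthetic fixture's structure |
| discount λ | 1.0 in the fixture, 0.95 generator default | — | the reference analysis accumulates undiscounted returns over a fixed horizon |
| horizon | 2000 (fixture) | years | long enough that per-state values are effectively stationary |
| value-iteration tol | 1e-8 | sup-norm | far below any reported precision |
| probability tolerance | 1e-10 | row sums | catches transcription errors without rejecting binary-to-decimal noise |
| monitoring period `m` | 2 | years | the biennial comparison; any `m ≥ 1` is supported (cost grows as `(A·S)^m`) |

The acceptance script (`scripts/acceptance.py`) runs the synthetic fixture
at `h = 0.01` and the property battery at the sizes noted in its output
(`n` fields); these sizes were chosen so the full script and test suite
complete in minutes while leaving every check's conclusion unchanged at
finer settings.

## Known limitations

* System state is assumed perfectly observed in observation years; partial
  observability of `x` is out of scope.
* External signals are finite-alphabet; continuous signal spaces are not
  supported.
* Periodic solves enumerate `A^m` action sequences and `S^m` state paths
  per block, which is practical for small `m` (biennial, triennial) only.
* The monitoring schedule itself is not optimized and monitoring costs are
  not accounted; the package reports the value a schedule change would add,
  not whether it is worth its cost.
* Finite-horizon solves report the time-0 (first-stage) policy; the full
  nonstationary policy is not stored.
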