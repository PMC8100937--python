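# Methods

## Model

The package operates on a deterministic additive value model. A decision
problem is a set of alternatives evaluated on $k$ criteria; each criterion
has an optimization direction and either a declared scale (all ordinal
criteria: integer levels, here 1–4 verbal scales) or an open continuous
scale (distance, age). The intracriteria evaluation maps raw performances
onto $[0,1]$ with *linear* value functions — the model assumes the
decision maker's marginal value is constant across each scale, which is
the standard simplification when no single-criterion elicitation has been
done. The intercriteria aggregation is the weighted sum
$v(a) = \sum_j w_j v_j(a)$ with nonnegative scale constants summing to
one. Scale constants are tradeoff coefficients, not "importance" scores:
they scale the value of sweeping a criterion from worst to best.

Compensatory rationality is assumed throughout: a good performance on one
criterion can fully offset a poor one elsewhere, and alternatives are
always mutually comparable.

### Normalization anchors

Two anchor policies are implemented. `declared_bounds` anchors the value
function at the criterion's declared scale endpoints; `observed_range`
anchors it at the column minimum/maximum, so the observed best scores 1
and the observed worst 0. The default `auto` policy uses declared bounds
where the criterion has them (all ordinal criteria) and the observed range
otherwise (open continuous scales), which keeps ordinal value functions
stable across problems while never requiring bounds that were not stated.
A constant column is legal under declared bounds (constant value) and an
error under observed-range anchoring, since the value function would be
undefined.

The reported weight ranges of the packaged case do not depend on this
choice: they are functions of the weight polytope only.

## Partial weight information and LP queries

The admissible weight set starts as the ranked simplex
$\{w : \sum w_j = 1,\ w_{(1)} \ge \dots \ge w_{(k)} \ge 0\}$ and shrinks
as tradeoff answers arrive. Every query is a linear program solved with
HiGHS (`scipy.optimize.linprog`); the polytope is bounded, so only
infeasibility needs handling. Strict preference inequalities are realized
with a margin $\varepsilon = 10^{-6}$; feasibility and containment checks
use an absolute tolerance of $10^{-9}$.

For a ranking-only space the range endpoints have a closed form — the
polytope's vertices are the uniform prefixes $(1/m, \dots, 1/m, 0, \dots)$
— giving $\max w_{(m)} = 1/m$, $\min w_{(1)} = 1/k$, $\min w_{(m>1)} = 0$.
The test suite uses this closed form, and dense simplex-grid enumeration
at $k=3$, as independent oracles for the LP layer.

Reported ranges are rounded half-up at a configurable number of decimals,
because such reports conventionally print mixed precision (0.333 next to
0.17 next to 0.1).

## Screening

An alternative is *potentially optimal* if the LP
$\{w \in W : v(a) \ge v(b)\ \forall b\}$ is feasible, and *LP-dominated*
by $b$ if $\min_W [v(b) - v(a)] \ge 0$ with a strictly positive maximum.
Both screens are applied: pairwise non-dominance does not imply potential
optimality, and a weakly-best-only alternative (tied with the winner on a
face of the polytope, worse inside) passes the potential-optimality test
yet is removed by dominance. LP dominance is transitive and antisymmetric,
so elimination by "some potentially optimal alternative" coincides with
elimination by a survivor and the survivor set does not depend on the
order of the two screens.

In the packaged dispatch case the ranking information alone is already
decisive: victim 2 LP-dominates every other victim (for victim 1 the value
difference has minimum exactly 0, attained only at the vertex putting all
weight on the top criterion), so screening returns a singleton before any
question is asked. Interactive sessions on such problems terminate with
zero questions; the weight-range report then describes the ranking-only
polytope.

## Elicitation

Tradeoff questions compare two hypothetical consequences: criterion $a$
(higher-ranked) at an intermediate level with everything else at worst,
versus criterion $b$ (next in the ranking) at best with everything else at
worst. Under the additive model these are worth $w_a v_a(x)$ and $w_b$, so
each answer is one linear constraint; indifference — the classic tradeoff
condition — is the equality special case.

The question-selection heuristic is adjacent-pair bisection: track, per
adjacent rank pair, the interval of value levels within which the ratio
$w_b / w_a$ is unresolved; ask at the midpoint of the widest interval
(highest-ranked pair on ties). Consistent answers halve the interval, so
the implied ratio bracket shrinks geometrically, sessions are
deterministic given the answer stream, and the JSON-lines log replays a
session bit-exactly.

Two numerical guards follow from the strict-inequality margin. A two-sided
squeeze on one pair needs $(v_{hi} - v_{lo})\, w_a \ge 2\varepsilon$ to
remain satisfiable, so a pair stops being asked once its interval width
times the LP-maximum of $w_a$ falls to $8\varepsilon$ — beyond that point
the pair carries no further resolvable information. And answers that
genuinely contradict earlier ones (possible only with externally supplied
statements, since bisection always asks inside the feasible bracket) abort
with a diagnostic naming the offending statement rather than attempting
constraint relaxation.

If the question budget is exhausted with several survivors, the session
reports the survivor set and the current weight ranges instead of forcing
a choice.

## Sensitivity analysis

Each cycle redraws every selected consequence $p$ uniformly and
independently from $[(1-f)p,\ (1+f)p]$ (default $f = 0.2$), clamps the
result into the column's nominal extremes so the consequence space keeps
its original limits, rounds ordinal entries half-up to integer levels, and
re-screens. Uniform sampling is the minimal assumption given that only the
interval is specified. The value functions are anchored once on the
nominal matrix and reused across cycles: perturbing performances should
not silently re-scale the value axes, and it also keeps observed-range
columns well-defined when clamping collapses a perturbed column to a
constant. Defaults are 200 cycles with a mandatory seed; the report counts
per-alternative appearances in the potentially-optimal subset and flags
membership in the unperturbed subset.

## Synthetic problems and the simulated decision maker

The generator draws ordinal columns uniformly over their integer levels
and continuous columns uniformly over declared bounds, with a random rank
permutation; by default 80 % of criteria are 1–4 ordinal scales,
mirroring the mix of the packaged case (eight verbal scales out of ten
criteria). The simulated decision maker holds a hidden weight vector drawn
uniformly from the ranked simplex (a sorted flat-Dirichlet sample) and
answers every question by exact comparison of $w_a v_a(x)$ with $w_b$ — a
perfectly consistent, noise-free respondent. Recovery experiments in the
test suite run 200 random problems (up to 6 alternatives and 6 criteria,
budget 25 questions) and check that the alternative optimal under the
hidden weights is never eliminated and is returned whenever a session
converges; these sizes keep the full suite under a minute for this
experiment while covering every generator configuration.

What the generator does *not* emulate: correlated criteria, decision-maker
inconsistency or hesitation, indifference thresholds, and ties engineered
between alternatives. Passing the recovery suite therefore shows the
elicitation logic is sound for a consistent respondent, not that the
method is robust to human error — inconsistent answers are detected and
reported, never repaired.

## Known limitations

- Value functions are linear only; no piecewise or elicited
  single-criterion functions.
- Single decision maker; no group aggregation.
- No missing-data handling: a matrix must be complete to load.
- The sensitivity report is subset-membership counting, not a tornado or
  weight-perturbation analysis.
- Potential optimality is decided with weak inequalities at solver
  tolerance; alternatives optimal only on a measure-zero face are
  reported as potentially optimal but are then removed by the dominance
  screen when a strictly better survivor exists.
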