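# Methods

## Model

A network of `n ≥ 2` genes with binary expression levels is specified by a
genome of `N = n·2^n` bits: for each gene, one truth-table column of length
`2^n` listing its next expression level in response to every network state.
States encode to integers with the first-listed gene as the most
significant bit, and genomes serialize as `N`-character 0/1 strings (the
concatenation of the columns in gene order, each indexed by the integer
encoding of the current state). This layout is the package's normative file
format; any fixed self-consistent bit ordering yields identical statistics,
since all results are averages over genome space or over seeded random
draws.

Under synchronous updating all genes switch simultaneously, so the
dynamics are a deterministic map on the `2^n` states and every trajectory
ends in a point attractor (fixed point) or a limit cycle of `T ≤ 2^n`
distinct states. The attractor from an initial state is located by
iterating `2^n` steps (enough to guarantee the trajectory has entered its
cycle) and then walking once around the cycle; the stored cycle starts at
the first repeated state, and cycle *identity* (for counting and
statistics) is its state set, which is phase-invariant.

### Fitness

Given contexts `(initial_x, target_x)`, fitness is

    f = prod_x prod_g ( 1 − (1/T) sum_t | s′_{g,x} − s_{g,x,t} | ),

the product over contexts and genes of the fraction of attractor states in
which the gene matches its target level. Only the `T` attractor states
enter the synchronous average — the transient is excluded. `f = 1` iff
every context's initial state reaches its target as a point attractor, and
`f = 0` iff some gene is wrong in every state of some context's attractor.
Because every non-unit per-gene factor is at most `1 − 1/T ≤ 1 − 2^{-n}`,
floating-point rounding cannot produce a spurious `f = 1`.

### Evolution

A single lineage is evolved. Each generation flips every bit of the
current genome independently with probability `p ∈ [0, 0.5]` and accepts
the proposal iff its fitness does not decrease (`Δf ≥ 0`, so neutral drift
is accepted). Every generation counts toward the discovery clock, accepted
or not, with or without actual flips (consistent with the mean discovery
time diverging as `p → 1/N`). When the accepted fitness reaches the
threshold (1.0 for synchronous runs) the generations since the last reset
are recorded as one discovery and the lineage restarts from a fresh
uniform-random genome; a starting genome already at threshold records a
discovery of 0 generations. Whether the original study reset or let
lineages drift at `f = 1` is not derivable from its description;
reset-on-discovery is this package's documented choice and makes
discoveries i.i.d. across epochs. At `p = 0.5` every proposal is an
independent uniform sample of genome space, so discovery times are
geometric with success probability equal to the density of maximally fit
genomes — the random-search control against which speed-ups are measured.

### Asynchronous variant

Asynchronous updating changes one uniformly chosen gene per step (chosen
with replacement; no shuffled sweeps). Fitness is evaluated over a fixed
window: from each context's initial state, `T = 2N` single-gene updates
are performed (320 for `n = 5`) and the same product formula is applied
with the time average over the `T` post-update visited states; the initial
state itself is excluded, keeping exactly `T` states per context. The
result is a noisy, bounded estimate, reproducible for a fixed seed. In the
evolutionary loop each proposal gets one fresh evaluation and the
incumbent's stored (noisy) value is re-used for the comparison — one
evaluation per generation, mirroring the synchronous loop's cost
structure; re-evaluating the incumbent every generation was examined and
destroys hill-climbing (the accepted genome churns with the noise and
discovery times explode by orders of magnitude). Asynchronous epochs
terminate when the accepted fitness strictly exceeds 0.95; accepted noisy
fitness is *not* monotone in the underlying expected fitness, and the
package makes no such claim.

The asynchronous mean-discovery curve reproduces the synchronous-style
acceleration at low mutation rates, but its measured log-linear slope over
`p ∈ [0.2, 0.35]` (≈ 8–10 at 50–200 runs per rate) is shallower than the
published ≈ 13.6; the curve steepens only near `p ≳ 0.4`. The ceiling of
the curve is implementation-independent — at `p = 0.5` the mean discovery
time equals the reciprocal probability that a single evaluation of a
uniform-random genome exceeds 0.95 (measured ≈ 1e5 generations) — which
suggests the published curve reflects a lower-noise evaluation than a
literal single 320-update window. Several alternative readings (shuffled
gene sweeps, multi-update strides between recorded states, averaged double
evaluations, incumbent re-evaluation) were tested and all sit further from
the published means than the literal reading, which is the one shipped.

## Exhaustive census and density

For `N ≤ 24` (`n = 3` gives 2^24 ≈ 1.7e7 genomes) the space is enumerated
outright, vectorized over chunks of 2^21 genome integers: each chunk's
transition maps are built by bit extraction and every context is checked
combinatorially ("reaches the target within `2^n` steps and the target is
a fixed point") with no floating-point fitness in the loop. Larger `n`
(refused without `force=True`) use uniform Monte-Carlo sampling with a
Clopper-Pearson binomial interval instead.

## Boolean-function statistics

Complexity of one gene's rule is the exact minimum number of product terms
in an equivalent DNF, normalized by `2^n`. All `3^n` product terms are
enumerated as row-coverage bitmasks, those implied by the function are
reduced to the prime implicants (exactly the Quine-McCluskey prime set),
and a branch-and-bound exact set cover over the function's true rows —
equivalent to Petrick's method — returns the fewest-term cover, which is
also available explicitly and always evaluates identically to the input
table. Conventions: constant-false costs 0 terms (empty disjunction),
constant-true 1 term (empty product), keeping the count monotone under
adding minterms. The guard `n ≤ 8` bounds the 3^n enumeration.

A gene is canalizing when fixing some *other* gene's input level forces
its output constant; constant functions are vacuously canalizing (their
density among random tables, `2^{1−2^n}`, is negligible for `n = 5`). A
network "contains canalizing functions" when at least one of its genes
does. The vectorized estimator packs columns into 32-bit integers and
tests all (input, level) restrictions with mask operations; for random
`n = 5` networks the analytic rate is ≈ 0.122% (union bound
`5·8·2·2^{-16}`), and the estimator reproduces it at 1e6 samples. Bias is
the fraction of 1s among all `N` bits; the attractor census counts the
distinct cycles of the transition map over all `2^n` initial states.
Evolved-network statistics default to genomes discovered at `p = 0.1` (the
mutation rate used for the published punctuated-equilibria traces; the
original sampling rate for the 1e4 fit networks is unstated).

## Experiments

Sweeps collect independent discovery batches per condition with seeds
spawned deterministically from one master seed. μ is the arithmetic mean
of discovery times (medians are also reported, since the distributions are
long-tailed); uncertainty is a percentile bootstrap of the mean with 1024
resamples at 95% by default. The mutation-rate law fits `ln μ = a·p + b`
by ordinary least squares over condition means (exact recovery on
synthetic exponential data; standard errors from the OLS fit).
Distribution shape is characterized by maximum-likelihood log-normal
parameters with a D'Agostino-Pearson normality test on log-times.

The target-distance sweep fixes the posterior context `00000 → 01010` and
the anterior initial state `10000`, and places the anterior target at
exact Hamming distance `h` from the posterior target by flipping its
leftmost `h` bits — which reproduces the published endpoints (`11010` at
`h = 1`, `10101` at `h = 5`); which bits flip for intermediate `h` is an
exposed parameter, since no convention is published. Context-count sweeps
use the canonical two neocortex contexts for `X = 2` and seeded random
sets with all-unique initial and target states otherwise, recording the
sets in the result metadata; speed-up is the ratio of mean discovery time
at `p = 0.5` to that at the low mutation rate under comparison (0.05 for
the context-count experiment, 0.1 for the target-distance experiment).

## Problem sizes and reproducibility

Simulated sample sizes are chosen so each statistic's sampling error is
small against the effect being measured while a full reproduction runs in
minutes on one CPU: 1000–2000 runs for single-condition discovery means,
1200 runs for `p = 0.5` controls entering ratio estimates (the control
distribution is near-geometric, so its mean converges slowly), 300–500
runs per rate for exponential-law fits, 50 runs per rate for the
asynchronous law (each evaluation is ~10× costlier), 1e4 networks for
complexity/attractor means and 1e6 for the rare canalizing fraction. The
original study's control budgets of 1e8–2e11 generations and its exact
X = 3/X = 4 context sets are not reproduced; scaled-down ordering checks
stand in. All loops consume a single numba RNG stream seeded per run;
results are deterministic given (config, seed) on a fixed software stack.

## Known limitations

- Binary expression only; no continuous/ODE dynamics, no multi-level
  expression, no probabilistic Boolean network semantics beyond the single
  random-gene update scheme.
- The synthetic experiments sample idealized uniform-random genomes and
  exact context specifications; they say nothing about parameter
  identifiability in real expression data, measurement noise, or the
  biological fidelity of the five-gene neocortex abstraction beyond its
  role as a canonical test case.
- Exhaustive census is limited to `N ≤ 24` by design; minimal-DNF search
  to 8 inputs; landscape export and attractor census to `n ≤ 16`.
- Asynchronous discovery-time curves match published values only at low
  mutation rates (see above); the synchronous model reproduces all
  published quantities tested.
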