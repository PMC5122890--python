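# Methods

## Game model

Each agent plays the two-strategy spatial prisoner's dilemma against all of
its network neighbors each round. With cooperation `C` and defection `D`
encoded as unit vectors, the pairwise payoff of focal strategy `s_x`
against `s_y` is `s_x^T P s_y` with

    P = [[R, Su], [Te, Pu]] = [[1, 0], [b, 0]],   1 < b < 2.

`R = 1` rewards mutual cooperation, the temptation `Te = b` (default 1.2)
is what a defector extracts from a cooperator, and `Pu = Su = 0`. The
ordering `Te > R > Pu >= Su` with `2R > Te + Su` keeps the game a social
dilemma. An agent's round payoff is the weight-weighted sum of pairwise
payoffs over its neighbors (weights `x_ij >= 1`).

Strategy updating is synchronous Fermi imitation: after payoffs are
computed, every agent picks one uniformly random neighbor `j` and adopts
`S_j` with probability `1 / (1 + exp((P_i − P_j)/κ))`. The rationality
noise `κ` (default 0.1) admits occasional payoff-decreasing imitation; the
exponent is clamped at ±700 to avoid overflow. Isolated nodes earn 0 and
never change strategy (a warning is emitted).

## Observation protocol (what the synthetic data emulate — and what not)

These dynamics have absorbing homogeneous states. All-defector
configurations earn zero payoff everywhere; all-cooperator configurations
make every pairwise payoff equal to `R`. Either way, once strategies stop
varying the recorded rounds become linearly redundant and the per-node
design matrices `A_i` lose rank — the inverse problem is only well posed
while strategies keep changing. At the mean degrees studied here (6-12)
synchronous Fermi dynamics reach quasi-absorption within roughly 5-15
rounds, far less than the 1.6·N rounds the reconstruction experiments use.

The simulator therefore records **episodes**: every `episode_rounds` rounds
(default 6, i.e. just under the typical absorption time, so nearly every
round carries structural information) the strategy vector is redrawn i.i.d.
Bernoulli(`init_coop_fraction`, default 0.5) and the game restarts. One
trace is a concatenation of short, independently initialized bursts of the
true dynamics — the natural way to observe a game system repeatedly rather
than once. Setting `episode_rounds=None` yields one uninterrupted run; the
test suite uses that mode to verify the absorbing-state behavior itself.

Consequences for interpretation: passing tests show that weighted networks
are recoverable from short, repeatedly restarted game observations with
additive Gaussian payoff noise. They do not show recoverability from a
single long run that has fixated, nor robustness to unobserved agents,
strategy-recording errors, or time-varying networks — none of which the
generator emulates.

Measurement noise is additive i.i.d. `N(0, σ²)` on the payoff vector `Y_i`
only (the strategies, and hence `A_i`, are observed exactly), applied per
node with per-node seeds.

## Per-node inverse problem

For focal node `i`, `Y_i[t]` is its recorded payoff and
`A_i[t, l] = S_i(t)^T P S_l(t)` for every candidate neighbor `l != i`
(entries take values in {0, 1, b}). The focal column is excluded —
`x_ii = 0` structurally — and estimated rows are re-embedded to length N
with a zero at `i`. The relative data length `N_M = M/N` measures how many
rounds are available per unknown; fractional `N_M · N` is rounded half up.

## Sparse solvers

The single-penalty baseline solves

    min_{x >= 0}  (1/2m) ‖Y − A x‖₂² + λ ‖x‖₁

by coordinate descent (scikit-learn's `Lasso(positive=True)`; λ = 0 falls
back to NNLS). Nonnegativity reflects the weight convention (weights are 0
or >= 1; signs are meaningless). The m-normalized squared-error scaling
puts λ on a data-independent scale; the front objectives `f1 = ‖Y − Ax‖₂`
(unsquared) and `f2 = ‖x‖₁` are always recomputed from returned weight
vectors, so the solver's internal scaling never leaks into the
multiobjective model. KKT optimality is exposed via `kkt_violation` and
support recovery is cross-checked in the tests against exhaustive support
enumeration (every subset, NNLS per subset) on systems with <= 12
candidates. The baseline penalty is λ = 0.001.

## Multiobjective engine

A dominance-based EA minimizes `(f1, f2)` jointly:

* fast nondominated sorting (sorted-sweep peeling, O(n log n) per front for
  two objectives; verified against O(n²) pairwise dominance),
* NSGA-II crowding distance with infinite crowding at front boundaries,
* binary-tournament mating (rank, then crowding),
* simulated binary crossover (η_c = 15, rate 0.9) and polynomial mutation
  (η_m = 20, per-gene rate 1/n) on [0, 10], clipped at 0,
* a soft-thresholding operator `max(w − θ, 0)` applied to a quarter of the
  offspring with θ ~ U(0, 0.5 × mean positive weight), which injects
  sparser candidates,
* elitist μ+λ truncation back to the population size, plus an **external
  archive** of every nondominated solution encountered (capped at 4× the
  population by crowding). The archive is the returned front; this
  guarantees that good initial seeds can never be lost to diversity
  pressure, and makes the best-known `f1` and `f2` monotone over
  generations.

Initialization is either IPL — one nonnegative-lasso solution per penalty
on a log grid `λ ∈ [10⁻⁴, 1] × λ_max` (λ_max = the null threshold
`max_j A_jᵀY / m`, so the grid spans the all-zero vector down to a dense
low-error fit), with the baseline penalty 0.001 always included so the
front weakly dominates the single-λ lasso — or IPR, uniform random weights
on [0, 3]. Library defaults are pop 100 / 200 generations; the experiments
and acceptance runs use pop 60 / 80 generations, which reproduce the same
recovery quality at desk scale.

## Knee selection

The front is pruned of its `k = 10` largest-error members (those are
near-empty vectors; full reconstruction lives where the error term is
near 0), normalized per objective by the front maximum, fitted with a
smoothing B-spline (smoothing 0.005 in normalized units) and resampled at
100 arc-length-uniform points. Each interior point is assigned the largest
of the four vertex angles formed with its two left and two right neighbors,
the neighbors sitting 5% and 10% of the curve away so that the probe scale
is independent of resampling density. On a locally straight curve the
assigned angle is π; a bend pulls it below π, so the knee is the point
whose assigned angle is smallest, ties resolving to the smallest error.
Two numerical guards matter in practice:

* **Sharpness gate.** An interior bend counts as a knee only if its angle
  drops at least 0.35 rad below π. Evolved fronts here typically terminate
  *at* the noise-floor corner (no arm extends above the true solution), so
  interior curvature is weak; when nothing clears the gate, selection
  degenerates — per the straight-front tie-break — to the lowest-error
  Pareto member, which on these fronts is also where the reconstruction
  error is smallest.
* **Degenerate fronts** (fewer than two survivors, or too few distinct
  points for a spline) fall back to the lowest-error member directly.

The knee found on the resampled curve is mapped back to the closest
original front member in normalized space.

## Scoring

* `RE = Σ_{i≠j} |x̂_ij − x_ij| / Σ_{i≠j} x_ij` — 0 at perfect weighted
  recovery, 1 for an all-zero estimate; undefined (error) for an empty
  truth.
* TPR/FPR/Precision binarize at 0.5 — the maximum-margin cut between
  "no edge" (0) and the smallest admissible weight (1); precision of an
  empty prediction is defined as 1.
* AUROC (rank statistic, tie-corrected) and AUPR (average precision) pool
  all unordered node pairs network-wide, scored by estimated weight
  against true edge presence.

## Assembly

Per-node problems are independent; rows are estimated separately (per-node
seeds spawned from the master seed via `SeedSequence([master, node])`) and
symmetrized by averaging `(x̂_ij + x̂_ji)/2` (max/min offered as options).
Averaging is weight-preserving when both row estimates agree and halves a
one-sided spurious weight, which also pushes it below the 0.5 edge
threshold.

## Problem sizes used in tests and the acceptance script

Noise-free recovery: ER N=30, ⟨k⟩=6, N_M=1.6, σ=0. Karate-club benchmark:
N=34, weights U[1,3], σ=0.05, N_M=1.6, 10 realizations. Knee-vs-optimum:
single-node systems on ER N=100, ⟨k⟩=12, σ=0.05, N_M ∈ {0.4, 0.8, 1.2},
10 runs each. Initialization comparison: single-node ER N=50, ⟨k⟩=12,
σ=0.1, N_M=1.0, 10 matched seeds. Front-optimum vs lasso: ER N=50, ⟨k⟩=6,
σ=0.05, N_M ∈ {0.2, 0.4, 0.6, 0.8}, 5 realizations. Data-length sweep: ER
N=50, σ ∈ {0, 0.05, 0.3}, N_M endpoints 0.4 and 1.6, 3 replicates. These
sizes and replicate counts are the package's chosen desk-scale conditions;
larger sweeps run through `moeanet benchmark`.

## Known limitations

* Indirect-interaction effects are not removed: at low data lengths the
  estimate can place weight on two-hop neighbors.
* Knee detection on fronts without a geometric knee reduces to
  lowest-error selection (see the sharpness gate above); on such fronts
  the angle machinery adds robustness, not information.
* The weight distribution of the synthetic generators is uniform on
  [1, 3]; heavier-tailed weights change the difficulty of the RE metric
  but not the pipeline.
* Only undirected networks are supported; the game and the assembly both
  assume symmetry.
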