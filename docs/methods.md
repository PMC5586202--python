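# Methods

This note documents the models implemented in `sitefid`, the defaults and
why they were chosen, the numerical decisions that are not visible from the
API, and what the synthetic-data tests do and do not demonstrate.

## Data model

Trajectories are regular sequences of 2-D fixes at a fixed interval
(`tick_minutes`, default 10) inside an axis-aligned rectangular nest
(default 50 × 35 mm, entrance midway along the front wall). Missing fixes
are kept in-band (NaN coordinates on a contiguous tick axis), never as
dropped rows, so every algorithm can see the gap structure. All durations
are reported in minutes; a single-fix visit has dwell 0 by the literal
stop − start definition.

Space is discretized into square cells (default 3 mm, about one ant length;
17 × 12 = 204 cells on the default nest). Cells are half-open
[kc, (k+1)c) with points on the far nest edges clamped into the last
row/column, so the map from in-nest points to sites is total and single-
valued. Boundary cells may be partial; with 3 mm cells on a 50 × 35 mm nest
the last column and row are 2 mm slivers. All cells are indexed; only
visited cells are ever tested.

Brood censuses are snapshots every few hours. Lookups use the latest census
at or before the query tick (carry-forward): brood moves slowly, and
interpolating between snapshots would add machinery without information.

## The RW null model

A synthetic replicate of trajectory i is built by drawing, with
replacement, from i's empirical step-length and turn-angle distributions
(steps only between consecutively observed fixes; turns only where two
consecutive steps exist — gaps break both sequences). Constraints: the
replicate starts at i's first observed coordinate with a uniform random
initial heading (the data carry no heading prior); any proposed step
landing outside the nest is discarded and redrawn; after 1,000 rejections
at one step the turn is redrawn uniformly, which cannot fail in a convex
nest for step lengths observed inside it; and i's exact missing-fix
pattern is re-imposed on the finished walk. The walk is continuous through
gap ticks and masked afterwards, mirroring the fact that real gap-bridging
displacements were excluded from the sampled distributions.

Step and turn are drawn independently by default; `joint=True` draws
(step, preceding-turn) pairs instead, for users who prefer to preserve the
step/turn correlation. The results are insensitive to this choice for the
trajectories the package targets.

Ensembles are simulated with all replicates advancing in lock-step from one
seeded generator. This vectorisation is why 10,000-replicate ensembles are
practical; the ensemble is a pure function of (trajectory, seed, R). The
location-shuffling null draws each observed tick's coordinate uniformly
from the pooled fixes of all colony members including the focal ant
(excluding it changes nothing material and breaks the single-ant case).

## Site statistics and inference

A visit is a maximal run of consecutive observed ticks in one site. A
missing fix terminates the current visit — presence is no longer
demonstrably uninterrupted — which is conservative for dwell; return times
(end of one visit to start of the next at the same site) may span gaps.
The return after the last visit to a site is censored at the ant's last
observed tick (not the global experiment end, so trailing gaps do not
inflate censoring times).

The typical return time per site is the restricted mean: the area under
the Kaplan–Meier curve of the (n_is − 1 events + 1 censored) return
observations, up to the largest observation. With no censoring this is
exactly the arithmetic mean. It is computed by a direct product-limit pass
(at ties, events are processed before censorings with both still at risk);
the in-package implementation exists because the computation sits in the
innermost loop of the null distributions (one call per replicate × visited
site) where a general-purpose fitter is orders of magnitude too slow. It is
cross-checked against an independent Kaplan–Meier integration oracle to
1e-9 relative tolerance.

Null distributions per site: the visit count contributes one value per
replicate (zero when the replicate never visits the site); dwell and
return are conditional on the replicate visiting the site, so their null
sample size ("coverage") varies. Dwell/return tests require coverage ≥ 50
(`min_coverage`); below that the metric is reported untestable rather than
tested against a sample too small to define tails. z-scores use the null
mean and (ddof=1) SD. Permutation p-values are two-tailed with add-one
correction, p = min(1, 2·min[(#null ≤ obs)+1, (#null ≥ obs)+1]/(R+1)),
which is consistent with the 0.025/0.975 quantile rule at α = 0.05.
Benjamini–Hochberg correction is applied per ant and per metric across its
visited sites (the families the multiple-comparison argument defines);
classification is attracted/avoided by the direction of the deviation
(faster-than-null returns count as attraction), with an additional
`outside_null` flag for observations outside the whole null range. The
permutation floor matters: with R replicates the smallest achievable
two-tailed p is 2/(R+1), so BH can only ever reject when
2/(R+1) ≤ α k/N_i. Detection-oriented runs should use R in the thousands
(the package default is 10,000); small R is fine for calibration checks.

The reductive comparison test classifies an ant by N_i (distinct sites
visited) against the null N distribution: fidelity below the 0.025
quantile, roaming above the 0.975 quantile, else neutral.

## Overlap networks and communities

VI is computed on visit-count distributions normalized per ant
(utilization-distribution convention), equals 1 − total-variation distance,
and satisfies the identical→1 / disjoint→0 boundary cases exactly.
Zero-weight edges are dropped before partitioning (no modularity content).
Community detection uses igraph's Reichardt–Bornholdt spin-glass optimizer
(γ = 1, seeded; applied per connected component, isolated vertices become
singletons; components of ≤3 vertices are taken as single communities —
the annealer stalls on such graphs and a connected ≤3-vertex component
with positive weights is modularity-optimal as one group). A deterministic
greedy-modularity fallback (`method="greedy"`) exists for quick runs. A
colony is *unpartitioned* when the best partition has ≤1 community or
non-positive modularity; its ants are excluded from community-labelled
analyses. The community containing the queen is labelled "nurse", the rest
"other". Community space-use maps average n_is over members and count, per
site, the members for which the site is attracted-classified (consensus).

## Return-dynamics survival model

One record per visit: response = return time (event) or censoring time;
predictors = dwell time in minutes (untransformed, so the hazard ratio is
per minute), caste (queen = 1), community (nurse = 1), and the four brood
stage counts at the site, taken at the visit's *start* tick (the brood
context when the ant arrived; start vs end makes no material difference at
8-h census resolution). Colonies without a ≥2-community partition are
excluded when community is a predictor, since their ants cannot be
labelled.

The engine maximizes the Cox partial likelihood by Newton–Raphson with
step-halving (Efron ties by default — return times sit on a 10-minute grid
and are heavily tied — Breslow optional; both agree exactly when event
times are distinct). Variances: observed-information ("model"),
cluster-robust sandwich over per-record score residuals summed by cluster
(default cluster: ant, uniquely identified within colony), or a log-normal
shared frailty per ant or per colony. The frailty is fitted by penalized
partial likelihood — group log-frailties enter as ridge-penalized
indicator coefficients — with the frailty variance θ maximizing the
Laplace-approximate integrated likelihood
l(θ) = lp(β̂, b̂) − b̂ᵀb̂/(2θ) − ½ log det(θ K_bb + I). AIC uses the partial
(or integrated) log likelihood with k = number of fixed effects (+1 for
θ); `model_selection` fits candidate variance structures and returns the
minimum-AIC fit, resolving ties to the earlier candidate. Fully nested
(ant-within-colony) bivariate random effects are out of scope; the shared
frailty captures the dominant per-individual heterogeneity. Reported SEs
are on the coefficient scale, with the delta-method SE of the hazard ratio
(HR·SE) alongside, since conventions differ between packages.

Numerical notes: the linear predictor is shifted by its maximum before
exponentiation (scale-invariant, prevents overflow); constant predictors
are dropped with a warning (all-constant is an error); convergence is
declared at |Δ log L| < 1e-9 relative.

## Simulators

* **Unbiased walker**: correlated random walk; gamma(1.5, 1.5) step
  lengths (mean 2.25 mm per 10-min tick — short within-nest ant steps),
  von Mises(0, κ = 1) turns (moderate persistence), boundary by rejection.
  No printed step distribution exists for within-nest movement, so these
  are chosen once as field-plausible and kept configurable.
* **Biased walker**: each tick the correlated-walk heading h and the
  bearing b to a fixed attractor are mixed by circular interpolation,
  atan2((1−w) sin h + w sin b, (1−w) cos h + w cos b). w = 0 reduces
  *exactly* to the unbiased walker (same draws, same path); w = 1 is a
  beeline. This is the simplest mechanism with both limits correct; it
  concentrates visits without shrinking total coverage at moderate w,
  which is precisely the regime where area-based tests fail (w = 0.3 is
  the package's "moderate bias" reference condition).
* **Self-attracting walker**: lattice walk on the analysis grid; each tick
  the next cell is drawn from {current cell} ∪ 4-neighbourhood (clipped at
  walls) with probability ∝ exp(u · visits(cell)), then the occupied
  cell's count is incremented; coordinates are jittered uniformly within
  the cell. Including the current cell is deliberate: at a 10-minute tick
  a mover forced to change cell every tick would have identically zero
  dwell times, and the dwell→return test would be degenerate by
  construction. Stay-inclusive reinforcement lets familiar cells hold the
  walker longer *and* pull it back sooner — the joint signature the
  survival model detects. u = 0 reduces to a uniform choice among the ≤5
  candidates.
* **Colonies**: one queen (biased toward the brood centroid, w = 0.5) plus
  15 workers from a configurable archetype mixture (default: equal parts
  brood-biased, entrance-biased, and unbiased workers, w = 0.4), 289 ticks
  (48 h), 10.6% missing fixes placed uniformly at random (real gaps are
  somewhat bursty; uniform placement is harsher on visit continuity and
  therefore conservative), brood in four stages clustered near the nest
  centre-back with small per-census drift, censuses every 8 h.

## What the synthetic tests show — and what they do not

The generators produce movement with known, controllable bias and no
social interaction, pheromone fields, task switching, diel rhythm, or
measurement noise beyond missingness. Passing tests therefore demonstrate
that the *statistical machinery* is correct and calibrated: unbiased
walkers are not flagged (≤10% of 100 walkers with any post-FDR site at
R = 200), biased walkers are caught by site tests where the area test
stays silent, reinforced walkers produce dwell HR > 1 while unbiased ones
do not, and planted community structure is recovered. They do not
demonstrate that real ants are well described by these walk models; on
real data the framework's conclusions are conditional on the RW null being
the right "no preference" reference, which is its central modelling
assumption (it conditions on the observed step/turn distributions and gap
pattern).

## Problem sizes used in the shipped tests

Test-suite runs use ensemble sizes of 60–4,000 replicates, 50–100 synthetic
walkers per scenario and colonies of 7–17 ants, chosen so the whole suite
completes in a few minutes on one CPU while keeping every assertion at the
scale stated in its docstring. Production analyses should use the 10,000-
replicate default; the permutation-floor arithmetic above says everything
relevant about how R trades off against per-site FDR resolution.
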