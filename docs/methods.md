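# Methods

## Model and sampling problem

A constraint-based metabolic model is held as a dense m×n stoichiometric
matrix `S` with flux bounds `lb ≤ v ≤ ub` (mmol·gDW⁻¹·h⁻¹ by convention).
The steady-state flux space `P = {v : Sv = 0, lb ≤ v ≤ ub}` is a bounded
convex polytope inside the nullspace of `S`; its effective dimension is
the nullspace dimension minus coordinates fixed by `ub − lb ≤ 1e−9`.
Reversible reactions are kept signed (negative lower bound); splitting
them into forward/backward halves would double the dimension and distort
the geometry the samplers rely on.

Because `{Sv = 0}` is a linear subspace, the difference of two feasible
points is always a mass-balance-preserving direction. Every sampler move
exploits this closure property, so equality constraints are violated only
by accumulated floating-point round-off, which is removed by an orthogonal
projection onto the nullspace every 100 iterates and before any sample is
stored. Bound overshoots up to `bound_tol` after projection are clamped to
the bound. The projection never repairs residuals above `drift_limit`
(1e−3 relative); such a residual means the chain is corrupted and is a
hard error.

## The ACHR iterate and the three chain policies

One iterate: draw a point `p` uniformly from the direction pool, form
`d = (p − c)/‖p − c‖` where `c` is the running mean of every point the
chain has absorbed (warm-up set plus all accepted iterates), intersect the
line through the current point with the bounds, and jump to a uniformly
chosen point of that segment. Directions toward the empirical center
preferentially align with the polytope's elongated axes, which is what
makes the method practical on anisotropic flux spaces. The iterates are
not a Markov chain (the direction distribution depends on the whole past),
so no asymptotic uniformity guarantee exists for any policy built on them;
convergence is assessed empirically (below), and results on
high-dimensional models should be read with corresponding caution.

Warm-up points are LP optima: minimising and maximising each reaction flux
in turn gives 2n boundary points whose pairwise directions span the
polytope. The gp policy additionally draws random-weight LP optima
(`max cᵀv`, `c ~ U[−1,1]ⁿ`) when more than 2n start points are needed.
Since LP optima sit on the boundary — where the feasible segment through a
point degenerates — the whole warm-up set is pulled toward its centroid,
`x ← c + τ(x − c)`. The pulling coefficient is not specified anywhere
authoritative; the default `τ = 0.5` is a documented engineering choice,
is recorded in every sample matrix's provenance, and is configurable.

Policies:

* **hr** — directions uniform on the unit sphere of the free nullspace
  (standard normal in an orthonormal basis, normalised); one chain,
  optional thinning. Baseline only.
* **gp** — `nS` warm-up points, one short chain per sample, each chain
  runs exactly `st` iterates with the full warm-up set as its (static)
  direction pool and the warm-up centroid as initial center, and returns
  its end point. Restarting at boundary-derived points is precisely the
  behaviour that biases this policy at small `st` on large models.
* **optgp** — 2n warm-up points only, `nP` chains, chain j starts at a
  warm-up point chosen uniformly by its own RNG stream and stores every
  `st`-th iterate until it has its share of `nS` (earlier chains take the
  remainder of `nS mod nP`). The direction pool is the warm-up set plus
  the chain's own stored samples; the center is updated at every iterate,
  stored or not. Whether the original tool's pool also contained
  non-stored iterates is not documented; keeping only stored points bounds
  memory and is flagged in provenance (`pool_policy`) so outputs remain
  comparable across implementations.

Chains are logical: each derives an independent RNG stream from
`SeedSequence(seed).spawn(chain)`, so a run is a pure function of its
configuration and the worker count only changes wall-clock time. The chain
loops execute in numba kernels that consume the random stream exactly like
the pure-Python reference iterate (`achr_step`); the two paths are pinned
to agree by a test.

Numerical guards: direction components below `dir_tol = 1e−9` are ignored
in the segment intersection; a segment shorter than 1e−12 triggers a
direction redraw (10 attempts, then the pool point farthest from the
center is taken deterministically; a pool offering no usable direction is
an error); an unbounded segment is capped at `1e6·(1+‖v‖)` and logged,
since a correctly specified flux polytope is bounded.

## Preprocessing

`remove_blocked_reactions` performs flux-variability analysis (two LPs per
reaction) and drops reactions whose minimum and maximum flux are both
within `flux_tol = 1e−9` of zero, then metabolites left with all-zero
rows. Comparisons use absolute tolerance — fluxes in these models are
O(1)–O(1000), and a relative criterion would spare near-zero ranges that
cannot matter. The operation is idempotent and does not change the
attainable range of surviving reactions (tested). All LPs go through
HiGHS, which is deterministic for a fixed problem; LP degeneracy
tie-breaking is therefore reproducible per solver version rather than
enforced across solvers.

## xy-deviation

Given r runs of sampler x at step count x1 and r runs of y at a much
larger x2, each run's fluxes are sorted per reaction and divided by
`ub_j − lb_j`; y's sorted chains are averaged element-wise into a mean
chain; and `D_j` pools all r·N absolute gaps between x's sorted chains and
the mean chain. The scalar xy-deviation averages `D_j` over reactions and
lives in [0, 1] (a percentage). Design points:

* The measure is asymmetric by construction (only y is averaged); a
  convenience `symmetric_deviation` (max of the two directions) is
  provided but is not part of the published measure.
* Mean absolute deviation is used rather than standard deviation — more
  robust to erroneous measurements and to non-normal distributions.
* Reactions with `ub = lb` are excluded from the average (their width
  normalisation is 0/0); blocked reactions are removed upstream so this
  is rare, and exclusions are recorded.
* Pooling all r·N terms per reaction is identical to averaging per run
  first when all runs share N; unequal N is an alignment error, not an
  interpolation problem to be papered over, because the measure is defined
  on aligned order statistics.
* Duplicated identical runs short-circuit the mean chain to the common
  sorted matrix, so self-deviation of copies is exactly 0 rather than a
  last-ulp residual.

## Convergence diagnostics

* **Geweke**: per reaction, `z = (mean_A − mean_B)/√(ŝ_A/N_A + ŝ_B/N_B)`
  with A the first 10% and B the last 50% of the chain and `ŝ` the
  spectral density at frequency zero. Approximately standard normal under
  stationarity.
* **Gelman–Rubin**: per-reaction PSRF `√(((N−1)/N·W + B/N)/W)` over ≥ 2
  chains without chain splitting, plus the Brooks–Gelman multivariate
  form `√((N−1)/N + (M+1)/M·λ₁)` where λ₁ is the largest generalised
  eigenvalue of the between/within covariance pair. Stoichiometric
  coupling makes flux covariances singular, so the within-covariance is
  ridge-regularised with `1e−10·I` before the eigenproblem. R < 1.2 is
  read as converged.
* **Heidelberger–Welch**: per reaction, the Cramér–von-Mises statistic of
  the Brownian-bridge-standardised cumulative sum, with the spectral
  variance estimated once from the second half of the full chain; tested
  on the full chain and after discarding the first 10%…50%, passing at
  the first stage below the α critical value (α = 0.05 default; critical
  values tabulated for 0.1/0.05/0.025/0.01).

Spectral densities at zero come from an AR(p) fit: autocovariances up to
`min(20, N/20)` lags, Yule–Walker coefficients per order, order chosen by
AIC, `s(0) = σ²ₚ/(1 − Σφ)²`. Zero-variance reactions yield z = 0 / R = 1 /
HW-fail with a degenerate flag instead of NaN. The three tests frequently
disagree (the multivariate PSRF in particular is easy to satisfy); they
are reported side by side and deliberately never aggregated into a single
verdict.

## Synthetic fixtures and oracles

The generator produces, deterministically per seed: hyper-rectangles
(closed-form uniform moments), the unit triangle encoded with a slack
reaction (known centroid (1/3, 1/3), covariance 1/18·I, area ½), simplexes
(Beta(1, d) marginals, corner-concentrated mass — the slowest-mixing
convex geometry available at a given dimension), anisotropic slabs
(graded widths 1…aspect), and random networks: sparse integer
stoichiometry (entries in ±{1, 2}, each metabolite touching ≥ 2
reactions) with bounds built asymmetrically around a planted nullspace
vector whose components are all bounded away from zero — so the fixture
is feasible, bounded, strictly interior at the planted point, never
FVA-blocked, and anisotropic (roughly half the reactions get loose
widths 5–20, half tight widths 0.2–1).

The rejection oracle draws exactly-uniform points by proposing in the
axis-aligned bounding box of the polytope in an orthonormal nullspace
frame (box found by two LPs per basis direction). Its acceptance rate
collapses with dimension, so it refuses > 4 effective dimensions or a
pilot acceptance below 1e−4; it exists purely as ground truth for the
chain samplers' moment and uniformity tests.

What the fixtures do not emulate: genome-scale dimension (hundreds of
nullspace dimensions), biomass/exchange structure, and the extreme bound
asymmetry of curated reconstructions. Passing tests therefore demonstrate
correctness of the algorithms and calibration of the measures at desk
scale, not convergence behaviour on real genome-scale models, where large
step counts remain advisable.

## Problem sizes used by the test suite

Feasibility is audited on 10⁴ samples per fixture and mode; uniformity on
10⁴ box samples (st = 100) against a Kolmogorov–Smirnov bound of 0.025
(≈ 3× the 95% band for 10⁴ i.i.d. points, slack for residual
autocorrelation); the deviation calibration on r = 4 × N = 1000 i.i.d.
uniform runs; and the step-count ordering between the gp and optgp
policies on the 10-reaction simplex network with N = 1000 and r = 4. The
simplex is used for that comparison because on faster-mixing 10-reaction
random networks both policies converge by st ≈ 50 and the ordering
disappears into the Monte-Carlo floor — an artefact of scaling the
experiment down, not a property of the samplers. The repeated-run
convergence check uses four optgp runs of 5,000 samples at st = 500 on
the m=5 × n=10 random network and the multivariate PSRF threshold 1.2.
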