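# Methods

## The sampling problem

A metabolic network with `m` metabolites and `n` reactions is summarised by
its stoichiometric matrix `S` (m × n). At steady state the flux vector `v`
satisfies `S v = 0`, and capacity constraints bound each flux,
`v_lb ≤ v ≤ v_ub`. Because `m < n` in realistic networks, the steady-state
set is a bounded convex polytope rather than a point, and its statistical
characterisation — marginal flux densities, means, variances — is obtained
by sampling. Two formulations are implemented:

* **Deterministic**: the steady state holds exactly and the target is the
  uniform distribution on the polytope. Samplers: HR, CHR, ACHR, OPTGP,
  CHRR.
* **Stochastic**: measurement noise and/or steady-state slack enter the
  model. The mirror-Metropolis sampler targets
  `p(u) ∝ exp(−½ (AGu − b)ᵀ Σ⁻¹ (AGu − b))` on the polytope (exact steady
  state, noisy measurements `A v = b + ε`); the Gibbs sampler targets the
  truncated multivariate normal posterior `TMVN(μ, C, v_lb, v_ub)` of the
  relaxed model `S v = β`, `β ~ N(0, Γ)` with a Gaussian flux prior.

All line samplers operate in null-space coordinates: with `G` an orthonormal
basis of `ker S` (rank decided by singular values above `tol·σ_max`,
`tol = 1e-12`), every steady-state flux is `v = G u` and the polytope becomes
the full-dimensional set `{u : A u ≤ b}` with `A = [G; −G]`,
`b = [v_ub; −v_lb]`. The anchor point is the Chebyshev center (largest
inscribed ball, one LP), which guarantees strict interiority for chord
computations; an arbitrary feasible point can sit on a face and stall
hit-and-run. Fixed fluxes (`v_lb = v_ub`) are kept as tight inequality
pairs; if they pin `u` completely the polytope is a point and construction
fails with an explicit error rather than producing a degenerate sampler.

## Model reduction

Flux variability analysis solves the 2n LPs `min/max v_j` subject to
`S v = 0` and the bounds (HiGHS via `scipy.optimize.linprog`, fixed reaction
order for reproducibility). Reduction replaces the bounds by the FVA
extremes and removes reactions with `max(|v_min|, |v_max|)` below
`null_threshold` (default `1e-9`; the threshold applies to the maximum
magnitude, not the interval width — both interpretations are defensible and
the choice is configurable). Metabolite rows left empty are dropped so the
null-space dimension of the reduced matrix is well defined. Reduction is
idempotent. Reversible reactions are never split; the polytope formulation
works with signed fluxes throughout.

## Samplers

**HR / CHR.** Directions uniform on the unit sphere (HR) or drawn from the
coordinate axes (CHR); the step is uniform on the exact feasible chord,
computed by a ratio test over all inequality rows with denominators below
`1e-12` treated as parallel. Chords narrower than `1e-14` trigger a
direction redraw, with a warning after 100 consecutive failures.

**ACHR.** Sphere directions during warm-up (`M_warm ≥ d` is enforced);
afterwards the direction is the normalised difference between a uniformly
chosen earlier iterate (index drawn on `{0, …, a}` inclusive) and the
artificial center — the running mean of all iterates, initialised at the
start point and updated by `c ← (a c + u_a)/(a + 1)`. The adaptation makes
the chain non-Markovian: distributional convergence is not guaranteed, which
is the scientific reason CHRR exists.

**OPTGP.** Warm-up points are the 2n FVA optima projected into u-space and
pulled `1e-6` of the way toward the Chebyshev center (the optima lie on the
boundary, which a chord sampler cannot start from). Several short
ACHR-style chains share one artificial center and history; every k-th state
is emitted. "Parallel" is a statistical contract, not a concurrency one —
chains advance round-robin on interleaved draws from one seeded generator,
which keeps runs bit-for-bit reproducible.

**CHRR.** The maximum-volume inscribed ellipsoid (MVE) `{c + B y : |y| ≤ 1}`
of the polytope is computed and the affine map `u = B y + c` turns it into
the unit ball; CHR runs in the rounded space and kept states are mapped
back. The MVE is found by maximising `log det B` over symmetric `B` subject
to the support constraints `a_iᵀc + |B a_i| ≤ b_i` (SLSQP started from the
Chebyshev ball, `ftol = 1e-10`); axis-aligned boxes short-circuit to the
analytic solution (semi-axes = half side lengths), and the SLSQP path is
validated against rotated-box instances whose MVE is known analytically.
The mixing time of hit-and-run scales with the squared sandwiching ratio
R_s/R_b (circumscribed over inscribed ball radius), which the rounding
collapses to O(1); the package reports an estimate of the ratio from the MVE
semi-axes (`sqrt(Σ s_i²) / min s_i`, exact for boxes).

**Sampling protocol.** Thinning counts underlying iterations (every k-th
iterate is kept), warm-up iterates are never emitted, and every emitted flux
vector must satisfy the bounds within `ε = 1e-6` and `‖S v‖_∞ ≤ ε`;
violations are clipped and counted, and more than 0.1 % of entries violating
aborts the run. The genome-scale defaults mirrored by `ExperimentConfig`
are M = 20,000 samples, thinning 1000 and M_warm = 20,000; tests and the
acceptance evaluation use smaller chains (M between 600 and 20,000,
thinning 1–10) on low-dimensional synthetic polytopes, which the package
treats as its standard desk-scale study conditions.

**Mirror-Metropolis.** Gaussian random-walk proposals
`u₀ ~ N(u, diag(ω²))`; a proposal outside the polytope is reflected across
each violated hyperplane in index order, re-checking after every reflection,
up to 10⁴ reflections (then the proposal is rejected with a warning; more
than 1 % capped proposals aborts with advice to shrink the jump lengths —
oversized jumps are the known failure mode of this sampler). Reflections
are isometries, so the mirrored proposal is treated as symmetric in the
Metropolis ratio. This is exact when the reflecting faces are aligned with
the proposal axes (an axis-aligned box folds each coordinate independently
and the folded kernel is symmetric); when faces are oblique to an
anisotropic diagonal proposal the folded kernel is only approximately
symmetric and a small stationary-law bias can remain — a property of the
mirror construction itself, detectable as depressed KS p-values against
hit-and-run on rotated anisotropic boxes. The uniform-limit agreement check
therefore uses an axis-aligned box. Default jump lengths are half the per-coordinate chord
span through the anchor (the customary `0.5 (v_ub − v_lb)` rule mapped to
u-space); a 0.01 multiplier variant is available through
`default_jump_lengths`. With no measurements the acceptance ratio is 1 and
the target degenerates to the uniform law, which is the basis of the
HR-agreement check.

**TMVN posterior and Gibbs.** The posterior follows standard Gaussian
conjugacy:

    C  = (diag(prior_var)⁻¹ + Sᵀ Γ⁻¹ S + Aᵀ Σ⁻¹ A)⁻¹
    μ  = C (diag(prior_var)⁻¹ m₀ + Aᵀ Σ⁻¹ b)

with prior mean `m₀` the closest point to zero inside the bounds and prior
variances `(min(0.5 (v_ub − v_lb), cap))²`, cap 1000 by default (500/100
variants exist because overly wide priors make `C` numerically indefinite on
some models — the Cholesky factor is computed with escalating jitter and a
persistent failure raises with that advice). Defaults: steady-state slack
`γ_i = 1e-4`. The Gibbs sampler whitens `v = μ + L w` (`C = L Lᵀ`) and
cyclically redraws each `w_j` from its 1-D truncated standard-normal
conditional, whose interval comes from intersecting the box constraints
`v_lb ≤ μ + L w ≤ v_ub` at fixed `w_{−j}`. Truncated draws use the inverse
CDF, switching to scipy's tail-robust sampler beyond 6 SD. The chain starts
at the posterior mode projected into the box and uses no warm-up.
Numerically empty conditionals keep the current value; more than 1 % of them
aborts. The whole construction is validated against an exact
accept/reject oracle (dimension ≤ 4).

## Convergence diagnostics

Applied per reaction; a chain "fails" a test at the conventional threshold.

* **Raftery–Lewis** (fails at dependence factor I > 5): the chain is
  dichotomised at its empirical q-quantile; the thinning step k is the
  smallest at which a first-order Markov model is preferred over a
  second-order one by a BIC comparison (G² − 2 ln n); the 2×2 transition
  rates (α, β) then give the burn-in `M_warm_est` (time to within
  ε = 0.001 of stationarity) and run length `N_max` from the standard
  two-state spectral formulas, and
  `N_min = ⌈Φ⁻¹((s+1)/2)² q(1−q)/r²⌉` (3746 at the default
  q = 0.025, r = 0.005, s = 0.95). `I = (M_warm_est + N_max)/N_min`.
* **Geweke** (fails at |Z| > 1.28): Z-score of the first 10 % against the
  last 50 %, with segment-mean variances from the spectral density at
  frequency zero estimated by an AIC-selected autoregressive fit. A plain
  variance/n estimate over-rejects on autocorrelated chains, which is why
  the AR route is used. On an iid chain the nominal failure rate is
  P(|Z| > 1.28) ≈ 20 %, and the calibration suite checks exactly that.
* **IPSRF** (fails outside (0.9, 1.1)): first and last thirds act as two
  parallel chains; the statistic is the width of the pooled central 80 %
  interval over the mean within-segment width. The interval probability is
  configurable since toolbox defaults vary.
* **Hellinger distance** (fails at HD > 0.1): Gaussian-kernel KDEs
  (Silverman bandwidth) of the first and last thirds,
  `HD = √(½ ∫ (√p₁ − √p₃)² dv)` by adaptive quadrature (tolerance 1e-8) on
  the union support ± 3 bandwidths, clipped to [0, 1]; a zero-variance
  segment counts as a point mass and returns 1 with a warning.

Per-test flag sets are reported, not only counts, because different
diagnostics do not generally reject the same reactions.

## Comparison statistics

Per-reaction means and SDs use the 1/(M−1) variance denominator. The
Pearson correlation across reactions is computed after removing reactions
whose mean difference (or SD difference) deviates from the across-reaction
mean difference by more than 2 SD; centering matters, since a systematic
offset such as prior-induced shrinkage would otherwise flag every reaction.
KL divergence `KLD(p₂|p₁) = ∫ ln(p₁/p₂) p₁` is evaluated between Silverman
KDEs on the reference-sample range ± 3 bandwidths (trapezoid on a 2048-point
grid; `p₂` floored at 1e-12 of its maximum), and classified good
(< 0.05), medium (0.05–0.5) or poor (> 0.5). Autocorrelation uses the
1/(M−k) numerator, 1/M denominator convention;
`ESS = M/(1 + 2 Σ ρ_k)` truncates the sum at the first non-positive lag and
is clipped to (0, M]. Efficiency is `E = ESS/runtime` per reaction, with the
time-to-100-independent-samples summary `100 · runtime / mean(ESS)`;
runtimes are wall-clock around the sampling call only.

## Synthetic data: what it does and does not emulate

The generators provide every input class with analytic ground truth: the
two-flux toy network (`S = [1, −1]`, feasible set the segment v1 = v2);
random sparse integer stoichiometries (entries in {−2, −1, 1, 2}) made
feasible by construction around a null-space certificate `v*`; box and
simplex polytopes with exact uniform moments (boxes with side ratios up to
1e5 emulate the anisotropy of genome-scale polytopes); stationary AR(1)
chains for diagnostic calibration; and exact rejection-sampled TMVN draws as
a Gibbs oracle. Ground truth is attached to the generated object so tests
compare against stored analytic values rather than re-derivations.

What passing on these inputs does **not** show: behaviour at genome-scale
dimension (hundreds to thousands of free directions), LP degeneracy of real
reconstructions, sparsity-driven runtime effects, or the wall-clock
rankings reported for specific hardware. The efficiency *metric* is
implemented and tested; printed minutes are not a reproducible quantity.

## Numerical choices and edge cases

* LP feasibility tolerance 1e-9 (HiGHS primal tolerance floor 1e-10);
  FVA optima clipped back into the box before use.
* Hellinger estimation against an *analytic bounded* density (the rounding
  study) uses a 50-bin histogram on the known support instead of a KDE:
  Gaussian-kernel boundary bias alone contributes HD ≈ 0.13 at M = 20,000
  for a perfect uniform sample, which would swamp the sampler signal.
* Seeds: every sampler and generator takes an integer seed and is
  bit-for-bit reproducible; derived seeds in the evaluation scripts come
  from `numpy.random.SeedSequence.spawn`.
* KDE floors (1e-300 inside square roots, 1e-12·max for KLD denominators)
  keep logs and roots finite without visibly biasing the statistics.
* Degenerate inputs fail loudly: empty models after reduction, point
  polytopes, constant chains, zero-variance segments, empty test
  selections, unbounded MVE problems.

## Known limitations

* The MVE solver is a dense SLSQP program; it is appropriate for the
  desk-scale polytopes this package targets (tens of dimensions), not for
  thousands of inequality rows.
* Gibbs conditional intervals are computed with a per-coordinate Python
  loop; genome-scale sweeps would want a compiled kernel.
* Multi-chain (Gelman–Rubin) diagnostics are out of scope; all diagnostics
  here are single-chain.
* Hamiltonian Monte Carlo for the TMVN posterior is deliberately not
  included.
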