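# Methods

## Identification and estimands

For a sharp RD design with threshold `c`, treated side above, the package
estimates the conditional outcome means `mu1(x) = E[Y(1)|X=x]` (treated) and
`mu0(x) = E[Y(0)|X=x]` (control) from data on either side of the cutoff.
The estimands are the local average treatment effect `pi(c) = mu1(c) -
mu0(c)`, the treatment-effect derivative `pi'(c) = mu1'(c) - mu0'(c)`, and
the welfare-maximizing threshold

    c* = argmax_{t in [c-h, c+h]}  ∫_t^{c+h} pi(x) p(x) dx.

Interpreting the welfare argmax as the policy-relevant optimum requires
*policy invariance*: the effect conditional on the running variable must not
itself depend on where the threshold sits.  Under that assumption the
marginal threshold treatment effect (how the LATE changes as the cutoff
moves) equals the TED, and `estimate_mtte` returns the TED flagged
accordingly.  The extrapolation is trusted only within the bandwidth — the
solvers never search outside `[c-h, c+h]`, and effect curves warn (but do
not fail) when evaluated beyond it, since welfare accounting legitimately
integrates tail bins whose effect contribution the user accepts as
extrapolated.

For fuzzy designs, all quantities are per-complier: the LATE is the ratio of
the outcome discontinuity to the compliance discontinuity, the TED follows
the quotient rule `(mu1'-mu0')/p_f - p_f' * pi_f / p_f`, and the welfare
integrand is weighted by the estimated complier share `f1(x) - f0(x)`.

## Estimators

**Local linear (default).**  Rectangular kernel, so each side is an OLS fit
of `y` on `(x - c)` over `[c-h, c)` / `[c, c+h]` (the cutoff itself belongs
to the treated side).  Coefficient covariance is classical homoskedastic by
default, HC1 on request.  The extrapolated curve is affine with
delta-method pointwise SEs; the two sides are fitted on disjoint samples
and treated as independent.  For fuzzy ratios the numerator (outcome) and
denominator (treatment-probability) fits share rows, but their
cross-covariance is ignored in the delta-method SEs — a simplification
cross-checked in practice by the bootstrap, which resamples the whole
pipeline.

**Bandwidth.**  The Imbens–Kalyanaraman plug-in rule, uniform-kernel
constant `C_K = 5.40`, with the standard pilot constants (1.84, 3.56), the
regularization terms `2160 sigma^2 / (N2 h2^4)`, and a global-cubic third
derivative.  When the estimated third derivative is ~0 the second-stage
window would diverge; it is clipped to the observed side range.  The guard
refuses to select a bandwidth with fewer than 20 observations per side.

**Gaussian process.**  Zero-mean GP per side with squared-exponential
kernel (a Laplacian "double-exponential" kernel is available), exact
conditioning through a Cholesky factorization with a jitter ladder
(0 → 1e-6).  Reported variances are *predictive* (latent plus observation
noise), so they are bounded by `signal_var + noise_var` and revert to that
bound far from data.  Two hyperparameter rules:

* `"default"`: length scale `8h`, signal variance `1000 × var(y)`, noise
  variance `var(y)` (windowed).  These deliberately sit in the
  long-length-scale / high-signal-variance regime: threshold optimization
  evaluates the posterior mean up to a bandwidth beyond the side's data,
  and a short length scale would revert the extrapolation to the prior
  mean instead of continuing the local trend.  On locally linear data this
  default lands on the same threshold as the local-linear estimator (the
  test suite checks agreement within 0.1 x-units).
* `"cv"`: 5-fold cross-validation minimizing held-out negative log
  predictive density over a 7×7×5 log-spaced grid centered on data-scale
  heuristics (output variance, window/5, 10% output variance).  Folds come
  from a seeded permutation and ties break by grid order, so the selection
  is fully deterministic.

Sides share the kernel family but not hyperparameter values; passing the
same explicit `GPHyperparams` to both sides recovers the shared-covariance
variant.

## Welfare, solvers, and numerical choices

The density `p(x)` is a histogram with default bin width 0.40 x-units,
half-open bins, last bin closed.  Welfare is a Riemann sum: each bin
contributes the effect at the midpoint of its overlap with the integration
range, weighted by the overlapping mass share — exact for affine curves
against a piecewise-constant density (the tests verify agreement with
adaptive quadrature to 1e-9).

The numeric solver scans a 2001-point grid for sign changes of
`pi(x) - z`, refines each bracket by Brent's method to `1e-8 · h`, adds
both window endpoints, and returns the welfare argmax — robust to the
multiple roots a GP curve can have, and equal to the closed form
`c - ((alpha1 - z) - alpha0)/(beta1 - beta0)` for local-linear curves.
When the slopes are equal the root is undefined (the "flat TED" case) and
the welfare-preferred boundary is returned with an `undefined-root` flag.

The conservative threshold solves `pi(x) = Z_alpha · se(x)` by bracketed
root finding on the segment between `c*` and `c` only: elsewhere the
equation can have spurious roots that do not correspond to the furthest
risk-safe move.  If the effect at the current cutoff is not significantly
positive at level alpha, the threshold "cannot move" and `c` is returned
flagged; if the lower bound is positive on the whole segment the full move
to `c*` is safe.

The budget constraint counts treated subjects (`N · mass(x ≥ t) ≤ B`; a
spend-based variant `N · z · mass ≤ B` sits behind a flag).  Because
partial-bin overlap makes the mass function continuous and monotone, the
binding threshold is found by root finding on the load; if the effect turns
negative above the binding point the solver falls back to a grid argmax
over the feasible set.

Gains accounting for a move from `c` to `c*` renormalizes bin masses over
`[c*, c]`, so `gain_pp` reads as outcome units per newly treated unit.
When the outcome is declared a percentage of the running variable
(`outcome_is_pct_of_x`, the tipping-study convention), the per-unit
monetary gain is `Σ (pi/100) · x · p(x)` and the total scales by the
observed count of affected units.

The treated-below convention is handled by mirroring `(x, c) → (-x, -c)`
at the pipeline level and negating returned thresholds, so every solver is
written once, for the treated-above case with a desired positive effect.

## Synthetic data

The generators draw the running variable from a uniform, triangular
(peaked at the cutoff), or piecewise-constant density; outcomes follow
per-side lines in `(x - c)` with i.i.d. Gaussian noise — exactly the
setting where the local-linear estimator is correctly specified.  Fuzzy
mode draws treatment as Bernoulli from per-side linear compliance
probabilities (validated to stay in [0, 1]) and assigns the outcome by
realized treatment, so there are no defiers by construction.  Three presets
span the scenario taxonomy (all with `c = 10`, support `[5, 15]`, LATE
+2): `canonical` (TED +1, root at 8), `flat_ted` (TED 0, boundary
optimum), `adversarial` (TED −0.5, root on the treated side).  Generation
is bit-reproducible from a single named seed.

What the simulations do *not* emulate: curvature in the conditional means
(so passing tests certify solver and inference correctness under correct
specification, not robustness to misspecified extrapolation), heavy-tailed
or heteroskedastic noise, discrete running variables, and manipulation
(bunching) at the cutoff.  On real data those remain the analyst's
diagnostics to run.

## Inference

Bootstrap resamples observations with replacement (pooled across sides by
default; stratified-by-side available) and re-runs the *entire* estimator
per resample, including any bandwidth or hyperparameter selection inside
it.  Datasets above 100,000 rows automatically switch to subsampled
resamples of 10,000.  Resamples where estimation fails (e.g. no interior
root) are dropped and counted; more than 50% failures aborts with a
breakdown.  Default 100 repetitions.  Monte Carlo checks in the test suite:
the bootstrap SE of a sample mean matches `s/√n` within 10% at 2000 reps,
and the normal interval `c* ± 1.96·se` covers the true root at 95% ± 4 pp
over 200 canonical replications.

## Problem sizes and defaults

The simulation-based checks use the canonical study conditions n = 500,
sigma = 1 (200 replications with 100 bootstrap repetitions each), n =
20,000 for binomial-precision fuzzy checks, and n = 1,000 at sigma = 0.5
for GP/LLR agreement — sizes at which each check's Monte Carlo error is
comfortably below its assertion tolerance.  Key defaults: bin width 0.40,
jump floor 0.05 for fuzzy denominators (fail loudly rather than divide by
near-zero), alpha 0.05, bootstrap reps 100, grid 2001 points, bisection
tolerance `1e-8 · h`.

## Known limitations

* Extrapolation is linear (LLR) or prior-driven (GP); neither is validated
  away from `[c-h, c+h]`, and the package deliberately refuses to optimize
  outside it.
* Fuzzy delta-method SEs ignore the outcome/treatment fit covariance;
  prefer bootstrap SEs for fuzzy quantities.
* GP estimation is exact (O(n³)); for very large sides, subsample or use
  the local-linear estimator.
* No covariates beyond the running variable, no clustered SEs, no
  local-polynomial orders above 1.
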