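# Methods

## Models and error structures

All computations concern four Michaelis–Menten-type mean rate functions of a
substrate concentration x_S ∈ [0, 30] and an inhibitor concentration
x_I ∈ [0, 60] (concentration units as in the reference assay): the
two-parameter Michaelis–Menten model, the three-parameter competitive and
non-competitive inhibition models, and the four-parameter encompassing model
whose mixing parameter λ ∈ [0, 1] interpolates between them (λ = 1
competitive, λ = 0 non-competitive).  Parameters θ_V (maximum velocity),
θ_M (Michaelis constant) and θ_K (inhibition constant) are strictly
positive.

Two statistical models are supported for an observation y at x:

* standard scale: y = η(θ, x) + ε, ε ~ N(0, σ²) — the conventional additive
  assumption, under which simulated rates can be negative;
* log scale: ln y = ln η(θ, x) + e, e ~ N(0, σ²) — multiplicative
  log-normal error, under which rates are positive by construction.

The log response needs η > 0 and hence x_S > 0.  Data sets containing zero
substrate concentrations or zero rates are made log-compatible by replacing
those zeros with a small floor, ε = 0.02 by default.  This replacement is a
deliberate, documented distortion: the ε-wells carry a response pinned at
the floor while the model predicts η(ε) ≠ ε, which biases fits slightly and
is why the estimator-property tests use an all-positive variant of the plate
layout.

Gradients of both responses with respect to the parameters are analytic
(the log-scale gradient is the rate-scale gradient divided by the rate) and
are validated against central finite differences.

## Nominal values

Locally optimal design criteria need nominal parameter values.  The package
ships the least-squares estimates (with standard errors and residual SDs)
from a prior dextromethorphan–sertraline assay of N = 120 observations,
fitted per model on both scales (`enzdesign.nominals`).  Every report writes
a provenance line stating that these built-in nominals were used.  Users can
substitute their own estimates anywhere a θ is accepted.

## Estimation

`fit_model` minimises the residual sum of squares on the analysis scale with
scipy's trust-region-reflective least squares, box constraints (parameters
≥ 0, λ ∈ [0, 1]) and five jittered multistarts (log-normal jitter, SD 0.3 on
the log of the start).  Standard errors come from the linearisation
covariance σ̂²(FᵀF)⁻¹ with σ̂² = SSE/(N − m).  A singular information matrix
at the optimum (e.g. an inhibition model fitted to data with no inhibitor
variation) raises an identifiability error; classification work that only
needs the minimised SSE can disable that check.  A λ estimate at 0 or 1 is
flagged as a boundary solution whose standard error is unreliable.  The
three residual summaries report (SSE, MSE) on the standard scale, on the log
scale, and for the back-transformed fit exp(ln ŷ) against the raw rates.

## D- and Ds-optimal design

An approximate design ξ is a probability measure on the design region; its
per-observation Fisher information is M(ξ, θ) = Σ ωᵢ f(xᵢ)f(xᵢ)ᵀ with f the
response gradient on the chosen scale.  D-optimality maximises det M;
Ds-optimality maximises det M / det M₂₂ where M₂₂ is the block of the
nuisance parameters (here the subset of interest is usually {λ}, s = 1).

The optimiser works in three stages:

1. **Grid phase.**  A multiplicative (Titterington-type) weight update
   ωᵢ ← ωᵢ ψ(xᵢ)/bound on a finite candidate grid, where ψ is the
   D- or Ds-sensitivity function and the bound is m or s; the design-average
   of ψ equals the bound, so the update preserves total mass.  Candidates
   whose weight decays below 1e-10 are dropped along the way.  Grids:
   log scale {0.02, 1, …, 30} × {0, 1, …, 60} (31 × 61 points; the substrate
   floor is the zero-replacement ε); standard scale step 0.1 in both
   coordinates.  x_S = 0 contributes a zero gradient row and is excluded.
2. **Merge.**  Support points within five grid steps are merged into
   weighted centroids and weights below 1e-4 pruned — deliberately
   aggressive, because stage 3 restores anything dropped in error.
3. **Continuous refinement + certificate.**  Support coordinates and weights
   are jointly optimised by SLSQP with analytic gradients
   (∂ log det M/∂ωᵢ = ψ(xᵢ); ∂ log det M/∂xᵢ = 2ωᵢ fᵀM⁻¹ ∂f/∂x, with ∂f/∂x
   by central differences on the analytic f), then the equivalence theorem
   is checked on the full grid: max ψ ≤ bound·(1 + 1e-4).  If the check
   fails, the violating grid point is added with weight 1e-3 and refinement
   repeats (at most 12 rounds, else a convergence error reporting the gap).

Efficiencies are (det M(ξ)/det M(ξ*))^{1/m} for D and the analogous ratio to
the power 1/s for Ds; a design whose information (or subset information) is
singular under the reference model has efficiency 0 and is reported as
singular.  Because the criterion surface is extremely flat near the
standard-scale optima, support coordinates are only weakly determined: a
design whose interior points differ by ~0.1 from the optimum can be
99.995 % efficient.  The package reports the certified optimum; efficiency,
not coordinate agreement, is the meaningful comparison.

Exact designs are obtained by largest-remainder apportionment of N·ωᵢ
(remainder ties broken toward the larger weight, then lexicographically);
each count differs from N·ωᵢ by less than one and zero-count points are
dropped.

## T-, compound-T- and δ-optimal discrimination

T-optimality fixes one model as true at its nominals and maximises the
rival's lack of fit Δ(ξ) = inf_{θ₁} Σ ωᵢ (η₀(xᵢ) − η₁(θ₁, xᵢ))² over
designs.  The inner infimum is a box-constrained least-squares problem
(rival parameters in [1e-6, 1e4], λ in [0, 1] where applicable) solved with
multistart (nominal start plus log-uniform draws over [0.1, 100]; ten starts
for stand-alone evaluations, warm starts inside iterations).  The outer
maximisation runs a Fedorov–Wynn phase (move mass 1/(k+1) to the grid point
with the largest squared separation, prune weights < 1e-5; 300 iterations by
default) followed by a polish loop — merge support, re-optimise the weights
by SLSQP with the envelope gradient ∂Δ/∂ωᵢ = rᵢ(θ̂₁)², on the standard scale
also polish the support coordinates continuously — and the T-equivalence
certificate max_x (η₀ − η₁(θ̂₁))² ≤ Δ·(1 + 1e-4); violating points are added
and the loop repeats.  The fixed 5000-iteration Fedorov–Wynn schedule is not
used because the polish loop reaches the same certified designs orders of
magnitude faster; the certificate, not an iteration count, is the stopping
criterion.  A rival family able to interpolate the true model (e.g. rival =
true) raises a degeneracy error.

Compound-T maximises (1 − ν) ln Δ₀ + ν ln Δ₁ with the composite sensitivity
(1 − ν)ψ₀/Δ₀ + νψ₁/Δ₁ (bounded by 1 at the optimum); ν = 0 and ν = 1 return
the pure T-optima, which are always computed first as normalisers.

A cautionary note on cross T-efficiencies Δ(ξ)/Δ(ξ*): the inner problem is
multimodal, and for corner designs with a very low-weight support point the
global rival fit can almost interpolate the heavy points, leaving Δ an order
of magnitude below what a local inner solution suggests (the log-scale
T-optimum under the non-competitive truth, with corner weight 0.0095, is the
extreme case: its efficiency under the reverse criterion is ≈ 13 %, while a
shallower inner minimum would suggest ≈ 75 %).  This package always reports
the efficiency at the certified global inner minimum; published efficiency
tables computed with less exhaustive inner searches can differ by several
points, and by much more in the interpolation-prone cases.

δ-optimality is symmetric: both models are linearised at nominal centers
θ̃_u, giving offsets a_u = η_u(θ̃_u) − F_u θ̃_u, and
δ²(D) = min ‖(a₀ − a₁) − [−F₀, F₁]θ‖² over θ in the flexible nominal boxes
θ̂ ± r·SE — clipped at zero (alternative *a*) or clipped with the cut mass
shifted to the upper bound (alternative *b*).  The quadratic is solved with
bounded-variable least squares (`scipy.optimize.lsq_linear(method="bvls")`);
degenerate boxes (r = 0) reduce to the fixed-nominal distance and are
evaluated directly.  Replicated design points enter through √(count) row
weights, so the cost of one evaluation scales with the number of distinct
points.  δ-optimal exact N-run designs use a KL-exchange heuristic: start
from a uniform random N-sample of the grid (seed required; runs are
deterministic given the seed), then apply best single-run exchanges (remove
one replicate of a support point, add one run at any grid candidate) until
no exchange improves δ.  The full grid is the candidate set at desk scale;
for the large-N (N = 60) power study the tests use a 7 × 7 candidate lattice
to keep exchange sweeps proportionate, a package choice recorded here.

## Monte-Carlo discrimination power

For a named set of exact designs, `hit_rate_study` simulates B datasets from
each of the two rival models in turn (log scale: y = η·exp(e); standard:
y = η + e), fits both models to every dataset and classifies it to the
smaller residual sum of squares on the analysis scale — the likelihood-ratio
rule for equal-variance Gaussian errors and equal parameter counts, a choice
made here because both rivals have three parameters.  Numerical SSE ties
(relative difference < 1e-9, as when the models coincide on the design) are
broken uniformly at random.  Classification fits start at each model's
nominal values with 5 % log-normal jitter plus two random restarts; this
pragmatic warm start reflects that an analyst would fit from published
estimates.  Each (design, truth) cell draws from its own
`SeedSequence(master, spawn_key=(design, truth))` stream, so any cell is
independently reproducible and adding designs does not shift other cells'
results.

Default study conditions mirror the reference experiment: σ = 0.5128 (the
encompassing log-case residual SD) with B = 100 per truth for the small
designs N = 6…9, and 4σ with the N = 60 designs for the large-scale
comparison.  The package tests run the large-scale comparison at B = 150 and
the noise-monotonicity check at B = 200 per cell — sizes chosen so the whole
suite stays a desk-scale computation — and assert ordering up to a
2-point Monte-Carlo margin.

## Synthetic plate generator

The estimation pipeline was developed against a laboratory assay that is not
deposited; `enzdesign.synthetic` emulates its layout: 15 substrate levels
{0, 0.5, 1, 1.5, 2, 3, 4, 5, 7, 9, 12, 15, 20, 25, 30} crossed with 8
inhibitor levels {0, 2, 5, 10, 20, 30, 45, 60}, N = 120 single observations.
The published description fixes only the ranges, the counts, the inclusion
of zeros and the dense-low/sparse-high substrate spacing; the exact levels
above are a single package-level choice satisfying those constraints, kept
in module constants for overriding.  The generator reproduces the layout and
error structures of such a plate but not its real-world features — no
row/column plate effects, no heteroscedasticity beyond the error model, no
outliers — so passing tests demonstrate correctness of the methods under the
stated error models, not robustness to violations of them.

## Numerical choices and degenerate inputs

* Weights are treated as a design if they sum to 1 within 1e-9; rounding
  uses exact integer totals.
* Design supports are sorted lexicographically by (x_S, x_I) (keys rounded
  at 1e-9) so equal-criterion designs have a canonical form.
* Singularity thresholds: information matrices are declared singular below
  a 1e-12 relative smallest singular value (fits) or a non-positive
  determinant (designs).
* IC50 of the encompassing model is defined as the inhibitor concentration
  halving the expected rate at x_S = θ_M and located by Brent root finding
  (tolerance 1e-10) on the rate ratio; this reproduces the closed-form
  limits 2θ_K (λ = 1) and θ_K (λ = 0).  The Hill coefficient is fixed at
  one throughout the percent-inhibition arithmetic.
* All randomised procedures take explicit seeds; hypothesis-based property
  tests run derandomised.

## Limitations

* All optimal designs are locally optimal at the supplied nominals; no
  Bayesian or minimax robustification is provided.
* The δ-criterion implements nominal-box alternatives *a* and *b* only.
* Second-order (curvature-aware) design criteria are out of scope; the
  log-scale models behave near-linearly over wide parameter ranges, which
  is precisely why their optimal designs are corner designs.
* Hit-rate studies cover the competitive/non-competitive pair; other rival
  pairs would need equal parameter counts for the SSE rule to remain the
  likelihood-ratio rule.
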