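# enzdesign

Optimal experimental design for enzyme-inhibition kinetics under two rival
error structures: additive normal noise on the reaction rate and
multiplicative log-normal noise (equivalently, additive normal noise on the
log rate).  The package is aimed at statisticians and assay scientists who
plan substrate--inhibitor titration experiments and need to know where to put
their runs, both for precise parameter estimation and for deciding *which*
inhibition mechanism is at work.

## Models

Reaction velocity is described by Michaelis--Menten-type mean functions of
the substrate concentration x_S and inhibitor concentration x_I:

| model            | η(θ, x) |
|------------------|---------|
| Michaelis–Menten | θ_V x_S / (θ_M + x_S) |
| competitive      | θ_V x_S / (θ_M (1 + x_I/θ_K) + x_S) |
| non-competitive  | θ_V x_S / ((θ_M + x_S)(1 + x_I/θ_K)) |
| encompassing     | θ_V x_S / (θ_M (1 + x_I/θ_K) + x_S (1 + (1−λ) x_I/θ_K)) |

The four-parameter encompassing model nests the competitive (λ = 1) and
non-competitive (λ = 0) mechanisms.  The *standard* statistical model is
y = η + ε with ε ~ N(0, σ²); the *log* model is ln y = ln η + ln ε with
ln ε ~ N(0, σ²), which keeps simulated rates positive — the physical
requirement that motivates it.

On top of the mean models the package implements:

* **Estimation** — box-constrained nonlinear least squares on either scale,
  zero-well replacement (ε = 0.02 floor), linearization standard errors and
  the three residual summaries (standard, log, back-transformed).
* **D/Ds-optimal designs** — Fisher information M(ξ,θ) = Σ ωᵢ f(xᵢ)f(xᵢ)ᵀ,
  maximising det M (D) or det M / det M₂₂ (Ds, subset of interest such as λ),
  by a multiplicative weight algorithm on a candidate grid followed by
  continuous refinement, certified by the equivalence theorem
  (max_x f(x)ᵀM⁻¹f(x) = m at the optimum).
* **Discriminating designs** — T-optimality (maximise the rival model's
  lack-of-fit sum of squares Δ(ξ) = inf_θ₁ Σ ωᵢ (η₀ − η₁(θ₁))², via
  Fedorov–Wynn), compound-T designs maximising
  (1−ν) ln Δ₀ + ν ln Δ₁, and the symmetric δ-criterion (minimal distance
  between linearised expectation surfaces over flexible nominal boxes
  θ̂ ± r·SE, solved with bounded-variable least squares and a KL-exchange
  over exact N-run designs).
* **Discrimination power** — seeded Monte-Carlo hit-rate studies: simulate
  data from each rival model at an exact design, classify by the
  better-fitting model, report average correct-classification rates.
* **Synthetic data** — a 15 × 8 titration-plate generator (N = 120,
  substrate dense at the low end, both variables including 0) standing in
  for the non-public dextromethorphan–sertraline assay whose published
  nominal estimates (`enzdesign.nominals`) drive all design computations.

## Worked example

```python
import numpy as np
from enzdesign.designs import GridSpec, optimize_d, equivalence_check
from enzdesign.nominals import nominal

theta = np.append(nominal("competitive", "log").theta, 1.0)  # lam = 1
grid = GridSpec.log_case()                                   # 31 x 61 grid
design = optimize_d(grid, "encompassing", theta, scale="log")
print(design.as_dataframe().round(4))
print(equivalence_check(design, grid, "encompassing", theta, "log"))
```

prints

```
     x_S   x_I  weight
0   0.02   0.0    0.25
1   0.02  60.0    0.25
2  30.00   0.0    0.25
3  30.00  60.0    0.25
{'bound': 4.0, 'max_grid': 4.000000..., 'max_support': 4.000000...,
 'worst_point': array([0.02, 0.]), 'gap': 5.0e-09, 'ok': True}
```

Under the log error structure the D-optimal design puts a quarter of the
runs on each *corner* of the concentration region — the most extreme
substrate/inhibitor pairs — and the sensitivity function touching its bound
m = 4 exactly on those corners certifies global optimality.  Under additive
errors (`GridSpec.standard_case()`, `scale="standard"`) the same computation
spreads the support into the interior, e.g. support points near
(3.39, 0) and (7.89, 7.23): the choice of error structure decisively changes
where the experiment should be run.

The scripts in `examples/` walk through each capability: fitting synthetic
plates, estimation designs and efficiencies, discriminating designs, δ
designs, hit-rate simulations and the IC50 / percent-inhibition scheme.

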