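"""delta-optimal exact designs with flexible nominal boxes.

Builds the symmetric linearised-distance criterion between the log
competitive and non-competitive models with nominal boxes
(estimate +/- r * SE, clipped at zero), finds delta-optimal 6-run designs by
KL-exchange for two box sizes, and shows the monotone effect of the tuning
multiplier r.
"""

from enzdesign.designs import ExactDesign, GridSpec
from enzdesign.discrimination import DeltaSpec, delta_optimal, delta_value, nominal_box
from enzdesign.nominals import NOMINAL


def spec(r, alternative="a"):
    boxes = tuple(
        nominal_box(NOMINAL[(m, "log")].theta, NOMINAL[(m, "log")].se, r, alternative)
        for m in ("competitive", "noncompetitive")
    )
    return DeltaSpec(models=("competitive", "noncompetitive"), boxes=boxes,
                     scale="log", r=r, alternative=alternative)


grid = GridSpec.log_case()
for r in (1.0, 4.0):
    design = delta_optimal(6, grid, spec(r), seed=1)
    print(f"\ndelta-optimal design, N = 6, r = {r:g}:")
    print(design.as_dataframe().to_string(index=False))
    print(f"delta = {delta_value(design, spec(r)):.4f}")

fixed = ExactDesign([[0.02, 0.0], [30.0, 0.0], [0.02, 60.0], [30.0, 60.0]],
                    [2, 1, 1, 2])
print("\ndelta of a fixed corner design as the boxes grow:")
for r in (0, 1, 2, 3, 4, 5):
    print(f"  r = {r}: delta = {delta_value(fixed, spec(r)):.4f}")

print("\nLarger boxes let the two linearised surfaces approach each other, "
      "so delta shrinks monotonically in r; the r used in practice trades "
      "robustness to the nominals against discriminating power.")
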