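"""End-to-end reproduction drivers.

Each ``reproduce_*`` function recomputes one of the summary tables of the
package's reference study of the dextromethorphan--sertraline inhibition
system from the built-in nominal estimates alone:

* :func:`reproduce_estimation_designs` -- all D- and Ds-optimal designs on
  both error scales, with equivalence-theorem certificates;
* :func:`reproduce_estimation_efficiencies` -- the cross-table of D/Ds
  efficiencies of every design under every reference model;
* :func:`reproduce_discrimination_designs` -- T-, compound-T- and
  Ds-discriminating designs with both-direction T-efficiencies;
* :func:`reproduce_hit_rates` -- seeded Monte-Carlo hit rates of the exact
  (rounded) discriminating designs;
* :func:`inhibition_scheme` -- the inhibitor concentrations (in IC50
  multiples) needed for given percent-inhibition levels.

All functions work in memory and optionally write CSV reports (with a
provenance/seed header) to an output directory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import models
from .nominals import NOMINAL, PROVENANCE_NOTE, nominal
from .designs import (
    ApproximateDesign,
    GridSpec,
    d_efficiency,
    ds_efficiency,
    equivalence_check,
    optimize_d,
    optimize_ds,
    round_design,
)
from .discrimination import ct_optimal, lack_of_fit, t_optimal, nominal_box, DeltaSpec, delta_optimal
from .simulation import SimulationConfig, hit_rate_study

__all__ = [
    "default_grid",
    "design_problems",
    "reproduce_estimation_designs",
    "reproduce_estimation_efficiencies",
    "reproduce_discrimination_designs",
    "reproduce_hit_rates",
    "reference_discrimination_designs",
    "inhibition_scheme",
]

#: reference approximate discriminating designs on the log scale (corner
#: support, weights from the converged criteria); used as ready-made inputs
#: for simulation studies without re-running the optimisers.
_CORNERS = np.array([[0.02, 0.0], [30.0, 0.0], [0.02, 60.0], [30.0, 60.0]])
REFERENCE_LOG_DISCRIMINATION_WEIGHTS = {
    "A1": (0.0095, 0.1402, 0.3600, 0.4903),  # T-optimal, non-competitive true
    "A2": (0.1688, 0.1818, 0.3002, 0.3492),  # compound-T, nu = 0.5
    "A3": (0.1633, 0.2189, 0.2811, 0.3367),  # Ds for the mixing parameter
    "A4": (0.2500, 0.2500, 0.2500, 0.2500),  # T-optimal, competitive true
}


def reference_discrimination_designs() -> dict[str, ApproximateDesign]:
    """The four named log-scale discriminating designs A1--A4."""
    return {
        name: ApproximateDesign(_CORNERS.copy(), np.array(w))
        for name, w in REFERENCE_LOG_DISCRIMINATION_WEIGHTS.items()
    }


def default_grid(scale: str) -> GridSpec:
    return GridSpec.log_case() if scale == "log" else GridSpec.standard_case(0.1)


def design_problems(scale: str) -> dict[str, tuple[str, np.ndarray, object]]:
    """The named estimation-design problems: name -> (model, theta, subset).

    ``4D_N``/``4D_C`` are D-problems for the encompassing model pinned at
    mixing parameter 0 (non-competitive nominals) and 1 (competitive
    nominals); ``4D_E`` uses the encompassing estimates; ``3D_N``/``3D_C``
    are the three-parameter pure models; ``Ds_N``/``Ds_C`` target the mixing
    parameter alone.
    """
    nc = nominal("noncompetitive", scale).theta
    c = nominal("competitive", scale).theta
    e = nominal("encompassing", scale).theta
    return {
        "4D_N": ("encompassing", np.append(nc, 0.0), None),
        "3D_N": ("noncompetitive", nc, None),
        "4D_C": ("encompassing", np.append(c, 1.0), None),
        "3D_C": ("competitive", c, None),
        "4D_E": ("encompassing", e, None),
        "Ds_N": ("encompassing", np.append(nc, 0.0), [3]),
        "Ds_C": ("encompassing", np.append(c, 1.0), [3]),
    }


def _report(df: pd.DataFrame, outdir, name: str, meta: tuple[str, ...]) -> None:
    if outdir is None:
        return
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / name, "w") as fh:
        for line in (PROVENANCE_NOTE,) + meta:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def reproduce_estimation_designs(
    scales=("standard", "log"), grid=None, outdir=None,
) -> dict[tuple[str, str], dict]:
    """All D/Ds-optimal estimation designs with their equivalence certificates.

    Returns ``{(name, scale): {"design": ..., "certificate": ...}}``.
    """
    out = {}
    for scale in scales:
        g = grid or default_grid(scale)
        for name, (model, theta, subset) in design_problems(scale).items():
            if subset is None:
                design = optimize_d(g, model, theta, scale)
            else:
                design = optimize_ds(g, model, theta, subset, scale)
            cert = equivalence_check(design, g, model, theta, scale, subset)
            out[(name, scale)] = {"design": design, "certificate": cert}
            _report(design.as_dataframe(), outdir, f"design_{name}_{scale}.csv",
                    (f"criterion={'D' if subset is None else 'Ds'}",
                     f"model={model} scale={scale}",
                     f"equivalence gap={cert['gap']:.3g} ok={cert['ok']}"))
    return out


def reproduce_estimation_efficiencies(
    designs=None, scales=("standard", "log"), outdir=None,
) -> dict[str, pd.DataFrame]:
    """D/Ds efficiency (%) of every design under every reference optimum.

    One table per reference scale; rows are (design scale, design name),
    columns reference problems.  Singular design/reference combinations are
    reported as NaN (the design cannot estimate that model's parameters).
    """
    if designs is None:
        designs = reproduce_estimation_designs(scales)
    tables = {}
    for ref_scale in scales:
        problems = design_problems(ref_scale)
        rows = []
        for (dname, dscale), entry in designs.items():
            row = {"design": dname, "design_scale": dscale}
            for rname, (model, theta, subset) in problems.items():
                ref = designs[(rname, ref_scale)]["design"]
                if subset is None:
                    eff = d_efficiency(entry["design"], ref, model, theta, ref_scale)
                else:
                    eff = ds_efficiency(entry["design"], ref, model, theta, subset,
                                        ref_scale)
                row[rname] = 100.0 * eff if eff > 0 else np.nan
            rows.append(row)
        tables[ref_scale] = pd.DataFrame(rows)
        _report(tables[ref_scale], outdir, f"efficiencies_ref_{ref_scale}.csv",
                (f"reference scale={ref_scale}", "NaN = singular design",))
    return tables


def reproduce_discrimination_designs(
    scales=("log",), nus=(0.0, 0.5, 1.0), include_ds=True, grid=None, outdir=None,
) -> dict[tuple[str, str], dict]:
    """T-, compound-T- and Ds-discriminating designs with T-efficiencies.

    For each scale the discrimination is competitive vs non-competitive at
    the built-in nominals.  Keys are (label, scale) with labels ``T0`` (the
    non-competitive-true T-optimum), ``T1``, ``CT<nu>`` and ``DsE`` (the
    Ds-design for the mixing parameter at the encompassing estimates); on the
    log scale these are the designs usually called A1, A4, A2 and A3.
    Entries carry the design and its T-efficiency under both directions.
    """
    out = {}
    for scale in scales:
        g = grid or default_grid(scale)
        nc = nominal("noncompetitive", scale).theta
        c = nominal("competitive", scale).theta
        ref0 = t_optimal(g, "noncompetitive", nc, "competitive", scale)
        ref1 = t_optimal(g, "competitive", c, "noncompetitive", scale)
        entries = {("T0", scale): ref0.design, ("T1", scale): ref1.design}
        for nu in nus:
            if nu == 0.0 or nu == 1.0:
                continue
            ct = ct_optimal(g, ("noncompetitive", "competitive"), (nc, c), nu, scale)
            entries[(f"CT{nu:g}", scale)] = ct.design
        if include_ds:
            e = nominal("encompassing", scale).theta
            entries[("DsE", scale)] = optimize_ds(g, "encompassing", e, [3], scale)
        for key, design in entries.items():
            eff0 = lack_of_fit(design, "noncompetitive", nc, "competitive",
                               scale).delta / ref0.delta
            eff1 = lack_of_fit(design, "competitive", c, "noncompetitive",
                               scale).delta / ref1.delta
            out[key] = {"design": design, "eff_T0": 100 * eff0, "eff_T1": 100 * eff1}
            df = design.as_dataframe()
            _report(df, outdir, f"design_{key[0]}_{scale}.csv",
                    (f"T-efficiency vs T0 optimum: {100*eff0:.2f}%",
                     f"T-efficiency vs T1 optimum: {100*eff1:.2f}%"))
    return out


def _delta_designs(Ns, r_values, alternatives, seed, grid):
    """delta-optimal exact designs for each (N, r, alternative)."""
    out = {}
    boxes_se = {m: (NOMINAL[(m, "log")].theta, NOMINAL[(m, "log")].se)
                for m in ("competitive", "noncompetitive")}
    for r in r_values:
        for alt in alternatives:
            dspec = DeltaSpec(
                models=("competitive", "noncompetitive"),
                boxes=(nominal_box(*boxes_se["competitive"], r, alt),
                       nominal_box(*boxes_se["noncompetitive"], r, alt)),
                scale="log", r=r, alternative=alt,
            )
            for N in Ns:
                name = f"delta_r{r:g}{alt if r > 4 else ''}_N{N}"
                out[name] = delta_optimal(N, grid, dspec, seed=seed)
    return out


def reproduce_hit_rates(
    seed: int,
    B: int = 100,
    Ns=(6, 7, 8, 9),
    sigma: float | None = None,
    include_delta=(1, 4),
    outdir=None,
    grid=None,
) -> pd.DataFrame:
    """Seeded hit-rate study of the exact discriminating designs.

    The reference log-scale designs A1--A4 are rounded to each N; optionally
    delta-optimal exact designs (tuning multipliers in ``include_delta``) are
    computed at each N and compared alongside.  ``sigma`` defaults to the
    encompassing log-case residual SD.
    """
    if sigma is None:
        sigma = nominal("encompassing", "log").sigma
    g = grid or default_grid("log")
    approx = reference_discrimination_designs()
    frames = []
    for N in Ns:
        designs = {name: round_design(d, N) for name, d in approx.items()}
        if include_delta:
            designs.update(_delta_designs([N], include_delta, ("a",), seed, g))
        cfg = SimulationConfig(designs=designs, B=B, sigma=sigma, scale="log",
                               seed=seed)
        tab = hit_rate_study(cfg)
        frames.append(tab)
    table = pd.concat(frames, ignore_index=True)
    _report(table, outdir, "hit_rates.csv",
            (f"B={B} per truth, sigma={sigma}, seed={seed}",))
    return table


def inhibition_scheme(
    ic50: float | None = None,
    fractional_activities=(1.0, 0.50, 0.25, 0.10),
) -> pd.DataFrame:
    """Inhibitor concentrations for a percent-inhibition titration scheme.

    ``ic50`` defaults to the encompassing log-case estimate.  Returns one row
    per activity level with the required inhibitor concentration and its
    expression in IC50 multiples (Hill coefficient one throughout).
    """
    if ic50 is None:
        ic50 = models.ic50_encompassing(nominal("encompassing", "log").theta)
    rows = []
    for fa in fractional_activities:
        xi = models.inhibitor_for_activity(ic50, fa)
        rows.append({
            "percent_inhibition": 100.0 * (1.0 - fa),
            "fractional_activity": fa,
            "activity_ratio": 1.0 / fa,
            "x_I": xi,
            "x_I_in_ic50_units": xi / ic50,
        })
    return pd.DataFrame(rows)
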