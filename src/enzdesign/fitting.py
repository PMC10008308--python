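"""Nonlinear least-squares estimation of the kinetic models.

Datasets are plain :class:`pandas.DataFrame` objects with columns
``substrate``, ``inhibitor`` and ``rate`` (one observation per row), read and
written as delimited text.  Fitting minimises the residual sum of squares of
the rate (standard scale) or of its natural logarithm (log scale, the
multiplicative log-normal error model); parameters are box-constrained to be
non-negative, the mixing parameter of the encompassing model to [0, 1].

Zero substrate concentrations and zero observed rates cannot be
log-transformed; :func:`replace_zeros` substitutes a small positive floor
(default 0.02) for them before a log-scale fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import models
from .nominals import NOMINAL

__all__ = [
    "COLUMNS",
    "IdentifiabilityError",
    "ConvergenceError",
    "FitResult",
    "read_dataset",
    "write_dataset",
    "replace_zeros",
    "fit_model",
    "sse_mse",
    "residual_summaries",
]

COLUMNS = ("substrate", "inhibitor", "rate")

#: default floor used to replace zero substrate concentrations / rates
DEFAULT_ZERO_FLOOR = 0.02


class IdentifiabilityError(RuntimeError):
    """The information matrix is singular at the optimum."""


class ConvergenceError(RuntimeError):
    """An iterative numerical procedure failed to converge."""


@dataclass
class FitResult:
    """Result of one nonlinear least-squares fit."""

    model: str
    scale: str
    theta: np.ndarray
    se: np.ndarray
    sigma: float  # residual standard error sqrt(sse / dof)
    sse: float
    dof: int
    fitted: np.ndarray = field(repr=False)  # fitted response on the analysis scale
    at_bounds: np.ndarray = field(repr=False)  # parameters stuck at a box bound
    message: str = ""

    @property
    def mse(self) -> float:
        return self.sse / self.dof

    def to_json(self, path=None) -> str:
        payload = {
            "model": self.model,
            "scale": self.scale,
            "theta": [float(v) for v in self.theta],
            "se": [float(v) for v in self.se],
            "sigma_hat": self.sigma,
            "sse": self.sse,
            "dof": self.dof,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def read_dataset(path) -> pd.DataFrame:
    """Read a delimited rate dataset (columns substrate, inhibitor, rate)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset {path} lacks required columns {missing}")
    return df.loc[:, list(COLUMNS)].astype(float)


def write_dataset(data: pd.DataFrame, path) -> None:
    data.loc[:, list(COLUMNS)].to_csv(path, index=False)


def replace_zeros(data: pd.DataFrame, floor: float = DEFAULT_ZERO_FLOOR) -> pd.DataFrame:
    """Replace zero substrate concentrations and zero rates by ``floor``.

    Inhibitor concentrations are never modified.  Returns a copy.
    """
    if not floor > 0.0:
        raise ValueError(f"floor must be positive, got {floor}")
    out = data.copy()
    out.loc[out["substrate"] == 0.0, "substrate"] = floor
    out.loc[out["rate"] == 0.0, "rate"] = floor
    return out


def _default_init(model: str, scale: str, data: pd.DataFrame) -> np.ndarray:
    if (model, scale) in NOMINAL:
        return NOMINAL[(model, scale)].theta.copy()
    # Michaelis-Menten: crude data-driven start
    v0 = float(data["rate"].max())
    m0 = float(np.median(data["substrate"])) or 1.0
    return np.array([max(v0, 1e-3), max(m0, 1e-3)])


def _bounds(model: str):
    m = models.n_params(model)
    lo = np.full(m, 1e-9)
    hi = np.full(m, np.inf)
    if model == "encompassing":
        lo[3], hi[3] = 0.0, 1.0
    return lo, hi


def fit_model(
    data: pd.DataFrame,
    model: str,
    scale: str = "standard",
    init=None,
    n_starts: int = 5,
    seed: int = 0,
    zero_floor: float | None = None,
    check_identifiability: bool = True,
) -> FitResult:
    """Fit ``model`` to ``data`` by trust-region least squares with multistart.

    ``init`` defaults to the built-in nominal estimates for the model/scale
    (or a data-driven start for the Michaelis-Menten model).  ``n_starts``
    jittered restarts guard against local minima.  On the log scale all rates
    and substrate concentrations must be positive; pass ``zero_floor`` to
    apply :func:`replace_zeros` first.

    Raises :class:`IdentifiabilityError` when the information matrix at the
    optimum is singular (e.g. fitting an inhibition model to data with no
    inhibitor variation) and :class:`ConvergenceError` when no start converges.
    """
    m = models.n_params(model)
    if zero_floor is not None:
        data = replace_zeros(data, zero_floor)
    xs = data["substrate"].to_numpy(float)
    xi = data["inhibitor"].to_numpy(float)
    y = data["rate"].to_numpy(float)
    n = y.size
    if n <= m:
        raise ValueError(f"need more than m={m} observations, got {n}")
    if scale == "log":
        if np.any(y <= 0.0) or np.any(xs <= 0.0):
            raise models.DomainError(
                "log-scale fit needs positive rates and substrate concentrations; "
                "call replace_zeros first"
            )
        z = np.log(y)
    elif scale == "standard":
        z = y
    else:
        raise ValueError(f"unknown scale {scale!r}")

    def residuals(theta):
        return z - models.response(model, theta, xs, xi, scale)

    def jac(theta):
        return -models.response_gradient(model, theta, xs, xi, scale)

    lo, hi = _bounds(model)
    if init is None:
        init = _default_init(model, scale, data)
    init = np.clip(np.asarray(init, float), lo + 1e-12, hi)

    rng = np.random.default_rng(seed)
    starts = [init]
    for _ in range(max(0, n_starts - 1)):
        jit = init * np.exp(rng.normal(0.0, 0.3, size=m))
        starts.append(np.clip(jit, lo + 1e-12, hi))

    best = None
    trace = []
    for start in starts:
        try:
            sol = least_squares(
                residuals, start, jac=jac, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-10,
            )
        except Exception as exc:  # pragma: no cover - scipy-internal failure
            trace.append(f"start {start}: {exc}")
            continue
        trace.append(f"start {np.round(start, 4)}: cost={sol.cost:.6g} status={sol.status}")
        if sol.status > 0 and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise ConvergenceError("no least-squares start converged:\n" + "\n".join(trace))

    theta = best.x
    sse = float(2.0 * best.cost)
    dof = n - m
    F = models.response_gradient(model, theta, xs, xi, scale)
    info = F.T @ F
    sv = np.linalg.svd(info, compute_uv=False)
    singular = sv[0] <= 0.0 or sv[-1] / sv[0] < 1e-12
    if singular and check_identifiability:
        raise IdentifiabilityError(
            f"singular information matrix at the optimum of {model} ({scale}); "
            "some parameters are not identifiable from this design"
        )
    sigma = float(np.sqrt(sse / dof))
    if singular:
        se = np.full(m, np.nan)
    else:
        cov = sigma**2 * np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    at_bounds = (np.abs(theta - lo) < 1e-8) | (np.abs(theta - hi) < 1e-8)
    message = ""
    if model == "encompassing" and at_bounds[3]:
        message = (
            "mixing parameter at a boundary of [0, 1]; its linearization "
            "standard error is unreliable"
        )
    return FitResult(
        model=model, scale=scale, theta=theta, se=se, sigma=sigma, sse=sse,
        dof=dof, fitted=z - best.fun, at_bounds=at_bounds, message=message,
    )


def sse_mse(y, fitted, m: int) -> tuple[float, float]:
    """Residual sum of squares and mean square with ``len(y) - m`` dof."""
    y = np.asarray(y, float)
    fitted = np.asarray(fitted, float)
    sse = float(np.sum((y - fitted) ** 2))
    return sse, sse / (y.size - m)


def residual_summaries(
    data: pd.DataFrame,
    fit_standard: FitResult | None = None,
    fit_log: FitResult | None = None,
) -> dict[str, tuple[float, float]]:
    """The three residual summaries (SSE, MSE) of a fitted kinetic model.

    * ``standard``: rate residuals of a standard-scale fit;
    * ``log``: log-rate residuals of a log-scale fit (SSE_l*, MSE_l*);
    * ``back_transformed``: rate residuals against the exponentiated fitted
      log response (SSE_b*, MSE_b*).

    Only the summaries computable from the supplied fits are returned; the
    degrees of freedom are N - m throughout.
    """
    out: dict[str, tuple[float, float]] = {}
    y = data["rate"].to_numpy(float)
    if fit_standard is not None:
        if fit_standard.scale != "standard":
            raise ValueError("fit_standard must be a standard-scale fit")
        out["standard"] = sse_mse(y, fit_standard.fitted, models.n_params(fit_standard.model))
    if fit_log is not None:
        if fit_log.scale != "log":
            raise ValueError("fit_log must be a log-scale fit")
        m = models.n_params(fit_log.model)
        out["log"] = sse_mse(np.log(y), fit_log.fitted, m)
        out["back_transformed"] = sse_mse(y, np.exp(fit_log.fitted), m)
    return out
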