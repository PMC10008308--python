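"""Mean-rate models for Michaelis--Menten inhibition kinetics.

Four nested velocity models are supported, each mapping a substrate
concentration ``x_S`` and an inhibitor concentration ``x_I`` to an expected
reaction rate:

``michaelis_menten``
    eta = V * x_S / (M + x_S), no inhibition (2 parameters V, M).
``competitive``
    eta = V * x_S / (M * (1 + x_I / K) + x_S); the inhibitor competes with the
    substrate for the free enzyme, inflating the apparent Michaelis constant.
``noncompetitive``
    eta = V * x_S / ((M + x_S) * (1 + x_I / K)); inhibitor binding deactivates
    the enzyme--substrate complex and scales the whole rate down.
``encompassing``
    eta = V * x_S / (M * (1 + x_I / K) + x_S * (1 + (1 - lam) * x_I / K)); a
    four-parameter family with mixing parameter ``lam`` in [0, 1] that nests the
    competitive (lam = 1) and non-competitive (lam = 0) models.

Parameters are passed as flat arrays ``theta = (V, M, K[, lam])`` with V the
maximum velocity, M the Michaelis constant (substrate units) and K the
inhibition constant (inhibitor units).

Every model is available on two scales.  The ``standard`` scale returns the
rate itself (additive normal error model); the ``log`` scale returns the
natural logarithm of the rate, the mean of the log-transformed model with
multiplicative log-normal error, and therefore requires a strictly positive
rate (x_S > 0).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MODELS",
    "SCALES",
    "DomainError",
    "n_params",
    "validate_theta",
    "rate",
    "rate_gradient",
    "response",
    "response_gradient",
    "ic50_encompassing",
    "inhibitor_for_activity",
]

#: model identifier -> number of parameters m
MODELS = {
    "michaelis_menten": 2,
    "competitive": 3,
    "noncompetitive": 3,
    "encompassing": 4,
}

SCALES = ("standard", "log")


class DomainError(ValueError):
    """The requested response is undefined (e.g. log of a zero rate)."""


def n_params(model: str) -> int:
    try:
        return MODELS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(MODELS)}")


def validate_theta(model: str, theta) -> np.ndarray:
    """Check that ``theta`` is admissible for ``model`` and return it as an array.

    V, M, K must be strictly positive; the mixing parameter of the
    encompassing model must lie in [0, 1].
    """
    m = n_params(model)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if theta.shape != (m,):
        raise ValueError(f"{model} needs {m} parameters, got shape {theta.shape}")
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite parameter value")
    npos = min(m, 3)
    if np.any(theta[:npos] <= 0.0):
        raise ValueError(f"kinetic parameters must be positive, got {theta[:npos]}")
    if model == "encompassing" and not 0.0 <= theta[3] <= 1.0:
        raise ValueError(f"mixing parameter must lie in [0, 1], got {theta[3]}")
    return theta


def _check_scale(scale: str) -> None:
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")


def rate(model: str, theta, x_s, x_i=0.0) -> np.ndarray | float:
    """Expected reaction rate eta(theta, x) on the natural (standard) scale.

    Vectorised over ``x_s`` / ``x_i`` (broadcast against each other).
    """
    theta = np.asarray(theta, dtype=float)
    x_s, x_i = np.broadcast_arrays(
        np.asarray(x_s, dtype=float), np.asarray(x_i, dtype=float)
    )
    if model == "michaelis_menten":
        V, M = theta
        return V * x_s / (M + x_s) + 0.0 * x_i
    if model == "competitive":
        V, M, K = theta
        return V * x_s / (M * (1.0 + x_i / K) + x_s)
    if model == "noncompetitive":
        V, M, K = theta
        return V * x_s / ((M + x_s) * (1.0 + x_i / K))
    if model == "encompassing":
        V, M, K, lam = theta
        return V * x_s / (M * (1.0 + x_i / K) + x_s * (1.0 + (1.0 - lam) * x_i / K))
    raise ValueError(f"unknown model {model!r}")


def rate_gradient(model: str, theta, x_s, x_i=0.0) -> np.ndarray:
    """Analytic gradient of the rate w.r.t. the parameters.

    Returns an array of shape ``broadcast(x_s, x_i).shape + (m,)``.
    """
    theta = np.asarray(theta, dtype=float)
    x_s, x_i = np.broadcast_arrays(
        np.asarray(x_s, dtype=float), np.asarray(x_i, dtype=float)
    )
    if model == "michaelis_menten":
        V, M = theta
        dV = x_s / (M + x_s)
        dM = -V * x_s / (M + x_s) ** 2
        return np.stack([dV, dM], axis=-1)
    if model == "competitive":
        V, M, K = theta
        D = M * (1.0 + x_i / K) + x_s
        dV = x_s / D
        dM = -V * x_s * (1.0 + x_i / K) / D**2
        dK = V * x_s * M * x_i / (K**2 * D**2)
        return np.stack([dV, dM, dK], axis=-1)
    if model == "noncompetitive":
        V, M, K = theta
        A = M + x_s
        B = 1.0 + x_i / K
        dV = x_s / (A * B)
        dM = -V * x_s / (A**2 * B)
        dK = V * x_s * x_i / (A * B**2 * K**2)
        return np.stack([dV, dM, dK], axis=-1)
    if model == "encompassing":
        V, M, K, lam = theta
        D = M * (1.0 + x_i / K) + x_s * (1.0 + (1.0 - lam) * x_i / K)
        dV = x_s / D
        dM = -V * x_s * (1.0 + x_i / K) / D**2
        dK = V * x_s * x_i * (M + (1.0 - lam) * x_s) / (K**2 * D**2)
        dlam = V * x_s**2 * x_i / (K * D**2)
        return np.stack([dV, dM, dK, dlam], axis=-1)
    raise ValueError(f"unknown model {model!r}")


def response(model: str, theta, x_s, x_i=0.0, scale: str = "standard"):
    """Expected response: the rate, or its natural log when ``scale='log'``.

    On the log scale the rate must be strictly positive, which requires
    ``x_s > 0``; violations raise :class:`DomainError` naming the point.
    """
    _check_scale(scale)
    eta = rate(model, theta, x_s, x_i)
    if scale == "standard":
        return eta
    bad = np.asarray(eta) <= 0.0
    if np.any(bad):
        xs = np.broadcast_to(np.asarray(x_s, dtype=float), np.shape(bad))
        xi = np.broadcast_to(np.asarray(x_i, dtype=float), np.shape(bad))
        idx = np.argwhere(np.atleast_1d(bad))[0]
        pt = (np.atleast_1d(xs)[tuple(idx)], np.atleast_1d(xi)[tuple(idx)])
        raise DomainError(
            f"log-scale response undefined: zero rate at (x_S={pt[0]}, x_I={pt[1]})"
        )
    return np.log(eta)


def response_gradient(model: str, theta, x_s, x_i=0.0, scale: str = "standard"):
    """Gradient of the (possibly log) response w.r.t. the parameters.

    The log-scale gradient is the standard-scale gradient divided by the rate
    (chain rule).
    """
    _check_scale(scale)
    g = rate_gradient(model, theta, x_s, x_i)
    if scale == "standard":
        return g
    eta = rate(model, theta, x_s, x_i)
    bad = np.asarray(eta) <= 0.0
    if np.any(bad):
        raise DomainError(
            "log-scale gradient undefined at a zero rate (x_S = 0 somewhere)"
        )
    return g / np.asarray(eta)[..., np.newaxis]


def ic50_encompassing(theta, tol: float = 1e-10, xtol: float = 1e-12) -> float:
    """Half-maximal inhibitory concentration of the encompassing model.

    Defined as the inhibitor concentration at which the expected rate drops to
    half of its uninhibited value when the substrate is held at the Michaelis
    constant estimate (x_S = theta_M).  Located by one-dimensional root
    finding on the rate ratio; with mixing parameter 1 this reduces to the
    competitive-model value 2 * theta_K, with 0 to the non-competitive value
    theta_K.
    """
    theta = validate_theta("encompassing", theta)
    x_s = theta[1]
    top = rate("encompassing", theta, x_s, 0.0)

    def half_deficit(x_i: float) -> float:
        return rate("encompassing", theta, x_s, x_i) / top - 0.5

    hi = max(theta[2], 1.0)
    for _ in range(200):
        if half_deficit(hi) < 0.0:
            break
        hi *= 2.0
    else:  # pragma: no cover - rate is strictly decreasing in x_I
        raise RuntimeError("IC50 bracketing failed: rate never halved")
    return float(brentq(half_deficit, 0.0, hi, xtol=xtol, rtol=tol))


def inhibitor_for_activity(ic50: float, fractional_activity: float) -> float:
    """Inhibitor concentration producing a given fractional activity.

    For a concentration--response relationship with Hill coefficient one,
    ``x_I = IC50 * (E0 / Ei - 1)`` where ``fractional_activity = Ei / E0`` is
    the rate with inhibitor relative to the uninhibited rate.
    """
    if not ic50 > 0.0:
        raise ValueError(f"ic50 must be positive, got {ic50}")
    if not 0.0 < fractional_activity <= 1.0:
        raise DomainError(
            f"fractional activity must lie in (0, 1], got {fractional_activity}"
            " (zero activity needs an infinite inhibitor concentration)"
        )
    return ic50 * (1.0 / fractional_activity - 1.0)
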