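"""Built-in nominal parameter estimates.

The locally optimal designs computed in this package require nominal parameter
values.  The constants below are nonlinear least-squares estimates (with their
linearization standard errors and residual standard errors) obtained from a
prior dextromethorphan--sertraline inhibition assay of N = 120 rate
observations, fitted on both the standard (additive normal error) and the log
(multiplicative log-normal error) scale.  They are the package defaults for
every design computation and for initial values in fitting; any function that
takes ``theta`` accepts user-supplied values instead.

Parameter order is (V, M, K) for the three-parameter inhibition models and
(V, M, K, lam) for the encompassing model.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = ["Estimates", "NOMINAL", "nominal", "PROVENANCE_NOTE"]


class Estimates(NamedTuple):
    """A fitted parameter vector with standard errors and residual SD."""

    theta: np.ndarray
    se: np.ndarray
    sigma: float


def _e(theta, se, sigma) -> Estimates:
    return Estimates(np.asarray(theta, float), np.asarray(se, float), float(sigma))


NOMINAL: dict[tuple[str, str], Estimates] = {
    ("competitive", "standard"): _e(
        [7.2976, 4.3860, 2.5821], [0.1143, 0.2333, 0.1454], 0.1553
    ),
    ("competitive", "log"): _e(
        [6.0645, 3.2799, 3.3153], [0.9260, 0.7288, 0.6041], 0.5160
    ),
    ("noncompetitive", "standard"): _e(
        [8.6957, 8.0664, 12.0566], [0.2227, 0.4880, 0.6709], 0.2272
    ),
    ("noncompetitive", "log"): _e(
        [12.0125, 8.5359, 5.6638], [2.0553, 1.5721, 0.8879], 0.5306
    ),
    ("encompassing", "standard"): _e(
        [7.4253, 4.6808, 3.0581, 0.9636], [0.1298, 0.2724, 0.2815, 0.0191], 0.1526
    ),
    ("encompassing", "log"): _e(
        [6.9897, 3.9799, 3.7380, 0.8737], [1.3406, 1.0403, 0.7218, 0.1123], 0.5128
    ),
}

PROVENANCE_NOTE = (
    "nominal parameter values: built-in least-squares estimates from a prior "
    "dextromethorphan-sertraline inhibition assay (N=120)"
)


def nominal(model: str, scale: str) -> Estimates:
    """Return the built-in nominal estimates for ``model`` on ``scale``."""
    try:
        return NOMINAL[(model, scale)]
    except KeyError:
        raise KeyError(
            f"no built-in nominal estimates for model={model!r}, scale={scale!r}"
        )
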