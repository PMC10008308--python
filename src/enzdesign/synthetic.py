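"""Synthetic rate datasets emulating a substrate--inhibitor titration plate.

The estimation code in this package was developed against a laboratory
dextromethorphan--sertraline assay that is not publicly deposited.  This
module generates datasets with the same layout: 15 substrate concentrations
on [0, 30] (denser at the low end, including 0) fully crossed with 8
inhibitor concentrations on [0, 60] (including 0), giving N = 120 single
observations, under either error structure:

* ``multiplicative_lognormal`` -- y = eta * exp(e), e ~ N(0, sigma^2); rates
  stay positive at any noise level;
* ``additive_normal`` -- y = eta + e; large sigma can (deliberately) produce
  non-positive rates, the failure mode that motivates the log-scale model.

The exact concentration levels of the original plate were not published; the
defaults below are a single package-level choice matching the qualitative
layout, kept in module constants so users can override them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models

__all__ = [
    "SUBSTRATE_LEVELS",
    "INHIBITOR_LEVELS",
    "ERROR_STRUCTURES",
    "StudyTemplate",
    "default_template",
    "generate_study",
]

SUBSTRATE_LEVELS = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 7.0, 9.0,
                    12.0, 15.0, 20.0, 25.0, 30.0)
INHIBITOR_LEVELS = (0.0, 2.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0)

ERROR_STRUCTURES = ("additive_normal", "multiplicative_lognormal")


@dataclass(frozen=True)
class StudyTemplate:
    """The factorial layout of one synthetic titration study."""

    substrate_levels: tuple = SUBSTRATE_LEVELS
    inhibitor_levels: tuple = INHIBITOR_LEVELS
    error_structure: str = "multiplicative_lognormal"

    def __post_init__(self):
        s = np.asarray(self.substrate_levels, float)
        i = np.asarray(self.inhibitor_levels, float)
        if np.any(np.diff(s) <= 0) or np.any(np.diff(i) <= 0):
            raise ValueError("concentration levels must be sorted ascending")
        if self.error_structure not in ERROR_STRUCTURES:
            raise ValueError(
                f"error_structure must be one of {ERROR_STRUCTURES}"
            )

    @property
    def N(self) -> int:
        return len(self.substrate_levels) * len(self.inhibitor_levels)

    def grid(self) -> np.ndarray:
        """All (x_S, x_I) combinations, one row per observation."""
        ss, ii = np.meshgrid(self.substrate_levels, self.inhibitor_levels,
                             indexing="ij")
        return np.column_stack([ss.ravel(), ii.ravel()])


def default_template(error_structure: str = "multiplicative_lognormal") -> StudyTemplate:
    """The 15 x 8 = 120-well default plate layout."""
    return StudyTemplate(error_structure=error_structure)


def generate_study(
    template: StudyTemplate, model: str, theta, sigma: float, seed=None, rng=None,
) -> pd.DataFrame:
    """Simulate one dataset over the template's factorial layout.

    ``sigma`` is the error SD on the log scale for the multiplicative
    structure and on the rate scale for the additive one; ``sigma = 0``
    returns the exact mean surface.
    """
    theta = models.validate_theta(model, theta)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    pts = template.grid()
    eta = models.rate(model, theta, pts[:, 0], pts[:, 1])
    if template.error_structure == "multiplicative_lognormal":
        y = eta * np.exp(rng.normal(0.0, sigma, size=eta.shape))
    else:
        y = eta + rng.normal(0.0, sigma, size=eta.shape)
    return pd.DataFrame({"substrate": pts[:, 0], "inhibitor": pts[:, 1], "rate": y})
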