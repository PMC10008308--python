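"""Shared fixtures: candidate grids and cached optimal-design computations.

The heavier optimisations (standard-scale D/Ds designs, Fedorov-Wynn T and
compound-T optima) are session-scoped so that module tests and the
acceptance suite share one computation.
"""

import numpy as np
import pytest

from enzdesign.designs import GridSpec
from enzdesign.discrimination import ct_optimal, t_optimal
from enzdesign.nominals import nominal
from enzdesign.workflow import reproduce_estimation_designs


@pytest.fixture(scope="session")
def log_grid():
    return GridSpec.log_case()


@pytest.fixture(scope="session")
def std_grid():
    return GridSpec.standard_case(0.1)


@pytest.fixture(scope="session")
def log_estimation_designs(log_grid):
    """All log-scale D/Ds optima with equivalence certificates."""
    return reproduce_estimation_designs(scales=("log",), grid=log_grid)


@pytest.fixture(scope="session")
def std_estimation_designs(std_grid):
    """All standard-scale D/Ds optima with equivalence certificates."""
    return reproduce_estimation_designs(scales=("standard",), grid=std_grid)


@pytest.fixture(scope="session")
def log_t_optima(log_grid):
    """Log-scale T-optima: non-competitive true (A1) and competitive true (A4)."""
    nc = nominal("noncompetitive", "log").theta
    c = nominal("competitive", "log").theta
    return {
        "A1": t_optimal(log_grid, "noncompetitive", nc, "competitive", "log"),
        "A4": t_optimal(log_grid, "competitive", c, "noncompetitive", "log"),
    }


@pytest.fixture(scope="session")
def log_ct_optimum(log_grid):
    """Log-scale compound-T optimum at nu = 0.5 (A2)."""
    nc = nominal("noncompetitive", "log").theta
    c = nominal("competitive", "log").theta
    return ct_optimal(log_grid, ("noncompetitive", "competitive"), (nc, c), 0.5, "log")


@pytest.fixture(scope="session")
def std_t_optima(std_grid):
    nc = nominal("noncompetitive", "standard").theta
    c = nominal("competitive", "standard").theta
    return {
        "T0": t_optimal(std_grid, "noncompetitive", nc, "competitive", "standard"),
        "T1": t_optimal(std_grid, "competitive", c, "noncompetitive", "standard"),
    }


@pytest.fixture(scope="session")
def std_ct_optimum(std_grid):
    nc = nominal("noncompetitive", "standard").theta
    c = nominal("competitive", "standard").theta
    return ct_optimal(std_grid, ("noncompetitive", "competitive"), (nc, c), 0.5,
                      "standard")
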