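"""D- and Ds-optimal designs for precise parameter estimation.

An *approximate design* xi is a probability measure on the rectangular design
region of substrate and inhibitor concentrations; its Fisher information
matrix (per observation, unit error variance) is

    M(xi, theta) = sum_i w_i f(x_i) f(x_i)^T,

where f is the parameter gradient of the (possibly log-transformed) mean
response.  D-optimality maximises det M; Ds-optimality maximises
det M / det M_22 for a subset of parameters of interest, M_22 being the
nuisance-parameter block.  Optimal measures are found on a finite candidate
grid by a multiplicative weight algorithm, then the support is merged and
refined by continuous constrained maximisation, and the result is certified
with the corresponding equivalence theorem: at a D-optimum the sensitivity
function psi(x) = f(x)^T M^{-1} f(x) is bounded by the number of parameters m
(by s for Ds) and attains the bound on the support.

Exact designs of size N are obtained from approximate ones by
largest-remainder apportionment of N * w_i.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import models
from .fitting import ConvergenceError, DEFAULT_ZERO_FLOOR

__all__ = [
    "GridSpec",
    "ApproximateDesign",
    "ExactDesign",
    "SingularDesignError",
    "fim",
    "d_criterion",
    "ds_criterion",
    "d_efficiency",
    "ds_efficiency",
    "sensitivity_d",
    "sensitivity_ds",
    "equivalence_check",
    "optimize_d",
    "optimize_ds",
    "round_design",
]


class SingularDesignError(RuntimeError):
    """An information matrix (or nuisance block) is singular."""


# --------------------------------------------------------------------------- #
# candidate grids and design containers
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class GridSpec:
    """A finite candidate grid on the rectangular design region.

    ``substrate`` and ``inhibitor`` hold the sorted marginal levels; the grid
    is their Cartesian product.  ``zero_floor`` records the positive lower
    substrate bound used on the log scale (log responses need x_S > 0).
    """

    substrate: np.ndarray
    inhibitor: np.ndarray
    zero_floor: float | None = None

    def __post_init__(self):
        s = np.asarray(self.substrate, float)
        i = np.asarray(self.inhibitor, float)
        if np.any(np.diff(s) <= 0) or np.any(np.diff(i) <= 0):
            raise ValueError("grid levels must be strictly increasing")
        if self.zero_floor is not None and s[0] < self.zero_floor:
            raise ValueError("log-scale grid must not go below the zero floor")
        object.__setattr__(self, "substrate", s)
        object.__setattr__(self, "inhibitor", i)

    @classmethod
    def log_case(cls, floor: float = DEFAULT_ZERO_FLOOR) -> "GridSpec":
        """The 31 x 61 grid {floor, 1, ..., 30} x {0, 1, ..., 60}."""
        return cls(
            substrate=np.concatenate([[floor], np.arange(1.0, 31.0)]),
            inhibitor=np.arange(0.0, 61.0),
            zero_floor=floor,
        )

    @classmethod
    def standard_case(cls, step: float = 0.1) -> "GridSpec":
        """A step-``step`` grid on [0, 30] x [0, 60] (refined continuously later)."""
        return cls(
            substrate=np.round(np.arange(0.0, 30.0 + step / 2, step), 10),
            inhibitor=np.round(np.arange(0.0, 60.0 + step / 2, step), 10),
        )

    @property
    def bounds(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return (
            (float(self.substrate[0]), float(self.substrate[-1])),
            (float(self.inhibitor[0]), float(self.inhibitor[-1])),
        )

    @property
    def steps(self) -> tuple[float, float]:
        return (
            float(np.min(np.diff(self.substrate))) if self.substrate.size > 1 else 1.0,
            float(np.min(np.diff(self.inhibitor))) if self.inhibitor.size > 1 else 1.0,
        )

    def points(self) -> np.ndarray:
        """All grid points as an (n, 2) array of (x_S, x_I)."""
        ss, ii = np.meshgrid(self.substrate, self.inhibitor, indexing="ij")
        return np.column_stack([ss.ravel(), ii.ravel()])


def _lexsort_points(points: np.ndarray) -> np.ndarray:
    keys = np.round(points, 9)
    return np.lexsort((keys[:, 1], keys[:, 0]))


@dataclass
class ApproximateDesign:
    """Support points with continuous weights summing to one."""

    points: np.ndarray  # (n, 2)
    weights: np.ndarray  # (n,)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.weights = np.atleast_1d(np.asarray(self.weights, float))
        if self.points.shape != (self.weights.size, 2):
            raise ValueError("points must be (n, 2) with one weight per point")
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {self.weights.sum()}")
        order = _lexsort_points(self.points)
        self.points = self.points[order]
        self.weights = self.weights[order]

    @property
    def n(self) -> int:
        return self.weights.size

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_S": self.points[:, 0], "x_I": self.points[:, 1], "weight": self.weights}
        )

    def to_csv(self, path, header_lines: tuple[str, ...] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.as_dataframe().to_csv(fh, index=False)


@dataclass
class ExactDesign:
    """Support points with integer replication counts (an N-run design)."""

    points: np.ndarray  # (n, 2)
    replicates: np.ndarray  # (n,) positive ints

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.replicates = np.atleast_1d(np.asarray(self.replicates))
        if not np.issubdtype(self.replicates.dtype, np.integer):
            rep = np.asarray(self.replicates, float)
            if np.any(rep != np.round(rep)):
                raise ValueError("replicates must be integers")
            self.replicates = rep.astype(int)
        if np.any(self.replicates <= 0):
            raise ValueError("replicates must be positive")
        if self.points.shape != (self.replicates.size, 2):
            raise ValueError("points must be (n, 2) with one count per point")
        order = _lexsort_points(self.points)
        self.points = self.points[order]
        self.replicates = self.replicates[order]

    @property
    def N(self) -> int:
        return int(self.replicates.sum())

    def expand(self) -> np.ndarray:
        """The N individual runs, one row per observation."""
        return np.repeat(self.points, self.replicates, axis=0)

    def as_approximate(self) -> ApproximateDesign:
        return ApproximateDesign(self.points, self.replicates / self.N)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_S": self.points[:, 0], "x_I": self.points[:, 1],
             "replicates": self.replicates}
        )


# --------------------------------------------------------------------------- #
# information matrices, criteria, efficiencies
# --------------------------------------------------------------------------- #


def _grad_matrix(points: np.ndarray, model: str, theta, scale: str) -> np.ndarray:
    return models.response_gradient(model, theta, points[:, 0], points[:, 1], scale)


def fim(design: ApproximateDesign, model: str, theta, scale: str = "standard") -> np.ndarray:
    """Fisher information matrix M = sum_i w_i f(x_i) f(x_i)^T of a design."""
    F = _grad_matrix(design.points, model, theta, scale)
    return F.T @ (design.weights[:, None] * F)


def d_criterion(M: np.ndarray) -> float:
    """det M (the D-criterion)."""
    return float(np.linalg.det(M))


def _split(subset, m: int):
    subset = np.atleast_1d(np.asarray(subset, int))
    nuisance = np.setdiff1d(np.arange(m), subset)
    return subset, nuisance


def ds_criterion(M: np.ndarray, subset) -> float:
    """det M / det M_22 with M_22 the nuisance block (Ds-criterion).

    ``subset`` indexes the s parameters of interest.  With no nuisance
    parameters this reduces to the D-criterion.
    """
    m = M.shape[0]
    subset, nuisance = _split(subset, m)
    if nuisance.size == 0:
        return d_criterion(M)
    M22 = M[np.ix_(nuisance, nuisance)]
    det22 = np.linalg.det(M22)
    if det22 <= 0.0:
        raise SingularDesignError("nuisance block of the information matrix is singular")
    return float(np.linalg.det(M) / det22)


def _rel_criterion(M, M_opt, subset=None) -> tuple[float, bool]:
    """(criterion ratio, singular flag) for an efficiency computation."""
    if subset is None:
        num, den = d_criterion(M), d_criterion(M_opt)
    else:
        den = ds_criterion(M_opt, subset)
        try:
            num = ds_criterion(M, subset)
        except SingularDesignError:
            return 0.0, True
    if den <= 0.0:
        raise SingularDesignError("reference optimum has a singular information matrix")
    if num <= max(0.0, den * 1e-14):
        return 0.0, True
    return num / den, False


def d_efficiency(
    design: ApproximateDesign,
    reference: ApproximateDesign,
    model: str,
    theta,
    scale: str = "standard",
) -> float:
    """D-efficiency (det M(xi) / det M(xi*)) ** (1/m), 0 for singular designs."""
    M = fim(design, model, theta, scale)
    M_opt = fim(reference, model, theta, scale)
    ratio, singular = _rel_criterion(M, M_opt)
    return 0.0 if singular else float(ratio ** (1.0 / M.shape[0]))


def ds_efficiency(
    design: ApproximateDesign,
    reference: ApproximateDesign,
    model: str,
    theta,
    subset,
    scale: str = "standard",
) -> float:
    """Ds-efficiency with exponent 1/s; 0 for designs singular in the subset."""
    M = fim(design, model, theta, scale)
    M_opt = fim(reference, model, theta, scale)
    ratio, singular = _rel_criterion(M, M_opt, subset)
    s = np.atleast_1d(np.asarray(subset, int)).size
    return 0.0 if singular else float(ratio ** (1.0 / s))


def _psi(F: np.ndarray, M: np.ndarray, subset=None) -> np.ndarray:
    """Sensitivity function over the rows of F."""
    m = M.shape[0]
    Minv = np.linalg.inv(M)
    psi = np.einsum("ij,jk,ik->i", F, Minv, F)
    if subset is None:
        return psi
    _, nuisance = _split(subset, m)
    if nuisance.size == 0:
        return psi
    F2 = F[:, nuisance]
    M22inv = np.linalg.inv(M[np.ix_(nuisance, nuisance)])
    return psi - np.einsum("ij,jk,ik->i", F2, M22inv, F2)


def sensitivity_d(design: ApproximateDesign, model: str, theta, x, scale="standard") -> np.ndarray:
    """psi(x) = f(x)^T M^{-1} f(x) at the given point(s)."""
    M = fim(design, model, theta, scale)
    if np.linalg.det(M) <= 0.0:
        raise SingularDesignError("sensitivity undefined for a singular design")
    pts = np.atleast_2d(np.asarray(x, float))
    return _psi(_grad_matrix(pts, model, theta, scale), M)


def sensitivity_ds(design, model, theta, x, subset, scale="standard") -> np.ndarray:
    M = fim(design, model, theta, scale)
    pts = np.atleast_2d(np.asarray(x, float))
    return _psi(_grad_matrix(pts, model, theta, scale), M, subset)


def equivalence_check(
    design: ApproximateDesign,
    grid: GridSpec,
    model: str,
    theta,
    scale: str = "standard",
    subset=None,
    tol: float = 1e-4,
) -> dict:
    """Equivalence-theorem certificate of (D or Ds) optimality on a grid.

    Returns a dict with the sensitivity bound (m or s), the maximum of the
    sensitivity function over the grid and the design's support, the relative
    gap (max - bound) / bound, and ``ok`` (gap <= tol).
    """
    m = models.n_params(model)
    bound = m if subset is None else np.atleast_1d(np.asarray(subset, int)).size
    M = fim(design, model, theta, scale)
    pts = grid.points()
    if scale == "log":
        pts = pts[pts[:, 0] > 0.0]
    psi_grid = _psi(_grad_matrix(pts, model, theta, scale), M, subset)
    psi_supp = _psi(_grad_matrix(design.points, model, theta, scale), M, subset)
    k = int(np.argmax(psi_grid))
    gap = (max(psi_grid.max(), psi_supp.max()) - bound) / bound
    return {
        "bound": float(bound),
        "max_grid": float(psi_grid.max()),
        "max_support": float(psi_supp.max()),
        "worst_point": pts[k].copy(),
        "gap": float(gap),
        "ok": bool(gap <= tol),
    }


# --------------------------------------------------------------------------- #
# optimisation: multiplicative algorithm + merge + continuous refinement
# --------------------------------------------------------------------------- #


def _multiplicative(F: np.ndarray, bound: int, subset, m: int, n_iter: int):
    """Titterington-style multiplicative weight updates on the candidate set.

    Returns (active candidate indices, weights).  Candidates whose weight
    decays below a hard floor are dropped along the way to keep the active
    set small; the update w_i <- w_i * psi_i / bound preserves the total
    weight because the design-average of the sensitivity equals the bound.
    """
    n = F.shape[0]
    active = np.arange(n)
    w = np.full(n, 1.0 / n)
    Fa = F
    for it in range(n_iter):
        M = Fa.T @ (w[:, None] * Fa)
        try:
            psi = _psi(Fa, M, subset)
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            break
        psi = np.maximum(psi, 0.0)
        w = w * psi / bound
        w /= w.sum()
        if it % 25 == 24:
            keep = w > 1e-10
            if keep.sum() >= m and not keep.all():
                active, w, Fa = active[keep], w[keep], Fa[keep]
                w /= w.sum()
    return active, w


def _merge_clusters(points: np.ndarray, weights: np.ndarray, radius: tuple[float, float]):
    """Greedy weighted merge of support points within one grid step."""
    order = np.argsort(weights)[::-1]
    cpts: list[np.ndarray] = []
    cw: list[float] = []
    for i in order:
        p, w = points[i], weights[i]
        for j, c in enumerate(cpts):
            if abs(p[0] - c[0]) <= radius[0] + 1e-9 and abs(p[1] - c[1]) <= radius[1] + 1e-9:
                tot = cw[j] + w
                cpts[j] = (c * cw[j] + p * w) / tot
                cw[j] = tot
                break
        else:
            cpts.append(p.copy())
            cw.append(float(w))
    pts = np.array(cpts)
    w = np.array(cw)
    w /= w.sum()
    return pts, w


def _grad_matrix_dx(points, model, theta, scale, step=1e-6):
    """d f / d x_S and d f / d x_I by central differences on the analytic f."""
    def f(pts):
        return _grad_matrix(pts, model, theta, scale)

    es = np.array([step, 0.0])
    ei = np.array([0.0, step])
    dfs = (f(points + es) - f(points - es)) / (2 * step)
    dfi = (f(points + ei) - f(points - ei)) / (2 * step)
    return dfs, dfi


def _refine(points, weights, model, theta, scale, subset, bounds, maxiter=400):
    """Jointly maximise the (log) criterion over support coordinates and weights.

    SLSQP with analytic gradients: d logdet M / d w_i is the sensitivity
    psi(x_i); d logdet M / d x_i = 2 w_i f(x_i)^T M^{-1} df(x_i)/dx (and the
    analogous nuisance-block terms for the Ds-criterion).
    """
    n = points.shape[0]
    m = models.n_params(model)
    (s_lo, s_hi), (i_lo, i_hi) = bounds
    if subset is not None:
        _, nuisance = _split(subset, m)
    else:
        nuisance = np.array([], dtype=int)

    def unpack(z):
        return z[: 2 * n].reshape(n, 2), z[2 * n :]

    def eval_all(z):
        pts, w = unpack(z)
        w = np.maximum(w, 0.0)
        try:
            F = _grad_matrix(pts, model, theta, scale)
        except models.DomainError:
            return 1e12, np.zeros_like(z)
        M = F.T @ (w[:, None] * F)
        sign, logdet = np.linalg.slogdet(M)
        if sign <= 0:
            return 1e12, np.zeros_like(z)
        Minv = np.linalg.inv(M)
        val = logdet
        dw = np.einsum("ij,jk,ik->i", F, Minv, F)
        dfs, dfi = _grad_matrix_dx(pts, model, theta, scale)
        dx_s = 2 * w * np.einsum("ij,jk,ik->i", F, Minv, dfs)
        dx_i = 2 * w * np.einsum("ij,jk,ik->i", F, Minv, dfi)
        if nuisance.size:
            M22 = M[np.ix_(nuisance, nuisance)]
            s2, l2 = np.linalg.slogdet(M22)
            if s2 <= 0:
                return 1e12, np.zeros_like(z)
            val = logdet - l2
            M22inv = np.linalg.inv(M22)
            F2 = F[:, nuisance]
            dw = dw - np.einsum("ij,jk,ik->i", F2, M22inv, F2)
            dx_s = dx_s - 2 * w * np.einsum(
                "ij,jk,ik->i", F2, M22inv, dfs[:, nuisance]
            )
            dx_i = dx_i - 2 * w * np.einsum(
                "ij,jk,ik->i", F2, M22inv, dfi[:, nuisance]
            )
        grad = np.concatenate([np.column_stack([dx_s, dx_i]).ravel(), dw])
        return -val, -grad

    var_bounds = [(s_lo, s_hi), (i_lo, i_hi)] * n + [(0.0, 1.0)] * n
    z0 = np.concatenate([points.ravel(), weights])
    res = minimize(
        eval_all, z0, jac=True, method="SLSQP", bounds=var_bounds,
        constraints=[{"type": "eq", "fun": lambda z: z[2 * n :].sum() - 1.0,
                      "jac": lambda z: np.concatenate([np.zeros(2 * n), np.ones(n)])}],
        options={"maxiter": maxiter, "ftol": 1e-14},
    )
    pts, w = unpack(res.x if eval_all(res.x)[0] <= eval_all(z0)[0] else z0)
    w = np.maximum(w, 0.0)
    w /= w.sum()
    return pts, w


def _optimize_info(
    grid: GridSpec,
    model: str,
    theta,
    scale: str,
    subset=None,
    n_mult_iter: int = 600,
    prune_tol: float = 1e-6,
    eq_tol: float = 1e-4,
    refine: bool | None = None,
    max_rounds: int = 12,
) -> ApproximateDesign:
    theta = models.validate_theta(model, theta)
    m = models.n_params(model)
    bound = m if subset is None else np.atleast_1d(np.asarray(subset, int)).size
    pts_all = grid.points()
    if scale == "log":
        pts_all = pts_all[pts_all[:, 0] > 0.0]
    F_all = _grad_matrix(pts_all, model, theta, scale)
    # drop informationless candidates (x_S = 0 has a zero gradient row)
    keep = np.linalg.norm(F_all, axis=1) > 0.0
    pts_all, F_all = pts_all[keep], F_all[keep]

    active, w = _multiplicative(F_all, bound, subset, m, n_mult_iter)
    pts, w = pts_all[active], w
    sel = w > max(prune_tol, 1e-8)
    pts, w = pts[sel], w[sel] / w[sel].sum()
    # aggressive merge/prune keeps the refinement problem small; support
    # dropped by mistake is restored by the equivalence loop below
    pts, w = _merge_clusters(pts, w, (5 * grid.steps[0], 5 * grid.steps[1]))
    sel = w > 1e-4
    pts, w = pts[sel], w[sel] / w[sel].sum()

    if refine is None:
        refine = True
    for _ in range(max_rounds):
        if refine:
            pts, w = _refine(pts, w, model, theta, scale, subset, grid.bounds)
            # merge near-duplicates created by refinement, then re-normalise
            pts, w = _merge_clusters(pts, w, (grid.steps[0] / 2, grid.steps[1] / 2))
            sel = w > prune_tol
            pts, w = pts[sel], w[sel] / w[sel].sum()
        design = ApproximateDesign(pts, w)
        cert = equivalence_check(design, grid, model, theta, scale, subset, eq_tol)
        if cert["ok"]:
            return design
        # add the worst grid point and re-optimise
        pts = np.vstack([pts, cert["worst_point"]])
        w = np.concatenate([w * (1 - 1e-3), [1e-3]])
        if not refine:
            refine = True
    raise ConvergenceError(
        f"equivalence check failed after {max_rounds} refinement rounds; "
        f"sensitivity gap {cert['gap']:.3g} (tolerance {eq_tol})"
    )


def optimize_d(
    grid: GridSpec, model: str, theta, scale: str = "standard", **kwargs
) -> ApproximateDesign:
    """Locally D-optimal approximate design on the grid, certified by the
    equivalence theorem (support additionally refined off-grid)."""
    return _optimize_info(grid, model, theta, scale, subset=None, **kwargs)


def optimize_ds(
    grid: GridSpec, model: str, theta, subset, scale: str = "standard", **kwargs
) -> ApproximateDesign:
    """Locally Ds-optimal design for the parameters indexed by ``subset``."""
    subset_arr, nuisance = _split(subset, models.n_params(model))
    if nuisance.size == 0:
        return optimize_d(grid, model, theta, scale, **kwargs)
    return _optimize_info(grid, model, theta, scale, subset=subset_arr, **kwargs)


# --------------------------------------------------------------------------- #
# approximate -> exact rounding
# --------------------------------------------------------------------------- #


def round_design(design: ApproximateDesign, N: int) -> ExactDesign:
    """Largest-remainder apportionment of N runs to the design weights.

    Each count differs from N * w_i by less than one; support points that
    receive zero runs are dropped.
    """
    if N < 1:
        raise ValueError(f"N must be at least 1, got {N}")
    quota = N * design.weights
    base = np.floor(quota).astype(int)
    short = N - base.sum()
    remainder = quota - base
    # ties broken toward the larger weight, then lexicographically
    order = np.lexsort((np.arange(quota.size), -design.weights, -remainder))
    base[order[:short]] += 1
    keep = base > 0
    return ExactDesign(design.points[keep], base[keep])
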