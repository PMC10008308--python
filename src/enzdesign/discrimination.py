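"""T-, compound-T- and delta-optimal discriminating designs.

The discrimination problem is between the competitive and non-competitive
inhibition models (on either the standard or the log scale).

*T-optimality* assumes one model true with fixed nominal parameters and
maximises the lack-of-fit sum of squares of the rival model,

    Delta_0(xi) = inf_theta1 sum_i w_i (eta_0(x_i) - eta_1(theta1, x_i))^2,

found here by the Fedorov--Wynn vertex-direction algorithm on a candidate
grid with a final weight (and optionally support-coordinate) optimisation.
*CT-optimality* maximises the convex log-combination
(1 - nu) ln Delta_0 + nu ln Delta_1 of both discrimination directions.

*delta-optimality* is a symmetric criterion for exact N-run designs: both
models are linearised at nominal values and the criterion is the minimal
Euclidean distance between the two linear expectation surfaces with the
parameters confined to flexible nominal boxes (center +/- r * SE, clipped at
zero).  The inner problem is a bounded-variable linear least squares; the
outer maximisation over N-run designs uses a KL-exchange heuristic from a
random start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, lsq_linear, minimize

from . import models
from .fitting import ConvergenceError
from .designs import ApproximateDesign, ExactDesign, GridSpec, _merge_clusters

__all__ = [
    "TOptResult",
    "CTOptResult",
    "NominalBox",
    "DeltaSpec",
    "DegenerateDiscriminationError",
    "lack_of_fit",
    "t_optimal",
    "t_efficiency",
    "ct_optimal",
    "sensitivity_t",
    "nominal_box",
    "delta_value",
    "delta_optimal",
]

DEFAULT_RIVAL_BOUNDS = (1e-6, 1e4)


class DegenerateDiscriminationError(RuntimeError):
    """The rival model can interpolate the true one; the criterion is zero."""


@dataclass
class TOptResult:
    """A T-criterion evaluation or optimum."""

    design: ApproximateDesign
    delta: float  # lack-of-fit sum of squares Delta
    theta_rival: np.ndarray  # inner minimiser
    true_model: str
    theta_true: np.ndarray
    rival_model: str
    scale: str
    gap: float = np.nan  # relative equivalence gap (optimum only)


@dataclass
class CTOptResult:
    """A compound-T optimum between two discrimination directions."""

    design: ApproximateDesign
    nu: float
    delta0: float
    delta1: float
    delta0_star: float  # normalising T-optimum, direction 0
    delta1_star: float
    theta_rival0: np.ndarray
    theta_rival1: np.ndarray
    gap: float = np.nan

    @property
    def efficiency_product(self) -> float:
        return (self.delta0 / self.delta0_star) ** (1 - self.nu) * (
            self.delta1 / self.delta1_star
        ) ** self.nu


# --------------------------------------------------------------------------- #
# lack of fit (inner problem) and T-efficiency
# --------------------------------------------------------------------------- #


def _rival_fit(points, weights, resp0, rival_model, scale, bounds, starts, warm=None):
    """Minimise the weighted lack of fit over the rival parameters."""
    m = models.n_params(rival_model)
    lo = np.full(m, bounds[0])
    hi = np.full(m, bounds[1])
    if rival_model == "encompassing":
        lo[3], hi[3] = 0.0, 1.0
    sw = np.sqrt(weights)
    xs, xi = points[:, 0], points[:, 1]

    def resid(theta):
        return sw * (resp0 - models.response(rival_model, theta, xs, xi, scale))

    def jac(theta):
        return -sw[:, None] * models.response_gradient(rival_model, theta, xs, xi, scale)

    best = None
    cand = ([np.asarray(warm, float)] if warm is not None else []) + list(starts)
    for start in cand:
        start = np.clip(start, lo + 1e-12, hi)
        try:
            sol = least_squares(resid, start, jac=jac, bounds=(lo, hi), method="trf",
                                xtol=1e-13, ftol=1e-13, gtol=1e-12)
        except Exception:
            continue
        if sol.status > 0 and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise ConvergenceError("inner lack-of-fit minimisation failed on all starts")
    return best.x, float(2.0 * best.cost)


def _default_starts(rival_model, scale, n_starts, seed):
    """Deterministic multistart points: built-in nominals plus log-uniform draws."""
    from .nominals import NOMINAL

    m = models.n_params(rival_model)
    rng = np.random.default_rng(seed)
    starts = []
    if (rival_model, scale) in NOMINAL:
        starts.append(NOMINAL[(rival_model, scale)].theta.copy())
    while len(starts) < n_starts:
        th = np.exp(rng.uniform(np.log(0.1), np.log(100.0), size=m))
        if rival_model == "encompassing":
            th[3] = rng.uniform()
        starts.append(th)
    return starts


def lack_of_fit(
    design: ApproximateDesign,
    true_model: str,
    theta_true,
    rival_model: str,
    scale: str = "standard",
    rival_bounds=DEFAULT_RIVAL_BOUNDS,
    n_starts: int = 10,
    seed: int = 0,
) -> TOptResult:
    """Lack-of-fit sum of squares Delta of the rival model on a design.

    The inner minimisation over the rival parameters uses multistart
    box-constrained least squares (``n_starts`` starts).
    """
    theta_true = models.validate_theta(true_model, theta_true)
    resp0 = models.response(true_model, theta_true, design.points[:, 0],
                            design.points[:, 1], scale)
    starts = _default_starts(rival_model, scale, n_starts, seed)
    th1, delta = _rival_fit(design.points, design.weights, resp0, rival_model,
                            scale, rival_bounds, starts)
    return TOptResult(design=design, delta=delta, theta_rival=th1,
                      true_model=true_model, theta_true=np.asarray(theta_true, float),
                      rival_model=rival_model, scale=scale)


def t_efficiency(design: ApproximateDesign, reference: TOptResult, **kwargs) -> float:
    """T-efficiency Delta(xi) / Delta(xi*) under the reference's criterion."""
    if not reference.delta > 0.0:
        raise ValueError("reference T-optimum has zero lack of fit")
    val = lack_of_fit(design, reference.true_model, reference.theta_true,
                      reference.rival_model, reference.scale, **kwargs)
    return val.delta / reference.delta


def sensitivity_t(result: TOptResult, x) -> np.ndarray:
    """psi(x) = (eta_0(x) - eta_1(theta_hat_1, x))^2 at the given point(s).

    At a T-optimum the maximum over the design region equals Delta and is
    attained on the support.
    """
    pts = np.atleast_2d(np.asarray(x, float))
    r0 = models.response(result.true_model, result.theta_true, pts[:, 0], pts[:, 1],
                         result.scale)
    r1 = models.response(result.rival_model, result.theta_rival, pts[:, 0], pts[:, 1],
                         result.scale)
    return (r0 - r1) ** 2


# --------------------------------------------------------------------------- #
# Fedorov-Wynn with support polishing (T and CT)
# --------------------------------------------------------------------------- #


def _grid_candidates(grid: GridSpec, scale: str) -> np.ndarray:
    pts = grid.points()
    if scale == "log":
        pts = pts[pts[:, 0] > 0.0]
    return pts


def _initial_support(grid: GridSpec, scale: str) -> np.ndarray:
    """A coarse lattice over the region as the starting measure."""
    s = grid.substrate
    i = grid.inhibitor
    s_lev = np.unique(s[np.round(np.linspace(0, s.size - 1, 4)).astype(int)])
    i_lev = np.unique(i[np.round(np.linspace(0, i.size - 1, 4)).astype(int)])
    if scale == "log":
        s_lev = s_lev[s_lev > 0.0]
    ss, ii = np.meshgrid(s_lev, i_lev, indexing="ij")
    return np.column_stack([ss.ravel(), ii.ravel()])


def _weight_polish_t(points, w0, resp0, rival_model, scale, bounds, warm, starts):
    """Maximise Delta over the weights on a fixed support (envelope gradient)."""
    n = w0.size
    state = {"theta": warm}

    def negobj(w):
        w = np.maximum(w, 0.0)
        th, delta = _rival_fit(points, w, resp0, rival_model, scale, bounds,
                               starts[:2], warm=state["theta"])
        state["theta"] = th
        r = resp0 - models.response(rival_model, th, points[:, 0], points[:, 1], scale)
        return -delta, -(r**2)

    res = minimize(
        negobj, w0, jac=True, method="SLSQP", bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 300, "ftol": 1e-12},
    )
    w = np.maximum(res.x, 0.0)
    w /= w.sum()
    return w, state["theta"]


def t_optimal(
    grid: GridSpec,
    true_model: str,
    theta_true,
    rival_model: str,
    scale: str = "standard",
    max_iter: int = 300,
    gap_tol: float = 1e-4,
    rival_bounds=DEFAULT_RIVAL_BOUNDS,
    n_starts: int = 10,
    seed: int = 0,
    prune_tol: float = 1e-5,
    refine_points: bool | None = None,
) -> TOptResult:
    """T-optimal approximate design by the Fedorov--Wynn algorithm.

    At step k the rival parameters are refitted, mass ``1/(k+1)`` is moved to
    the grid point with the largest squared model separation, and weights
    below ``prune_tol`` are dropped.  Iteration stops at ``max_iter`` or when
    the relative sensitivity gap falls below ``gap_tol``; the final support is
    cluster-merged and its weights re-optimised (support coordinates are also
    polished off-grid for the standard scale, where optima are interior).

    Raises :class:`DegenerateDiscriminationError` when the rival model can
    match the true one (Delta stays at zero).
    """
    theta_true = models.validate_theta(true_model, theta_true)
    cand = _grid_candidates(grid, scale)
    resp0_grid = models.response(true_model, theta_true, cand[:, 0], cand[:, 1], scale)
    starts = _default_starts(rival_model, scale, n_starts, seed)
    if refine_points is None:
        refine_points = scale == "standard"

    pts = _initial_support(grid, scale)
    w = np.full(pts.shape[0], 1.0 / pts.shape[0])
    resp0 = models.response(true_model, theta_true, pts[:, 0], pts[:, 1], scale)
    th1, delta = _rival_fit(pts, w, resp0, rival_model, scale, rival_bounds, starts)

    for k in range(1, max_iter + 1):
        r1_grid = models.response(rival_model, th1, cand[:, 0], cand[:, 1], scale)
        psi = (resp0_grid - r1_grid) ** 2
        j = int(np.argmax(psi))
        if delta <= 1e-12 * max(1.0, float(psi[j])) and psi[j] <= 1e-10:
            raise DegenerateDiscriminationError(
                f"{rival_model} interpolates {true_model} on the region; "
                "the T-criterion is identically zero"
            )
        gap = (psi[j] - delta) / max(delta, 1e-300)
        if gap <= gap_tol:
            break
        alpha = 1.0 / (k + 1.0)
        w *= 1.0 - alpha
        match = np.flatnonzero((pts[:, 0] == cand[j, 0]) & (pts[:, 1] == cand[j, 1]))
        if match.size:
            w[match[0]] += alpha
        else:
            pts = np.vstack([pts, cand[j]])
            w = np.append(w, alpha)
        keep = w > prune_tol
        pts, w = pts[keep], w[keep] / w[keep].sum()
        resp0 = models.response(true_model, theta_true, pts[:, 0], pts[:, 1], scale)
        th1, delta = _rival_fit(pts, w, resp0, rival_model, scale, rival_bounds,
                                starts[:1], warm=th1)
        if delta <= 1e-14 and k > 50:
            raise DegenerateDiscriminationError(
                f"{rival_model} interpolates {true_model}; T-criterion is zero"
            )

    # polish: merge support, re-optimise weights, certify; add violators
    for _ in range(25):
        pts, w = _merge_clusters(pts, w, grid.steps)
        resp0 = models.response(true_model, theta_true, pts[:, 0], pts[:, 1], scale)
        w, th1 = _weight_polish_t(pts, w, resp0, rival_model, scale, rival_bounds,
                                  th1, starts)
        keep = w > prune_tol
        pts, w = pts[keep], w[keep] / w[keep].sum()
        if refine_points:
            pts, w, th1 = _support_polish_t(pts, w, true_model, theta_true,
                                            rival_model, scale, th1, starts,
                                            grid.bounds, rival_bounds)
        resp0 = models.response(true_model, theta_true, pts[:, 0], pts[:, 1], scale)
        th1, delta = _rival_fit(pts, w, resp0, rival_model, scale, rival_bounds,
                                starts, warm=th1)
        r1_grid = models.response(rival_model, th1, cand[:, 0], cand[:, 1], scale)
        psi = (resp0_grid - r1_grid) ** 2
        j = int(np.argmax(psi))
        gap = (psi[j] - delta) / max(delta, 1e-300)
        if gap <= gap_tol:
            design = ApproximateDesign(pts, w)
            return TOptResult(design=design, delta=delta, theta_rival=th1,
                              true_model=true_model, theta_true=theta_true,
                              rival_model=rival_model, scale=scale, gap=float(gap))
        pts = np.vstack([pts, cand[j]])
        w = np.append(w * (1 - 1e-3), 1e-3)
    raise ConvergenceError(
        f"Fedorov-Wynn did not reach sensitivity gap {gap_tol}; last gap {gap:.3g}"
    )


def _support_polish_t(points, w, true_model, theta_true, rival_model, scale,
                      warm, starts, bounds, rival_bounds=DEFAULT_RIVAL_BOUNDS):
    """Continuous polish of support coordinates and weights (envelope gradient
    in the weights, finite differences in the coordinates)."""
    n = points.shape[0]
    (s_lo, s_hi), (i_lo, i_hi) = bounds
    state = {"theta": warm}

    def negobj(z):
        pts = z[: 2 * n].reshape(n, 2)
        ww = np.maximum(z[2 * n :], 0.0)
        tot = ww.sum()
        if tot <= 0:
            return 1e12
        ww = ww / tot
        resp0 = models.response(true_model, theta_true, pts[:, 0], pts[:, 1], scale)
        th, delta = _rival_fit(pts, ww, resp0, rival_model, scale, rival_bounds,
                               starts[:1], warm=state["theta"])
        state["theta"] = th
        return -delta

    var_bounds = [(s_lo, s_hi), (i_lo, i_hi)] * n + [(0.0, 1.0)] * n
    z0 = np.concatenate([points.ravel(), w])
    res = minimize(
        negobj, z0, method="SLSQP", bounds=var_bounds,
        constraints=[{"type": "eq", "fun": lambda z: z[2 * n :].sum() - 1.0}],
        options={"maxiter": 120, "ftol": 1e-12},
    )
    z = res.x if negobj(res.x) <= negobj(z0) else z0
    pts = z[: 2 * n].reshape(n, 2)
    ww = np.maximum(z[2 * n :], 0.0)
    ww /= ww.sum()
    return pts, ww, state["theta"]


def ct_optimal(
    grid: GridSpec,
    model_pair: tuple[str, str],
    theta_pair,
    nu: float,
    scale: str = "standard",
    max_iter: int = 300,
    gap_tol: float = 1e-4,
    rival_bounds=DEFAULT_RIVAL_BOUNDS,
    n_starts: int = 10,
    seed: int = 0,
    prune_tol: float = 1e-5,
    refine_points: bool | None = None,
) -> CTOptResult:
    """Compound-T optimal design maximising (1-nu) ln Delta_0 + nu ln Delta_1.

    Direction 0 treats ``model_pair[0]`` as true (rival ``model_pair[1]``),
    direction 1 the reverse.  The two pure T-optima are computed first as
    normalisers; ``nu`` = 0 or 1 reproduces them.
    """
    if not 0.0 <= nu <= 1.0:
        raise ValueError(f"nu must lie in [0, 1], got {nu}")
    m0, m1 = model_pair
    th0, th1n = (models.validate_theta(m0, theta_pair[0]),
                 models.validate_theta(m1, theta_pair[1]))
    common = dict(scale=scale, max_iter=max_iter, gap_tol=gap_tol,
                  rival_bounds=rival_bounds, n_starts=n_starts, seed=seed,
                  prune_tol=prune_tol, refine_points=refine_points)
    ref0 = t_optimal(grid, m0, th0, m1, **common)
    ref1 = t_optimal(grid, m1, th1n, m0, **common)
    if nu == 0.0:
        return CTOptResult(design=ref0.design, nu=nu, delta0=ref0.delta,
                           delta1=lack_of_fit(ref0.design, m1, th1n, m0, scale,
                                              rival_bounds, n_starts, seed).delta,
                           delta0_star=ref0.delta, delta1_star=ref1.delta,
                           theta_rival0=ref0.theta_rival,
                           theta_rival1=ref1.theta_rival, gap=ref0.gap)
    if nu == 1.0:
        return CTOptResult(design=ref1.design, nu=nu,
                           delta0=lack_of_fit(ref1.design, m0, th0, m1, scale,
                                              rival_bounds, n_starts, seed).delta,
                           delta1=ref1.delta,
                           delta0_star=ref0.delta, delta1_star=ref1.delta,
                           theta_rival0=ref0.theta_rival,
                           theta_rival1=ref1.theta_rival, gap=ref1.gap)

    cand = _grid_candidates(grid, scale)
    r0_grid = models.response(m0, th0, cand[:, 0], cand[:, 1], scale)
    r1_grid = models.response(m1, th1n, cand[:, 0], cand[:, 1], scale)
    starts0 = _default_starts(m1, scale, n_starts, seed)
    starts1 = _default_starts(m0, scale, n_starts, seed + 1)
    if refine_points is None:
        refine_points = scale == "standard"

    pts = _initial_support(grid, scale)
    w = np.full(pts.shape[0], 1.0 / pts.shape[0])

    def inner(pts, w, warm0=None, warm1=None, full=False):
        resp0 = models.response(m0, th0, pts[:, 0], pts[:, 1], scale)
        resp1 = models.response(m1, th1n, pts[:, 0], pts[:, 1], scale)
        s0 = starts0 if full else starts0[:1]
        s1 = starts1 if full else starts1[:1]
        a, d0 = _rival_fit(pts, w, resp0, m1, scale, rival_bounds, s0, warm=warm0)
        b, d1 = _rival_fit(pts, w, resp1, m0, scale, rival_bounds, s1, warm=warm1)
        return a, d0, b, d1

    ra, d0, rb, d1 = inner(pts, w, full=True)

    def composite(ra, rb, d0, d1):
        psi0 = (r0_grid - models.response(m1, ra, cand[:, 0], cand[:, 1], scale)) ** 2
        psi1 = (r1_grid - models.response(m0, rb, cand[:, 0], cand[:, 1], scale)) ** 2
        return (1 - nu) * psi0 / d0 + nu * psi1 / d1

    for k in range(1, max_iter + 1):
        phi = composite(ra, rb, d0, d1)
        j = int(np.argmax(phi))
        gap = phi[j] - 1.0
        if gap <= gap_tol:
            break
        alpha = 1.0 / (k + 1.0)
        w *= 1.0 - alpha
        match = np.flatnonzero((pts[:, 0] == cand[j, 0]) & (pts[:, 1] == cand[j, 1]))
        if match.size:
            w[match[0]] += alpha
        else:
            pts = np.vstack([pts, cand[j]])
            w = np.append(w, alpha)
        keep = w > prune_tol
        pts, w = pts[keep], w[keep] / w[keep].sum()
        ra, d0, rb, d1 = inner(pts, w, ra, rb)

    def weight_polish(pts, w, ra, rb):
        n = w.size
        resp0 = models.response(m0, th0, pts[:, 0], pts[:, 1], scale)
        resp1 = models.response(m1, th1n, pts[:, 0], pts[:, 1], scale)
        state = {"a": ra, "b": rb}

        def negobj(ww):
            ww = np.maximum(ww, 0.0)
            a, d0 = _rival_fit(pts, ww, resp0, m1, scale, rival_bounds,
                               starts0[:1], warm=state["a"])
            b, d1 = _rival_fit(pts, ww, resp1, m0, scale, rival_bounds,
                               starts1[:1], warm=state["b"])
            state["a"], state["b"] = a, b
            e0 = resp0 - models.response(m1, a, pts[:, 0], pts[:, 1], scale)
            e1 = resp1 - models.response(m0, b, pts[:, 0], pts[:, 1], scale)
            g = (1 - nu) * e0**2 / d0 + nu * e1**2 / d1
            return -((1 - nu) * np.log(d0) + nu * np.log(d1)), -g

        res = minimize(negobj, w, jac=True, method="SLSQP",
                       bounds=[(0.0, 1.0)] * n,
                       constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0}],
                       options={"maxiter": 300, "ftol": 1e-13})
        ww = np.maximum(res.x, 0.0)
        return ww / ww.sum(), state["a"], state["b"]

    for _ in range(25):
        pts, w = _merge_clusters(pts, w, grid.steps)
        w, ra, rb = weight_polish(pts, w, ra, rb)
        keep = w > prune_tol
        pts, w = pts[keep], w[keep] / w[keep].sum()
        if refine_points:
            pts, w = _support_polish_ct(pts, w, m0, th0, m1, th1n, nu, scale,
                                        rival_bounds, starts0, starts1, grid.bounds)
        ra, d0, rb, d1 = inner(pts, w, ra, rb, full=True)
        phi = composite(ra, rb, d0, d1)
        j = int(np.argmax(phi))
        gap = float(phi[j] - 1.0)
        if gap <= gap_tol:
            return CTOptResult(design=ApproximateDesign(pts, w), nu=nu,
                               delta0=d0, delta1=d1, delta0_star=ref0.delta,
                               delta1_star=ref1.delta, theta_rival0=ra,
                               theta_rival1=rb, gap=gap)
        pts = np.vstack([pts, cand[j]])
        w = np.append(w * (1 - 1e-3), 1e-3)
    raise ConvergenceError(
        f"compound-T Fedorov-Wynn did not reach gap {gap_tol}; last gap {gap:.3g}"
    )


def _support_polish_ct(points, w, m0, th0, m1, th1n, nu, scale, rival_bounds,
                       starts0, starts1, bounds):
    n = points.shape[0]
    (s_lo, s_hi), (i_lo, i_hi) = bounds
    state = {"a": None, "b": None}

    def negobj(z):
        pts = z[: 2 * n].reshape(n, 2)
        ww = np.maximum(z[2 * n :], 0.0)
        tot = ww.sum()
        if tot <= 0:
            return 1e12
        ww = ww / tot
        resp0 = models.response(m0, th0, pts[:, 0], pts[:, 1], scale)
        resp1 = models.response(m1, th1n, pts[:, 0], pts[:, 1], scale)
        a, d0 = _rival_fit(pts, ww, resp0, m1, scale, rival_bounds, starts0[:1],
                           warm=state["a"])
        b, d1 = _rival_fit(pts, ww, resp1, m0, scale, rival_bounds, starts1[:1],
                           warm=state["b"])
        state["a"], state["b"] = a, b
        return -((1 - nu) * np.log(d0) + nu * np.log(d1))

    var_bounds = [(s_lo, s_hi), (i_lo, i_hi)] * n + [(0.0, 1.0)] * n
    z0 = np.concatenate([points.ravel(), w])
    res = minimize(negobj, z0, method="SLSQP", bounds=var_bounds,
                   constraints=[{"type": "eq", "fun": lambda z: z[2 * n :].sum() - 1.0}],
                   options={"maxiter": 120, "ftol": 1e-12})
    z = res.x if negobj(res.x) <= negobj(z0) else z0
    pts = z[: 2 * n].reshape(n, 2)
    ww = np.maximum(z[2 * n :], 0.0)
    return pts, ww / ww.sum()


# --------------------------------------------------------------------------- #
# delta-optimality (flexible nominal sets, exact designs)
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class NominalBox:
    """A flexible nominal set: a box [lower, upper] around a center."""

    center: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.center, float)
        lo = np.asarray(self.lower, float)
        hi = np.asarray(self.upper, float)
        if not (np.all(lo <= c + 1e-12) and np.all(c <= hi + 1e-12) and np.all(lo >= -1e-12)):
            raise ValueError("need 0 <= lower <= center <= upper")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)


@dataclass(frozen=True)
class DeltaSpec:
    """Specification of the delta-criterion: one nominal box per model."""

    models: tuple[str, str]
    boxes: tuple[NominalBox, NominalBox]
    scale: str = "log"
    r: float = np.nan  # tuning multiplier used to build the boxes (record only)
    alternative: str = "a"


def nominal_box(theta_hat, se, r: float, alternative: str = "a") -> NominalBox:
    """Build a flexible nominal box theta_hat +/- r * se.

    ``alternative='a'`` clips negative lower bounds at zero; ``'b'``
    additionally shifts the clipped amount onto the upper bound.
    """
    if r < 0:
        raise ValueError(f"r must be non-negative, got {r}")
    theta_hat = np.asarray(theta_hat, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    lo = theta_hat - r * se
    hi = theta_hat + r * se
    clipped = np.maximum(-lo, 0.0)
    lo = np.maximum(lo, 0.0)
    if alternative == "b":
        hi = hi + clipped
    elif alternative != "a":
        raise ValueError(f"alternative must be 'a' or 'b', got {alternative!r}")
    return NominalBox(center=theta_hat, lower=lo, upper=hi)


def _linearization(points, mult, model, box, scale):
    """Weighted linearisation rows F and offset a at the box center."""
    sw = np.sqrt(np.asarray(mult, float))
    F = models.response_gradient(model, box.center, points[:, 0], points[:, 1], scale)
    eta = models.response(model, box.center, points[:, 0], points[:, 1], scale)
    a = eta - F @ box.center
    return sw[:, None] * F, sw * a


def delta_value(design: ExactDesign, dspec: DeltaSpec) -> float:
    """The linearised distance delta(D) between the two model surfaces.

    delta^2 = min over theta in the boxes of
    ||(a_0 - a_1) - [-F_0, F_1] theta||^2, a bounded-variable linear least
    squares problem (replicated design points enter through row weights).
    """
    m0, m1 = dspec.models
    b0, b1 = dspec.boxes
    F0, a0 = _linearization(design.points, design.replicates, m0, b0, dspec.scale)
    F1, a1 = _linearization(design.points, design.replicates, m1, b1, dspec.scale)
    A = np.hstack([-F0, F1])
    b = a0 - a1
    lo = np.concatenate([b0.lower, b1.lower])
    hi = np.concatenate([b0.upper, b1.upper])
    free = hi - lo > 1e-13
    x = np.concatenate([b0.center, b1.center]).astype(float)
    if np.any(free):
        sol = lsq_linear(A[:, free], b - A[:, ~free] @ x[~free],
                         bounds=(lo[free], hi[free]), method="bvls")
        x[free] = sol.x
    resid = b - A @ x
    return float(np.sqrt(np.sum(resid**2)))


def delta_optimal(
    N: int,
    grid: GridSpec,
    dspec: DeltaSpec,
    seed: int,
    max_passes: int = 200,
) -> ExactDesign:
    """delta-optimal exact N-run design by the KL-exchange heuristic.

    Starts from a uniform random N-sample (with replacement) of the grid and
    repeatedly applies the best single-point exchange (remove one run from a
    support point, add one run at a grid candidate) until no exchange
    improves the criterion.  Deterministic given ``seed``.
    """
    if N < 1:
        raise ValueError(f"N must be at least 1, got {N}")
    cand = _grid_candidates(grid, dspec.scale)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, cand.shape[0], size=N)
    uniq, counts = np.unique(idx, return_counts=True)

    def make(uniq, counts):
        return ExactDesign(cand[uniq], counts)

    def key(uniq, counts):
        return tuple(sorted(zip(uniq.tolist(), counts.tolist())))

    current = make(uniq, counts)
    best_val = delta_value(current, dspec)
    for _ in range(max_passes):
        improved = False
        best_move = None
        for rm_pos in range(uniq.size):
            u2 = uniq.copy()
            c2 = counts.copy()
            c2[rm_pos] -= 1
            if c2[rm_pos] == 0:
                u2 = np.delete(u2, rm_pos)
                c2 = np.delete(c2, rm_pos)
            for j in range(cand.shape[0]):
                pos = np.searchsorted(u2, j)
                if pos < u2.size and u2[pos] == j:
                    u3, c3 = u2, c2.copy()
                    c3[pos] += 1
                else:
                    u3 = np.insert(u2, pos, j)
                    c3 = np.insert(c2, pos, 1)
                val = delta_value(make(u3, c3), dspec)
                if val > best_val + 1e-12:
                    best_val = val
                    best_move = (u3.copy(), c3.copy())
                    improved = True
        if not improved:
            break
        uniq, counts = best_move
    return make(uniq, counts)
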