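"""T/CT lack-of-fit machinery and delta-optimality."""

import numpy as np
import pytest
from scipy.optimize import minimize

from enzdesign import models
from enzdesign.designs import ApproximateDesign, ExactDesign, GridSpec
from enzdesign.discrimination import (
    DegenerateDiscriminationError,
    DeltaSpec,
    delta_optimal,
    delta_value,
    lack_of_fit,
    nominal_box,
    sensitivity_t,
    t_efficiency,
    t_optimal,
    ct_optimal,
)
from enzdesign.nominals import NOMINAL, nominal

NC_LOG = nominal("noncompetitive", "log").theta
C_LOG = nominal("competitive", "log").theta
CORNERS = np.array([[0.02, 0.0], [30.0, 0.0], [0.02, 60.0], [30.0, 60.0]])


def delta_spec(r, alt="a", models_pair=("competitive", "noncompetitive")):
    boxes = []
    for m in models_pair:
        est = NOMINAL[(m, "log")]
        boxes.append(nominal_box(est.theta, est.se, r, alt))
    return DeltaSpec(models=models_pair, boxes=tuple(boxes), scale="log",
                     r=r, alternative=alt)


class TestLackOfFit:
    def test_rival_equal_to_truth_gives_zero(self):
        d = ApproximateDesign(CORNERS, [0.25] * 4)
        res = lack_of_fit(d, "competitive", C_LOG, "competitive", "log")
        assert res.delta == pytest.approx(0.0, abs=1e-12)

    def test_one_point_design_always_interpolable(self):
        d = ApproximateDesign([[10.0, 5.0]], [1.0])
        res = lack_of_fit(d, "competitive", C_LOG, "noncompetitive", "log")
        assert res.delta == pytest.approx(0.0, abs=1e-10)

    def test_multistart_matches_dense_grid_search(self):
        d = ApproximateDesign(CORNERS, [0.1, 0.2, 0.3, 0.4])
        res = lack_of_fit(d, "noncompetitive", NC_LOG, "competitive", "log")
        # oracle: dense 3-D log-spaced grid over the rival parameters followed
        # by a Nelder-Mead polish, entirely independent of the trf path
        pts, w = d.points, d.weights
        resp0 = models.response("noncompetitive", NC_LOG, pts[:, 0],
                                pts[:, 1], "log")

        def sse(theta):
            if np.any(theta <= 0):
                return np.inf
            r = resp0 - models.response("competitive", theta, pts[:, 0],
                                        pts[:, 1], "log")
            return float(np.sum(w * r**2))

        axis = np.exp(np.linspace(np.log(0.05), np.log(500.0), 45))
        best, argbest = np.inf, None
        for V in axis:
            r_v = resp0 - (np.log(V) + np.log(pts[:, 0]))
            for M in axis:
                num = np.log(M * (1 + pts[:, 1][:, None] / axis[None, :])
                             + pts[:, 0][:, None])
                vals = np.sum(w[:, None] * (r_v[:, None] + num) ** 2, axis=0)
                j = int(np.argmin(vals))
                if vals[j] < best:
                    best, argbest = vals[j], np.array([V, M, axis[j]])
        polish = minimize(sse, argbest, method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
        assert res.delta == pytest.approx(polish.fun, abs=1e-6)


class TestTOptimal:
    def test_log_noncompetitive_true_reproduces_reference_weights(self, log_t_optima):
        d = log_t_optima["A1"].design
        assert d.n == 4
        expected = {(0.02, 0.0): 0.0095, (30.0, 0.0): 0.1402,
                    (0.02, 60.0): 0.3600, (30.0, 60.0): 0.4903}
        for p, w in zip(d.points, d.weights):
            assert w == pytest.approx(expected[tuple(p)], abs=0.01)

    def test_rival_same_family_degenerates(self, log_grid):
        with pytest.raises(DegenerateDiscriminationError):
            t_optimal(log_grid, "competitive", C_LOG, "competitive", "log")

    def test_standard_competitive_true_support(self, std_t_optima):
        pts = std_t_optima["T1"].design.points
        for target in ((3.080, 0.0), (5.491, 11.598)):
            dist = np.min(np.abs(pts - np.array(target)).max(axis=1))
            assert dist <= 0.1

    def test_optimum_is_its_own_reference(self, log_t_optima):
        ref = log_t_optima["A4"]
        assert t_efficiency(ref.design, ref) == pytest.approx(1.0, abs=1e-6)


class TestSensitivityT:
    def test_weighted_average_equals_delta(self, log_t_optima):
        res = log_t_optima["A1"]
        psi = sensitivity_t(res, res.design.points)
        assert float(np.sum(res.design.weights * psi)) == pytest.approx(
            res.delta, rel=1e-8
        )

    def test_max_attained_on_support_at_optimum(self, log_t_optima, log_grid):
        res = log_t_optima["A4"]
        psi_grid = sensitivity_t(res, log_grid.points()[log_grid.points()[:, 0] > 0])
        psi_supp = sensitivity_t(res, res.design.points)
        assert psi_grid.max() <= psi_supp.max() * (1 + 1e-3)

    def test_nonoptimal_design_max_exceeds_average(self):
        d = ApproximateDesign(CORNERS, [0.7, 0.1, 0.1, 0.1])
        res = lack_of_fit(d, "noncompetitive", NC_LOG, "competitive", "log")
        psi = sensitivity_t(res, d.points)
        assert psi.max() > np.sum(d.weights * psi) + 1e-6


class TestCTOptimal:
    def test_nu_zero_and_one_reproduce_pure_t_optima(self, log_grid, log_t_optima):
        ct0 = ct_optimal(log_grid, ("noncompetitive", "competitive"),
                         (NC_LOG, C_LOG), nu=0.0, scale="log")
        assert ct0.delta0 == pytest.approx(log_t_optima["A1"].delta, rel=1e-6)
        ct1 = ct_optimal(log_grid, ("noncompetitive", "competitive"),
                         (NC_LOG, C_LOG), nu=1.0, scale="log")
        assert ct1.delta1 == pytest.approx(log_t_optima["A4"].delta, rel=1e-6)

    def test_log_half_weights_match_reference(self, log_ct_optimum):
        d = log_ct_optimum.design
        expected = {(0.02, 0.0): 0.1688, (30.0, 0.0): 0.1818,
                    (0.02, 60.0): 0.3002, (30.0, 60.0): 0.3492}
        for p, w in zip(d.points, d.weights):
            assert w == pytest.approx(expected[tuple(p)], abs=0.01)

    def test_compound_criterion_beats_both_pure_optima(self, log_ct_optimum,
                                                       log_t_optima):
        # the CT optimum maximises the weighted log-criterion, so its value is
        # at least that of either pure T-optimal design
        nu = log_ct_optimum.nu

        def phi(d0, d1):
            return (1 - nu) * np.log(d0) + nu * np.log(d1)

        a1, a4 = log_t_optima["A1"], log_t_optima["A4"]
        d0_a1 = a1.delta
        d1_a1 = lack_of_fit(a1.design, "competitive", C_LOG, "noncompetitive",
                            "log").delta
        d0_a4 = lack_of_fit(a4.design, "noncompetitive", NC_LOG, "competitive",
                            "log").delta
        d1_a4 = a4.delta
        ct = phi(log_ct_optimum.delta0, log_ct_optimum.delta1)
        assert ct >= phi(d0_a1, d1_a1) - 1e-9
        assert ct >= phi(d0_a4, d1_a4) - 1e-9


class TestNominalBox:
    def test_degenerate_box_at_r_zero(self):
        b = nominal_box([3.0, 2.0], [0.5, 0.4], 0.0)
        np.testing.assert_allclose(b.lower, b.center)
        np.testing.assert_allclose(b.upper, b.center)

    def test_alternative_a_clips_at_zero(self):
        b = nominal_box([3.2799], [0.7288], 5.0, "a")
        assert b.lower[0] == 0.0
        assert b.upper[0] == pytest.approx(6.9239)

    def test_alternative_b_shifts_clipped_mass_upward(self):
        b = nominal_box([3.2799], [0.7288], 5.0, "b")
        assert b.lower[0] == 0.0
        assert b.upper[0] == pytest.approx(6.9239 + (5 * 0.7288 - 3.2799))


class TestDeltaValue:
    def test_identical_models_and_boxes_give_zero(self):
        spec = delta_spec(1.0, models_pair=("competitive", "competitive"))
        d = ExactDesign(CORNERS, [2, 2, 1, 1])
        assert delta_value(d, spec) == pytest.approx(0.0, abs=1e-10)

    def test_monotone_nonincreasing_in_r(self):
        d = ExactDesign([[0.02, 0.0], [30.0, 0.0], [30.0, 60.0]], [2, 2, 2])
        vals = [delta_value(d, delta_spec(r)) for r in (0, 1, 2, 3, 4, 5)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_r_zero_is_fixed_nominal_linearised_distance(self):
        spec = delta_spec(0.0)
        d = ExactDesign(CORNERS, [1, 2, 2, 1])
        # with degenerate boxes the criterion is the plain distance between
        # the two model responses at the nominal centers
        r0 = models.response("competitive", C_LOG, d.points[:, 0], d.points[:, 1],
                             "log")
        r1 = models.response("noncompetitive", NC_LOG, d.points[:, 0],
                             d.points[:, 1], "log")
        direct = np.sqrt(np.sum(d.replicates * (r0 - r1) ** 2))
        assert delta_value(d, spec) == pytest.approx(direct, rel=1e-10)

    def test_solver_matches_dense_box_grid_oracle(self):
        spec = delta_spec(1.0)
        d = ExactDesign([[0.02, 0.0], [30.0, 0.0], [30.0, 60.0]], [1, 1, 1])
        got = delta_value(d, spec)
        # oracle: exhaustive grid over the 6-D box, then a projected-gradient
        # polish of the quadratic -- no bvls involved
        lo = np.concatenate([spec.boxes[0].lower, spec.boxes[1].lower])
        hi = np.concatenate([spec.boxes[0].upper, spec.boxes[1].upper])
        F0 = models.response_gradient("competitive", spec.boxes[0].center,
                                      d.points[:, 0], d.points[:, 1], "log")
        F1 = models.response_gradient("noncompetitive", spec.boxes[1].center,
                                      d.points[:, 0], d.points[:, 1], "log")
        a0 = models.response("competitive", spec.boxes[0].center, d.points[:, 0],
                             d.points[:, 1], "log") - F0 @ spec.boxes[0].center
        a1 = models.response("noncompetitive", spec.boxes[1].center,
                             d.points[:, 0], d.points[:, 1], "log") - F1 @ spec.boxes[1].center
        A = np.hstack([-F0, F1])
        b = a0 - a1
        axes = [np.linspace(l, h, 8) for l, h in zip(lo, hi)]
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 6)
        vals = np.sum((b[None, :] - mesh @ A.T) ** 2, axis=1)
        x0 = mesh[int(np.argmin(vals))]
        res = minimize(lambda x: float(np.sum((b - A @ x) ** 2)), x0,
                       method="L-BFGS-B", bounds=list(zip(lo, hi)),
                       options={"ftol": 1e-16, "gtol": 1e-12})
        assert got == pytest.approx(np.sqrt(res.fun), abs=1e-4)


class TestDeltaOptimal:
    TINY = GridSpec(substrate=np.array([0.02, 10.0]), inhibitor=np.array([0.0, 60.0]))

    def test_matches_exhaustive_enumeration_on_tiny_grid(self):
        from itertools import combinations_with_replacement

        spec = delta_spec(1.0)
        cand = self.TINY.points()
        best = -np.inf
        for combo in combinations_with_replacement(range(4), 3):
            idx, counts = np.unique(combo, return_counts=True)
            val = delta_value(ExactDesign(cand[idx], counts), spec)
            best = max(best, val)
        got = delta_optimal(3, self.TINY, spec, seed=0)
        assert delta_value(got, spec) == pytest.approx(best, rel=1e-10)

    def test_ascent_from_random_start(self):
        spec = delta_spec(2.0)
        rng = np.random.default_rng(11)
        cand = self.TINY.points()
        idx = rng.integers(0, 4, size=3)
        uniq, counts = np.unique(idx, return_counts=True)
        start_val = delta_value(ExactDesign(cand[uniq], counts), spec)
        final = delta_optimal(3, self.TINY, spec, seed=11)
        assert delta_value(final, spec) >= start_val - 1e-12

    def test_deterministic_given_seed(self):
        spec = delta_spec(1.0)
        a = delta_optimal(4, self.TINY, spec, seed=5)
        b = delta_optimal(4, self.TINY, spec, seed=5)
        np.testing.assert_array_equal(a.points, b.points)
        np.testing.assert_array_equal(a.replicates, b.replicates)
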