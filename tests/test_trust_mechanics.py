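import numpy as np
import pytest

from iontune.design import DecisionSpace, full_factorial
from iontune.optimizer import (accept_step, lagrangian_gradient,
                               solve_trust_subproblem, trust_ratio,
                               update_radius)
from iontune.surface import fit_quadratic_rsa


class TestTrustRatio:
    @pytest.mark.parametrize("to, tn, so, sn, expected", [
        (10.0, 5.0, 10.0, 5.0, 1.0),      # perfect surrogate
        (10.0, 7.5, 10.0, 5.0, 0.5),
        (10.0, 12.0, 10.0, 5.0, -0.4),    # true worsened: rejection territory
    ])
    def test_examples(self, to, tn, so, sn, expected):
        assert trust_ratio(to, tn, so, sn) == pytest.approx(expected)

    def test_degenerate_guard(self):
        assert trust_ratio(1.0, 1.0 + 1e-15, 2.0, 2.0) == 1.0
        assert trust_ratio(1.0, 2.0, 3.0, 3.0) == np.inf
        assert trust_ratio(2.0, 1.0, 3.0, 3.0) == -np.inf


class TestAcceptStep:
    def test_feasible_candidate_accepted(self):
        assert accept_step(0.8, [1.5, 0.2], [-0.5, -0.1], 0.25)

    def test_ratio_band_rescues_infeasible_candidate(self):
        assert accept_step(0.8, [1.1, 0.9], [0.2, -0.3], 0.25)

    def test_nonpositive_objective_ratio_always_rejects(self):
        assert not accept_step(-0.1, [1.0, 1.0], [-1.0, -1.0], 0.25)
        assert not accept_step(0.0, [1.0], [-1.0], 0.25)

    def test_infeasible_and_poor_marker_ratios_rejected(self):
        assert not accept_step(0.8, [1.5, 1.0], [0.2, -0.3], 0.25)

    def test_no_constraints(self):
        assert accept_step(0.3, [], [], 0.25)


class TestUpdateRadius:
    def test_rejection_quarters(self):
        assert update_radius(1.0, False, False, 6.0) == 0.25

    def test_interior_acceptance_keeps(self):
        assert update_radius(1.0, True, False, 6.0) == 1.0

    def test_boundary_acceptance_doubles_with_cap(self):
        assert update_radius(1.0, True, True, 6.0) == 2.0
        assert update_radius(1.0, True, True, 1.5) == 1.5

    def test_positive_radius_required(self):
        with pytest.raises(ValueError):
            update_radius(0.0, True, False, 6.0)


def _surface_from(fn, levels=5, hw=2.0, n=2):
    space = DecisionSpace([f"v{i}" for i in range(n)], np.ones(n),
                          xL=-10, xU=10)
    X = full_factorial(space, np.zeros(n), hw, levels=levels)
    return fit_quadratic_rsa(X, fn(X)), space


class TestLagrangianGradient:
    def test_stationary_point_no_constraints(self):
        f, _ = _surface_from(lambda X: (X[:, 0] - 0.2) ** 2)
        g = lagrangian_gradient(f, [], [], np.array([0.2, 0.0]))
        assert abs(g[0]) < 1e-8

    def test_closed_form_with_multiplier(self):
        # f = x1^2, constraint surface s = x1, lambda = -2: grad phi(1) = 0
        f, _ = _surface_from(lambda X: X[:, 0] ** 2)
        s, _ = _surface_from(lambda X: X[:, 0])
        g = lagrangian_gradient(f, [s], [-2.0], np.array([1.0, 0.0]))
        assert g[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_finite_differences(self, rng):
        f, _ = _surface_from(lambda X: rng.normal(size=len(X)))
        s1, _ = _surface_from(lambda X: rng.normal(size=len(X)))
        s2, _ = _surface_from(lambda X: rng.normal(size=len(X)))
        lam = [0.7, -1.3]
        x = rng.uniform(-1, 1, size=2)

        def phi(z):
            return f(z) + lam[0] * s1(z) + lam[1] * s2(z)

        g = lagrangian_gradient(f, [s1, s2], lam, x)
        h = 1e-6
        for i in range(2):
            e = np.zeros(2)
            e[i] = h
            assert g[i] == pytest.approx((phi(x + e) - phi(x - e)) / (2 * h),
                                         abs=1e-6)

    def test_multiplier_count_checked(self):
        f, _ = _surface_from(lambda X: X[:, 0] ** 2)
        with pytest.raises(ValueError):
            lagrangian_gradient(f, [f], [1.0, 2.0], np.zeros(2))


class TestSubproblem:
    def setup_method(self):
        self.f, self.space = _surface_from(
            lambda X: (X[:, 0] - 0.2) ** 2 + (X[:, 1] + 0.1) ** 2)

    def test_interior_unconstrained_minimum(self):
        x, lam, feas = solve_trust_subproblem(self.f, [], np.zeros(2), 1.0,
                                              self.space)
        np.testing.assert_allclose(x, [0.2, -0.1], atol=1e-6)
        assert feas and np.all(lam == 0)

    def test_small_radius_pins_to_box_boundary(self):
        # dense-grid oracle at 1e-3 resolution over the trust box
        x, _, feas = solve_trust_subproblem(self.f, [], np.zeros(2), 0.1,
                                            self.space)
        assert feas
        assert np.max(np.abs(x)) == pytest.approx(0.1, abs=1e-9)
        ax = np.arange(-0.1, 0.1 + 5e-4, 1e-3)
        G1, G2 = np.meshgrid(ax, ax, indexing="ij")
        vals = (G1 - 0.2) ** 2 + (G2 + 0.1) ** 2
        assert self.f(x) <= vals.min() + 1e-6

    def test_active_linear_constraint(self):
        # minimize x1 subject to -x1 - 0.5 <= 0: optimum at x1 = -0.5
        f, space = _surface_from(lambda X: X[:, 0])
        g, _ = _surface_from(lambda X: -X[:, 0] - 0.5)
        x, lam, feas = solve_trust_subproblem(f, [g], np.zeros(2), 1.0, space)
        assert feas
        assert x[0] == pytest.approx(-0.5, abs=1e-6)
        # KKT: grad f + lam * grad g = 0 along x1 -> lam = 1
        assert lam[0] == pytest.approx(1.0, abs=1e-4)

    def test_infeasible_subproblem_flagged(self):
        # g = x1^2 + 1 <= 0 has no solution
        g, _ = _surface_from(lambda X: X[:, 0] ** 2 + 1.0)
        x, _, feas = solve_trust_subproblem(self.f, [g], np.zeros(2), 1.0,
                                            self.space)
        assert not feas
        # the returned point minimizes the violation: x1 -> 0
        assert abs(x[0]) < 1e-3

    def test_candidate_within_box_tolerance(self):
        x, _, _ = solve_trust_subproblem(self.f, [], np.ones(2) * 5.0, 0.5,
                                         self.space)
        assert np.all(x <= 5.5 + 1e-9) and np.all(x >= 4.5 - 1e-9)
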