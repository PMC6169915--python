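import numpy as np
import pytest

from iontune.design import ConstraintSpec, DecisionSpace, TrustRegionParams
from iontune.optimizer import (ConductanceCalibration, OptimizationProblem,
                               run_optimization)
from iontune.synthetic import AnalyticProblem, grid_oracle


def quadratic_problem(n=2, bound=6.0):
    space = DecisionSpace([f"g{i}" for i in range(n)], np.ones(n),
                          xL=-bound, xU=bound)
    cons = ConstraintSpec(["m1"], [-100.0], [100.0])

    def evaluator(X):
        X = np.atleast_2d(X)
        f = np.sum((X - 0.7) ** 2, axis=1)
        M = (X[:, :1] * 2.0) + 1.0
        return f, M

    problem = OptimizationProblem(space=space, constraints=cons,
                                  trust_region=TrustRegionParams())
    return problem, evaluator


class TestQuadraticExactness:
    """A degree-2 evaluator is represented exactly by the surfaces."""

    def test_single_acceptance_to_optimum(self):
        problem, evaluator = quadratic_problem()
        res = run_optimization(problem, evaluator)
        np.testing.assert_allclose(res.x_final, 0.7, atol=1e-5)
        assert res.records[0].accepted
        assert res.records[0].rho0 == pytest.approx(1.0, abs=1e-6)

    def test_all_trust_ratios_unity(self):
        problem, evaluator = quadratic_problem()
        res = run_optimization(problem, evaluator)
        for r in res.records:
            assert r.rho0 == pytest.approx(1.0, abs=1e-6)
            for rho in r.rho_markers:
                assert rho == pytest.approx(1.0, abs=1e-6)

    def test_surfaces_reproduce_database(self):
        from iontune.design import full_factorial
        from iontune.surface import fit_quadratic_rsa
        problem, evaluator = quadratic_problem()
        X = full_factorial(problem.space, np.zeros(2), 2.0, 3)
        f, M = evaluator(X)
        fs = fit_quadratic_rsa(X, f, center=np.zeros(2), scale=2.0)
        np.testing.assert_allclose(fs(X), f, atol=1e-8)


class TestLoopInvariants:
    def test_accepted_steps_never_increase_objective(self):
        res = run_optimization(*quadratic_problem())
        f_prev = np.inf
        for r in res.records:
            if r.accepted:
                assert r.f_star <= r.f_k + 1e-12
                assert r.f_star <= f_prev + 1e-12
                f_prev = r.f_star

    def test_radius_factors_and_cap(self):
        problem = AnalyticProblem()
        op = problem.problem(TrustRegionParams(delta0=2.0, delta_max=4.0,
                                               max_iterations=12))
        res = run_optimization(op, problem.evaluator)
        deltas = [r.delta_k for r in res.records]
        for a, b in zip(deltas, deltas[1:]):
            assert b <= 4.0 + 1e-12
            assert min(abs(b / a - f) for f in (0.25, 1.0, 2.0)) < 1e-9 \
                or b == pytest.approx(4.0)

    def test_termination_reason_is_valid(self):
        res = run_optimization(*quadratic_problem())
        assert res.termination in ("step-size", "gradient", "radius",
                                   "max-iter")


class TestAnalyticOracleEquivalence:
    def test_matches_coarse_grid_oracle(self):
        problem = AnalyticProblem()
        res = run_optimization(problem.problem(), problem.evaluator)
        assert problem.feasible(res.x_final[None, :])[0]
        _, f_opt = grid_oracle(problem, resolution=1e-2)
        assert res.f_final <= f_opt + 1e-3

    def test_constraints_satisfied_at_solution(self):
        problem = AnalyticProblem()
        res = run_optimization(problem.problem(), problem.evaluator)
        g = problem.bands.g(res.markers_final)
        assert np.all(g <= 1e-8)


class TestEvaluatorFailurePolicy:
    def test_failed_points_dropped_with_warning(self):
        problem, evaluator = quadratic_problem()

        def flaky(X):
            f, M = evaluator(X)
            X = np.atleast_2d(X)
            # one grid corner of every database fails
            bad = (X[:, 0] > 1.9) & (X[:, 1] > 1.9) if len(X) > 1 \
                else np.zeros(len(X), bool)
            f = np.where(bad, np.nan, f)
            return f, M

        with pytest.warns(UserWarning, match="dropping"):
            res = run_optimization(problem, flaky)
        np.testing.assert_allclose(res.x_final, 0.7, atol=1e-4)


@pytest.fixture(scope="module")
def result():
    return run_optimization(*quadratic_problem())


class TestResultsObject:

    def test_summary_table(self, result):
        s = result.summary()
        assert "Termination" in s and "g0" in s and "m1" in s

    def test_percent_change_consistent_with_scaling(self, result):
        pc = result.percent_change
        np.testing.assert_allclose(
            1.0 + pc / 100.0, 10 ** (result.x_final / 20.0), rtol=1e-12)

    def test_iteration_log_columns(self, result):
        df = result.iteration_frame()
        for col in ("k", "delta_k", "f", "rho0", "flgTR", "m_m1"):
            assert col in df.columns

    def test_json_round_trip(self, result, tmp_path):
        import json
        p = tmp_path / "r.json"
        result.to_json(p)
        d = json.loads(p.read_text())
        assert d["termination"] == result.termination
        assert set(d["conductances"]) == {"g0", "g1"}

    def test_model_facade(self):
        problem, evaluator = quadratic_problem()
        res = ConductanceCalibration(problem, evaluator).fit()
        np.testing.assert_allclose(res.x_final, 0.7, atol=1e-5)


class TestLogOutput:
    def test_csv_logs_written(self, tmp_path):
        problem, evaluator = quadratic_problem()
        run_optimization(problem, evaluator, log_dir=tmp_path)
        assert (tmp_path / "iterations.csv").exists()
        assert (tmp_path / "database_k0.csv").exists()
        assert (tmp_path / "result.json").exists()
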