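import numpy as np
import pandas as pd
import pytest

from iontune.models import ToyVentricularModel
from iontune.sensitivity import (SensitivityMatrix, percent_change,
                                 run_sensitivity, select_decision_variables,
                                 sensitivity)


class TestPercentChange:
    @pytest.mark.parametrize("m, ctrl, expected", [
        (100.0, 100.0, 0.0),
        (130.0, 100.0, 30.0),
        (70.0, 100.0, -30.0),
    ])
    def test_examples(self, m, ctrl, expected):
        assert percent_change(m, ctrl) == pytest.approx(expected)

    def test_zero_control_flagged_undefined(self):
        assert np.isnan(percent_change(1.0, 0.0))


class TestSensitivityFormula:
    def test_unit_elasticity_is_100(self):
        assert sensitivity(30.0, -30.0, 0.3) == pytest.approx(100.0)

    def test_insensitive_property(self):
        assert sensitivity(5.0, 5.0, 0.3) == 0.0

    def test_literal_convention_factor_100(self):
        assert sensitivity(30.0, -30.0, 0.3, convention="literal") \
            == pytest.approx(10_000.0)

    def test_sign_flips_with_run_swap(self):
        assert sensitivity(10.0, -20.0, 0.3) == -sensitivity(-20.0, 10.0, 0.3)

    def test_positive_perturbation_required(self):
        with pytest.raises(ValueError):
            sensitivity(1.0, -1.0, 0.0)


class _ParamModel:
    """Marker values are closed-form functions of the parameters."""

    def __init__(self, **params):
        self.params = params

    def with_params(self, **updates):
        p = dict(self.params)
        p.update(updates)
        return _ParamModel(**p)


def linear_marker_fn(m):
    return {"obj": 3.0 * m.params["a"], "other": 5.0}


class TestRunSensitivity:
    def test_linear_evaluator_gives_exactly_100(self):
        model = _ParamModel(a=2.0, b=1.0)
        for a in (0.1, 0.3, 0.5):
            mat = run_sensitivity(model, ["a"], linear_marker_fn, a=a)
            assert mat.S.loc["a", "obj"] == pytest.approx(100.0)

    def test_uninvolved_parameter_has_zero_sensitivity(self):
        model = _ParamModel(a=2.0, b=1.0)
        mat = run_sensitivity(model, ["b"], linear_marker_fn)
        assert mat.S.loc["b", "obj"] == 0.0
        assert mat.S.loc["b", "other"] == 0.0

    def test_evaluation_count_bookkeeping(self):
        calls = []
        model = _ParamModel(a=2.0, b=1.0, c=3.0)

        def counting_fn(m):
            calls.append(1)
            return linear_marker_fn(m)

        run_sensitivity(model, ["a", "b", "c"], counting_fn)
        assert len(calls) == 2 * 3 + 1

    def test_failed_run_marks_nan_and_proceeds(self):
        model = _ParamModel(a=2.0, b=1.0)

        def flaky(m):
            if m.params["b"] > 1.2:
                raise RuntimeError("boom")
            return linear_marker_fn(m)

        with pytest.warns(UserWarning, match="failed"):
            mat = run_sensitivity(model, ["a", "b"], flaky)
        assert np.isnan(mat.S.loc["b", "obj"])
        assert mat.S.loc["a", "obj"] == pytest.approx(100.0)

    def test_toy_potassium_conductance_shortens_apd(self):
        """More delayed-rectifier current repolarizes faster: S < 0 for
        APD90 against G_K on the toy model."""
        from iontune.protocols import steady_state_pacing
        from iontune import biomarkers as B

        def marker_fn(m):
            _, trace = steady_state_pacing(m, 1000.0, 60)
            return {"APD90": B.apd(trace, 0.9),
                    "iktot_integral": B.iktot_integral(trace)}

        mat = run_sensitivity(ToyVentricularModel(), ["G_K"], marker_fn)
        assert mat.S.loc["G_K", "APD90"] < 0


class TestNormalization:
    @pytest.fixture
    def matrix(self):
        S = pd.DataFrame({"obj": [10.0, -20.0, 5.0],
                          "m1": [0.0, 0.0, 0.0],
                          "m2": [-3.0, 3.0, 1.0]},
                         index=["a", "b", "c"])
        return SensitivityMatrix(D_plus=S, D_minus=-S, S=S,
                                 M_control=pd.Series({"obj": 1.0}), a=0.3)

    def test_columns_in_unit_interval_with_unique_max(self, matrix):
        norm = matrix.normalized()
        for col in ("obj", "m2"):
            v = norm[col].to_numpy()
            assert v.min() >= 0.0 and v.max() == 1.0
            assert (v == 1.0).sum() == 1

    def test_tie_broken_by_first_index(self, matrix):
        norm = matrix.normalized()
        # m2 has |S| = 3 for both 'a' and 'b': 'a' takes the 1
        assert norm.loc["a", "m2"] == 1.0
        assert norm.loc["b", "m2"] < 1.0


class TestSelection:
    def make_matrix(self, S):
        return SensitivityMatrix(D_plus=S, D_minus=-S, S=S,
                                 M_control=pd.Series(0.0, index=S.columns),
                                 a=0.3)

    def test_unique_dominator_excluded(self):
        S = pd.DataFrame({
            "iktot_integral": [200.0, 150.0, 100.0],
            "tau_slow": [5.0, 120.0, 8.0],
        }, index=["g1", "g2", "g3"])
        selected, excl = select_decision_variables(self.make_matrix(S))
        assert "g2" in excl and excl["g2"] == "tau_slow"
        assert selected == ["g1", "g3"]

    def test_compensated_dominator_kept(self):
        S = pd.DataFrame({
            "iktot_integral": [200.0, 150.0],
            "tau_slow": [80.0, 120.0],   # both influence tau_slow
        }, index=["g1", "g2"])
        selected, excl = select_decision_variables(self.make_matrix(S))
        assert excl == {}
        assert selected == ["g1", "g2"]

    def test_all_zero_matrix_warns_empty(self):
        S = pd.DataFrame({"iktot_integral": [0.0], "m": [0.0]}, index=["g"])
        with pytest.warns(UserWarning, match="all-zero"):
            selected, _ = select_decision_variables(self.make_matrix(S))
        assert selected == []

    def test_ranking_is_deterministic(self):
        S = pd.DataFrame({"iktot_integral": [10.0, 30.0, 20.0],
                          "m": [1.0, 1.0, 1.0]}, index=list("abc"))
        first, _ = select_decision_variables(self.make_matrix(S))
        second, _ = select_decision_variables(self.make_matrix(S))
        assert first == second == ["b", "c", "a"]

    def test_top_k_truncation(self):
        S = pd.DataFrame({"iktot_integral": [10.0, 30.0, 20.0],
                          "m": [1.0, 1.0, 1.0]}, index=list("abc"))
        selected, _ = select_decision_variables(self.make_matrix(S), k=2)
        assert selected == ["b", "c"]
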