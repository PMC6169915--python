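import numpy as np
import pytest

from iontune.models import ToyVentricularModel
from iontune.protocols import (APTrace, BeatSeries, ko_step_unstimulated,
                               rate_adaptation_protocol, restitution,
                               steady_state_pacing)


class TestSteadyStatePacing:
    def test_single_beat_series(self, toy):
        series, trace = steady_state_pacing(toy, 1000.0, 1)
        assert len(series) == 1
        assert trace.t[-1] == pytest.approx(1000.0)

    def test_beat_accounting(self, short_paced):
        _, series, _ = short_paced
        assert len(series) == 20
        np.testing.assert_array_equal(series.beat, np.arange(20))

    def test_quasi_steady_state_at_300_beats(self, paced_1hz):
        _, series, _ = paced_1hz
        drift = np.abs(series.apd90[-10:] - series.apd90[-1])
        assert drift.max() < 0.1  # ms

    def test_conductance_perturbation_breaks_k_balance(self, toy, paced_1hz):
        _, series0, _ = paced_1hz
        m = toy.with_params(G_K1=toy.params["G_K1"] * 1.3)
        series1, _ = steady_state_pacing(m, 1000.0, 300)
        assert abs(series1.iktot_integral[-1]) \
            > 10.0 * abs(series0.iktot_integral[-1])

    def test_trace_carries_currents_and_concentrations(self, paced_1hz):
        _, _, trace = paced_1hz
        assert trace.Cai is not None and trace.Ki is not None
        assert np.ndim(trace.currents.IK1) == 1
        assert np.all(np.diff(trace.t) > 0)

    def test_invalid_inputs(self, toy):
        with pytest.raises(ValueError):
            steady_state_pacing(toy, 1000.0, 0)
        with pytest.raises(ValueError):
            steady_state_pacing(toy, 1.0, 1)  # CL shorter than stimulus


class TestRateAdaptation:
    def test_beat_count_and_onsets(self, toy):
        series = rate_adaptation_protocol(toy, duration_pre_ms=30_000,
                                          duration_post_ms=30_000)
        assert len(series) == 30 + 50
        post = series.onset_s >= 0
        assert post.sum() == 50
        assert series.onset_s[~post].max() < 0

    def test_default_durations_are_eight_minutes(self, toy):
        # 480 beats at CL 1000 + 800 at CL 600 without running them
        import inspect
        sig = inspect.signature(rate_adaptation_protocol)
        assert sig.parameters["duration_pre_ms"].default == 480_000.0
        assert int(480_000 / 1000) + int(480_000 / 600) == 480 + 800

    def test_adaptation_direction(self, toy):
        series = rate_adaptation_protocol(toy, duration_pre_ms=60_000,
                                          duration_post_ms=60_000)
        post = series.onset_s >= 0
        pre_last = series.apd90[~post][-1]
        post_late = series.apd90[post][5:]
        assert np.all(post_late < pre_last)

    def test_null_protocol_is_flat(self, toy):
        series = rate_adaptation_protocol(toy, cl_pre=1000.0, cl_post=1000.0,
                                          duration_pre_ms=60_000,
                                          duration_post_ms=30_000)
        post = series.apd90[series.onset_s >= 0]
        assert post.max() - post.min() < 0.1


class TestKoStep:
    def test_no_step_gives_zero_t90_with_warning(self, toy):
        with pytest.warns(UserWarning, match="no membrane-potential"):
            r = ko_step_unstimulated(toy, 5.4, 5.4, settle_ms=500,
                                     observe_ms=500)
        assert r.t90 == 0.0 and r.warning

    def test_hyperkalemia_depolarizes(self, toy):
        r = ko_step_unstimulated(toy, 4.4, 6.6, settle_ms=5000,
                                 observe_ms=2000)
        assert np.isfinite(r.t90) and r.t90 > 0
        assert r.V_ss > r.V_start

    def test_hypokalemia_hyperpolarizes(self, toy):
        r = ko_step_unstimulated(toy, 5.4, 3.0, settle_ms=5000,
                                 observe_ms=2000)
        assert r.V_ss < r.V_start

    def test_positive_ko_required(self, toy):
        with pytest.raises(ValueError):
            ko_step_unstimulated(toy, -1.0, 5.4)


class TestRestitution:
    def test_normalization_identity(self, toy):
        table = restitution(toy, [1000.0], n_beats=50)
        assert table.loc[0, "apd90_norm"] == pytest.approx(1.0)

    def test_rate_dependence_direction(self, toy):
        table = restitution(toy, [600.0, 1000.0, 2000.0], n_beats=150)
        apd = table["apd90"].to_numpy()
        assert np.all(np.diff(apd) >= -0.05)  # non-decreasing in CL

    def test_loss_of_capture_marked_inexcitable(self, toy):
        weak = toy.copy()
        weak.stim_amplitude = -2.0  # far below threshold
        table = restitution(weak, [1000.0], n_beats=3)
        assert not table.loc[0, "excitable"]
        assert np.isnan(table.loc[0, "apd90"])

    def test_empty_cl_list_rejected(self, toy):
        with pytest.raises(ValueError):
            restitution(toy, [])


class TestContainers:
    def test_trace_requires_increasing_time(self):
        with pytest.raises(ValueError):
            APTrace(t=np.array([0.0, 0.0, 1.0]), V=np.zeros(3), CL=1.0)

    def test_beat_series_frame(self, short_paced):
        _, series, _ = short_paced
        df = series.to_frame()
        assert list(df["beat"]) == list(range(20))
        assert df["captured"].all()

    def test_concat(self, short_paced):
        _, series, _ = short_paced
        cat = BeatSeries.concat([series, series])
        assert len(cat) == 40


class TestDeterminism:
    def test_identical_runs_bitwise_equal(self, toy):
        s1, t1 = steady_state_pacing(toy, 1000.0, 5)
        s2, t2 = steady_state_pacing(toy, 1000.0, 5)
        np.testing.assert_array_equal(s1.apd90, s2.apd90)
        np.testing.assert_array_equal(t1.V, t2.V)
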