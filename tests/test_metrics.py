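"""Stability-property formulas, online resilience, and their invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cytostability import (
    EcologicalSituation,
    displacement_speed,
    elasticity,
    online_resilience,
    resilience,
    resistance,
    summarize,
)
from cytostability.errors import UndefinedPropertyError
from cytostability.reference import DeviationTrace


def make_trace(devs, times=None, t_ref=None, metric="canberra"):
    devs = np.asarray(devs, dtype=float)
    times = np.arange(float(len(devs))) if times is None else np.asarray(times, dtype=float)
    return DeviationTrace(times, devs, t_ref=float(times[0]) if t_ref is None else t_ref, metric=metric)


class TestResistance:
    @pytest.mark.parametrize("d_max,expected", [(0.0, 1.0), (1.0, 0.0), (0.5, 0.5)])
    def test_affine_map(self, d_max, expected):
        assert resistance(make_trace([0.0, d_max])) == pytest.approx(expected)


class TestDisplacementSpeed:
    def test_hand_values(self):
        trace = make_trace([0.0, 0.5], times=[0.0, 6.0])
        assert displacement_speed(trace) == pytest.approx(0.5 / 6, abs=1e-12)
        slow = make_trace([0.0, 0.79], times=[0.0, 88.0])
        assert displacement_speed(slow) == pytest.approx(0.009, abs=5e-4)

    def test_time_scaling_halves_speed(self):
        base = make_trace([0.0, 0.4, 0.3], times=[0.0, 5.0, 9.0])
        doubled = make_trace([0.0, 0.4, 0.3], times=[0.0, 10.0, 18.0])
        assert displacement_speed(doubled) == pytest.approx(displacement_speed(base) / 2)

    def test_max_at_reference_sample_undefined(self):
        with pytest.raises(UndefinedPropertyError):
            displacement_speed(make_trace([0.5, 0.2, 0.1]))


class TestResilience:
    def test_no_recovery_is_zero(self):
        assert resilience(make_trace([0.0, 0.5, 0.5])) == 0.0

    def test_perfect_return_is_one(self):
        assert resilience(make_trace([0.0, 0.5, 0.0])) == 1.0

    def test_partial_recovery_hand_value(self):
        # d_max 0.5, d_end 0.385 -> 2*0.5/0.885 - 1
        assert resilience(make_trace([0.0, 0.5, 0.385])) == pytest.approx(0.129944, abs=1e-5)

    def test_never_displaced_undefined(self):
        with pytest.raises(UndefinedPropertyError):
            resilience(make_trace([0.0, 0.0]))

    def test_monotone_decreasing_in_d_end(self):
        values = [resilience(make_trace([0.0, 0.5, d_end])) for d_end in (0.1, 0.2, 0.3, 0.4)]
        assert values == sorted(values, reverse=True)

    @given(st.floats(1e-6, 1.0), st.floats(0.0, 1.0))
    def test_range_bound(self, d_max, frac):
        d_end = d_max * frac
        rl = resilience(make_trace([0.0, d_max, d_end]))
        assert 0.0 <= rl <= 1.0


class TestElasticity:
    def test_no_recovery_not_available(self):
        assert elasticity(make_trace([0.0, 0.5, 0.5])) is None

    def test_hand_values(self):
        # d_max 0.5 at 6 h, d_end 0.385 at 47 h: E = 0.115/41
        trace = make_trace([0.0, 0.5, 0.385], times=[0.0, 6.0, 47.0])
        assert elasticity(trace) == pytest.approx(0.115 / 41, abs=1e-12)
        fast = make_trace([0.0, 0.31, 0.211], times=[0.0, 1.0, 6.8])
        assert elasticity(fast) == pytest.approx(0.099 / 5.8, abs=1e-12)

    def test_monotone_decreasing_in_t_end(self):
        vals = [
            elasticity(make_trace([0.0, 0.5, 0.3], times=[0.0, 1.0, t_end]))
            for t_end in (5.0, 10.0, 20.0)
        ]
        assert vals == sorted(vals, reverse=True)

    def test_units_scale_with_time(self):
        t1 = make_trace([0.0, 0.5, 0.3], times=[0.0, 1.0, 5.0])
        t2 = make_trace([0.0, 0.5, 0.3], times=[0.0, 3.0, 15.0])
        assert elasticity(t2) == pytest.approx(elasticity(t1) / 3)


class TestOnlineResilience:
    def test_hand_computed_sequence(self):
        trace = make_trace([0.1, 0.3, 0.5, 0.4, 0.2])
        online = online_resilience(trace)
        np.testing.assert_allclose(online.running_max, [0.1, 0.3, 0.5, 0.5, 0.5])
        np.testing.assert_allclose(
            online.rl_online,
            [0.0, 0.0, 0.0, 2 * 0.5 / 0.9 - 1, 2 * 0.5 / 0.7 - 1],
            atol=1e-12,
        )

    def test_monotone_increasing_deviation_all_zero(self):
        online = online_resilience(make_trace([0.0, 0.1, 0.2, 0.5]))
        np.testing.assert_array_equal(online.rl_online, 0.0)

    def test_return_to_zero_gives_one(self):
        online = online_resilience(make_trace([0.0, 0.5, 0.0]))
        assert online.rl_online[-1] == 1.0

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30))
    def test_final_value_equals_post_hoc(self, devs):
        """Online and post hoc resilience coincide exactly at the trace end."""
        trace = make_trace(devs)
        online = online_resilience(trace)
        assert np.all(np.diff(online.running_max) >= 0)
        assert np.all((online.rl_online >= 0) & (online.rl_online <= 1))
        if trace.d_max > 0:
            assert online.rl_online[-1] == resilience(trace)
        else:
            assert online.rl_online[-1] == 0.0
        # zero exactly at running-maximum samples
        at_max = trace.deviations == online.running_max
        assert np.all(online.rl_online[at_max] == 0.0)


class TestSummarize:
    def test_non_resilient_trace(self):
        report = summarize(make_trace([0.0, 0.5, 0.5]))
        assert report.resilience == 0.0
        assert report.elasticity is None
        assert not report.resilient_flag

    def test_inside_reference_space_bound(self):
        report = summarize(make_trace([0.0, 0.05, 0.02]), reference_radius=0.16)
        assert report.resistance >= 1 - 0.16

    def test_hand_trace_composition(self):
        trace = make_trace([0.0, 0.5, 0.385], times=[0.0, 6.0, 47.0])
        situation = EcologicalSituation(variable_of_interest="gate abundances")
        report = summarize(trace, situation)
        assert report.resistance == pytest.approx(0.50, abs=1e-12)
        assert report.displacement_speed == pytest.approx(0.0833, abs=5e-5)
        assert report.resilience == pytest.approx(0.1299, abs=5e-5)
        assert report.elasticity == pytest.approx(0.0028, abs=5e-5)
        assert report.resilient_flag
        assert report.situation.variable_of_interest == "gate abundances"

    def test_undisturbed_trace_reports_none_speed(self):
        report = summarize(make_trace([0.0, 0.0, 0.0]))
        assert report.resistance == 1.0
        assert report.displacement_speed is None
        assert report.resilience is None
        assert not report.resilient_flag

    def test_rs_rl_bounds_random_traces(self, rng):
        for _ in range(200):
            devs = rng.uniform(0, 1, size=int(rng.integers(2, 12)))
            report = summarize(make_trace(devs))
            assert 0.0 <= report.resistance <= 1.0
            if report.resilience is not None:
                assert 0.0 <= report.resilience <= 1.0
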