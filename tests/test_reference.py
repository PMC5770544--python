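"""Reference-space construction, constancy, deviation traces, crossings."""

import numpy as np
import pytest

from cytostability import (
    DisturbanceAnnotation,
    GateAbundanceSeries,
    boundary_crossings,
    build_reference,
    constancy_check,
    deviation_trace,
    distance,
)
from cytostability.errors import (
    ConfigurationError,
    EmptyWindowError,
    MissingReferenceError,
)
from cytostability.reference import DeviationTrace, ReferenceSpace

from conftest import random_composition


class TestBuildReference:
    def test_mean_and_radius_hand_value(self):
        ref = build_reference([[0.6, 0.4], [0.4, 0.6]], metric="canberra")
        np.testing.assert_allclose(ref.s_ref, [0.5, 0.5])
        assert ref.radius == pytest.approx((0.1 / 1.1 + 0.1 / 0.9) / 2, abs=1e-12)
        assert ref.m == 2

    def test_identical_samples_zero_sigma_zero_radius(self):
        ref = build_reference([[0.5, 0.5]] * 3)
        np.testing.assert_array_equal(ref.sigma_ref, [0.0, 0.0])
        assert ref.radius == 0.0

    def test_single_sample_uses_fallback_radius(self):
        ref = build_reference([[0.7, 0.3]], fallback_radius=0.16)
        assert ref.radius == 0.16
        np.testing.assert_array_equal(ref.sigma_ref, [0.0, 0.0])

    def test_single_sample_without_fallback_is_error(self):
        with pytest.raises(ConfigurationError, match="previous experience"):
            build_reference([[0.7, 0.3]])

    def test_sigma_uses_sample_denominator(self):
        samples = [[0.6, 0.4], [0.4, 0.6]]
        ref = build_reference(samples)
        np.testing.assert_allclose(ref.sigma_ref, np.std(samples, axis=0, ddof=1))

    @pytest.mark.parametrize("metric", ["canberra", "euclidean"])
    def test_every_replicate_inside_space(self, rng, metric):
        """By construction the radius covers all reference samples."""
        for _ in range(20):
            samples = [random_composition(rng, 8) for _ in range(5)]
            ref = build_reference(samples, metric=metric)
            for s in samples:
                assert distance(ref.s_ref, s, metric) <= ref.radius + 1e-12


class TestConstancy:
    def test_low_technical_variability_is_constant(self):
        # mean replicate sd of 0.6% against the 25% intrinsic-variation default
        ref = ReferenceSpace(
            s_ref=np.array([0.5, 0.5]), sigma_ref=np.array([0.006, 0.006]),
            radius=0.1, metric="canberra", m=5,
        )
        result = constancy_check(ref)
        assert result.constant and result.verdict == "constant"
        assert result.mean_sigma == pytest.approx(0.006)
        assert result.threshold == 0.25

    def test_zero_sigma_constant_for_any_positive_threshold(self):
        ref = build_reference([[0.5, 0.5]] * 3)
        assert constancy_check(ref, threshold=1e-12).constant

    def test_threshold_exceedance(self):
        ref = ReferenceSpace(
            s_ref=np.array([0.5, 0.5]), sigma_ref=np.array([0.30, 0.30]),
            radius=0.1, metric="canberra", m=5,
        )
        result = constancy_check(ref, threshold=0.25)
        assert not result.constant and result.verdict == "not_constant"


def _series():
    # reference phase at (0.5,0.3,0.2), displaced afterwards
    rows = np.array(
        [
            [0.5, 0.3, 0.2],
            [0.5, 0.3, 0.2],
            [0.3, 0.3, 0.4],
            [0.1, 0.3, 0.6],
            [0.2, 0.3, 0.5],
        ]
    )
    return GateAbundanceSeries(np.array([0.0, 2.0, 4.0, 6.0, 8.0]), ("a", "b", "c"), rows)


class TestDeviationTrace:
    def test_identical_series_all_zero(self):
        rows = np.tile([0.5, 0.3, 0.2], (4, 1))
        series = GateAbundanceSeries(np.arange(4.0), ("a", "b", "c"), rows)
        ref = build_reference([rows[0]], fallback_radius=0.1)
        trace = deviation_trace(series, ref, DisturbanceAnnotation("w", 0.5, 3.0))
        assert trace.d_max == 0.0
        np.testing.assert_array_equal(trace.deviations, 0.0)

    def test_max_and_end_extraction(self):
        series = _series()
        ref = build_reference([series.state(1)], fallback_radius=0.1)
        trace = deviation_trace(series, ref, DisturbanceAnnotation("w", 3.0, 8.0))
        assert trace.t_ref == 2.0
        assert trace.times[0] == 2.0 and trace.t_end == 8.0
        # canberra deviations of the three post-onset states
        expected = [distance(series.state(i), ref.s_ref) for i in (2, 3, 4)]
        np.testing.assert_allclose(trace.deviations[1:], expected, atol=1e-15)
        assert trace.d_max == max(expected)
        assert trace.t_max == 6.0
        assert trace.d_end == expected[-1]

    def test_tie_takes_earlier_time(self):
        trace = DeviationTrace(
            times=np.array([0.0, 1.0, 2.0, 3.0]),
            deviations=np.array([0.0, 0.4, 0.4, 0.1]),
            t_ref=0.0,
            metric="canberra",
        )
        assert trace.t_max == 1.0

    def test_empty_window_raises(self):
        series = _series()
        ref = build_reference([series.state(0)], fallback_radius=0.1)
        with pytest.raises(EmptyWindowError):
            deviation_trace(series, ref, DisturbanceAnnotation("w", 8.5, 9.0))

    def test_no_sample_before_onset_raises(self):
        series = _series()
        ref = build_reference([series.state(0)], fallback_radius=0.1)
        with pytest.raises(MissingReferenceError):
            deviation_trace(series, ref, DisturbanceAnnotation("w", -1.0, 8.0))

    def test_permutation_invariance(self, rng):
        series = _series()
        window = DisturbanceAnnotation("w", 3.0, 8.0)
        ref = build_reference([series.state(1)], fallback_radius=0.1)
        base = deviation_trace(series, ref, window)
        perm = rng.permutation(3)
        permuted = GateAbundanceSeries(
            series.times, tuple(series.gate_ids[i] for i in perm), series.abundances[:, perm]
        )
        ref_p = build_reference([permuted.state(1)], fallback_radius=0.1)
        trace_p = deviation_trace(permuted, ref_p, window)
        np.testing.assert_allclose(trace_p.deviations, base.deviations, atol=1e-14)

    def test_invariants_d_end_le_d_max(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 10))
            dev = rng.uniform(0, 1, size=n)
            trace = DeviationTrace(np.arange(float(n)), dev, t_ref=0.0, metric="canberra")
            assert trace.d_end <= trace.d_max
            assert trace.t_ref <= trace.t_max <= trace.t_end


class TestBoundaryCrossings:
    def _ref(self, radius=0.16):
        return ReferenceSpace(
            s_ref=np.array([0.5, 0.5]), sigma_ref=np.zeros(2),
            radius=radius, metric="canberra", m=1,
        )

    def _trace(self, devs):
        return DeviationTrace(
            np.arange(float(len(devs))), np.asarray(devs), t_ref=0.0, metric="canberra"
        )

    def test_single_exit(self):
        events = boundary_crossings(self._trace([0.01, 0.3, 0.4]), self._ref())
        assert events == [(1.0, "exit")]

    def test_all_inside_no_events(self):
        assert boundary_crossings(self._trace([0.01, 0.1, 0.15]), self._ref()) == []

    def test_return_after_initial_exit_state(self):
        events = boundary_crossings(self._trace([0.3, 0.1]), self._ref())
        assert events == [(0.0, "exit"), (1.0, "return")]

    def test_events_alternate(self, rng):
        for _ in range(50):
            devs = rng.uniform(0, 1, size=12)
            events = boundary_crossings(self._trace(devs), self._ref(0.5))
            directions = [d for _, d in events]
            assert directions == (["exit", "return"] * 6)[: len(directions)]

    def test_metric_mismatch_rejected(self):
        ref = ReferenceSpace(
            s_ref=np.array([0.5, 0.5]), sigma_ref=np.zeros(2),
            radius=0.1, metric="euclidean", m=1,
        )
        with pytest.raises(ConfigurationError):
            boundary_crossings(self._trace([0.1]), ref)
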