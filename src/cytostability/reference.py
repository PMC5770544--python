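"""Reference state, reference space, constancy, and deviation traces.

A stability assessment needs a predisturbance reference.  Given m reference
samples (a predisturbance time series or technical replicates), the
reference state ``s_ref`` is the per-gate mean composition, the per-gate
standard deviations ``sigma_ref`` measure predisturbance variability
(natural plus technical), and an n-sphere of radius

    r = max over reference samples of d(s_ref, sample)

under the chosen metric defines the reference space.  Crossing that
boundary marks departure from the reference; a crossing in the opposite
direction marks return.  With a single predisturbance sample available the
sample itself is the reference state and the radius must be supplied from
prior experience.

The deviation trace d(t) = d(s(t), s_ref) over one disturbance window,
together with its maximum d_max (first attained at t_max) and its final
value d_end at t_end, is the raw material for every stability property.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DisturbanceAnnotation, GateAbundanceSeries
from .distances import DEFAULT_METRIC, distance
from .errors import (
    ConfigurationError,
    DimensionMismatchError,
    EmptyWindowError,
    MissingReferenceError,
)


@dataclass(frozen=True)
class ReferenceSpace:
    """Mean reference composition plus variability and boundary radius."""

    s_ref: np.ndarray
    sigma_ref: np.ndarray
    radius: float
    metric: str
    m: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "s_ref", np.asarray(self.s_ref, dtype=float))
        object.__setattr__(self, "sigma_ref", np.asarray(self.sigma_ref, dtype=float))

    @property
    def n_gates(self) -> int:
        return self.s_ref.size

    def contains(self, state) -> bool:
        """Whether *state* lies inside the reference space (d <= radius)."""
        return distance(self.s_ref, state, self.metric) <= self.radius


@dataclass(frozen=True)
class ConstancyResult:
    """Outcome of the constancy check on a reference space."""

    constant: bool
    mean_sigma: float
    threshold: float

    @property
    def verdict(self) -> str:
        return "constant" if self.constant else "not_constant"


def build_reference(samples, metric: str = DEFAULT_METRIC, fallback_radius=None) -> ReferenceSpace:
    """Construct a reference space from one or more reference samples.

    Parameters
    ----------
    samples
        Sequence of composition vectors (predisturbance time series or
        technical replicates), all the same length.
    metric
        Distance used both for the radius and for later deviation traces.
    fallback_radius
        Radius to use when only one sample is given (required in that case).

    Notes
    -----
    ``s_ref`` is the per-gate arithmetic mean renormalized to sum 1 (means
    of compositions can drift off the simplex by rounding).  ``sigma_ref``
    uses the sample (m-1) denominator and is the zero vector for m = 1.
    Every input sample lies within the resulting space by construction
    (radius is the maximal sample deviation).
    """
    mat = np.asarray([np.asarray(s, dtype=float) for s in samples], dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 1:
        raise ConfigurationError("build_reference needs a non-empty list of equal-length samples")
    m, _n = mat.shape
    s_ref = mat.mean(axis=0)
    total = s_ref.sum()
    if total <= 0:
        raise ConfigurationError("reference samples sum to zero; cannot normalize")
    s_ref = s_ref / total
    if m == 1:
        sigma_ref = np.zeros_like(s_ref)
        if fallback_radius is None:
            raise ConfigurationError(
                "only one reference sample is available: the sample serves as the "
                "reference state, but a reference-space radius cannot be derived from "
                "it; supply fallback_radius, choosing a threshold from previous "
                "experience (e.g. from technical replicates)"
            )
        radius = float(fallback_radius)
    else:
        sigma_ref = mat.std(axis=0, ddof=1)
        radius = max(distance(s_ref, row, metric) for row in mat)
    if radius < 0:
        raise ConfigurationError(f"radius must be non-negative, got {radius}")
    return ReferenceSpace(s_ref=s_ref, sigma_ref=sigma_ref, radius=float(radius), metric=metric, m=m)


#: Default constancy threshold on the mean per-gate standard deviation.
#: Intrinsic community variation of natural communities has been reported
#: around 25%, so a reference phase well below that counts as constant.
DEFAULT_CONSTANCY_THRESHOLD = 0.25


def constancy_check(ref: ReferenceSpace, threshold: float = DEFAULT_CONSTANCY_THRESHOLD) -> ConstancyResult:
    """Check that the reference phase is constant enough to anchor a reference.

    The mean of ``sigma_ref`` (average per-gate standard deviation across
    reference samples, in abundance-fraction units) is compared against
    *threshold*; technical replicates of a steady community typically sit
    near 0.006 (0.6%), far below the default 0.25.
    """
    if threshold <= 0:
        raise ConfigurationError("constancy threshold must be positive")
    mean_sigma = float(np.mean(ref.sigma_ref))
    return ConstancyResult(constant=mean_sigma <= threshold, mean_sigma=mean_sigma, threshold=threshold)


@dataclass(frozen=True)
class DeviationTrace:
    """d(t) over one disturbance window, anchored at the reference time.

    ``times[0]`` is t_ref (the time of the last sample before disturbance
    onset); subsequent entries are the in-window samples.  Derived
    quantities follow the first-attainment convention for t_max.
    """

    times: np.ndarray
    deviations: np.ndarray
    t_ref: float
    metric: str
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        dev = np.asarray(self.deviations, dtype=float)
        if times.shape != dev.shape or times.ndim != 1 or times.size < 1:
            raise ConfigurationError("trace times and deviations must be equal-length 1-D arrays")
        if np.any(np.diff(times) <= 0):
            raise ConfigurationError("trace times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "deviations", dev)

    @property
    def d_max(self) -> float:
        return float(np.max(self.deviations))

    @property
    def t_max(self) -> float:
        """Time of first attainment of the maximal deviation."""
        return float(self.times[int(np.argmax(self.deviations))])

    @property
    def d_end(self) -> float:
        return float(self.deviations[-1])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])


def deviation_trace(
    series: GateAbundanceSeries,
    ref: ReferenceSpace,
    window: DisturbanceAnnotation,
) -> DeviationTrace:
    """Deviation-from-reference trace for the samples of one disturbance window.

    Includes every sample with ``onset_time <= t <= window_end`` plus the
    last sample before onset, whose time becomes ``t_ref`` (the clock zero
    for displacement speed).
    """
    if series.n_gates != ref.n_gates:
        raise DimensionMismatchError(
            f"series has {series.n_gates} gates but reference has {ref.n_gates}"
        )
    idx = series.window_indices(window.onset_time, window.window_end)
    if idx.size == 0:
        raise EmptyWindowError(
            f"disturbance window {window.label!r} "
            f"[{window.onset_time}, {window.window_end}] contains no samples"
        )
    ref_idx = series.last_index_before(window.onset_time)
    if ref_idx < 0:
        raise MissingReferenceError(
            f"no sample before onset {window.onset_time} to anchor the reference "
            f"for window {window.label!r}"
        )
    indices = np.concatenate(([ref_idx], idx))
    times = series.times[indices]
    devs = np.array(
        [distance(series.state(i), ref.s_ref, ref.metric) for i in indices], dtype=float
    )
    return DeviationTrace(
        times=times,
        deviations=devs,
        t_ref=float(series.times[ref_idx]),
        metric=ref.metric,
        label=window.label,
    )


def boundary_crossings(trace: DeviationTrace, ref: ReferenceSpace) -> list:
    """Detect reference-space boundary crossings along a deviation trace.

    Returns a list of ``(time, direction)`` tuples with direction ``"exit"``
    (first sample with d > radius after being inside) or ``"return"``
    (first sample with d <= radius after being outside).  The system is
    assumed inside before the first sample, so events alternate starting
    with an exit.  Detection is sample-based; no interpolation between
    samples is attempted.
    """
    if trace.metric != ref.metric:
        raise ConfigurationError(
            f"trace metric {trace.metric!r} differs from reference metric {ref.metric!r}"
        )
    events = []
    inside = True
    for t, d in zip(trace.times, trace.deviations):
        if inside and d > ref.radius:
            events.append((float(t), "exit"))
            inside = False
        elif not inside and d <= ref.radius:
            events.append((float(t), "return"))
            inside = True
    return events
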