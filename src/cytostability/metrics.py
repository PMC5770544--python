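"""Stability properties computed from a deviation trace.

Four post hoc properties characterize displacement and recovery of a
community after a pulse disturbance, all derived from the normalized
deviation trace d(t) with maximum d_max (first attained at t_max) and
final value d_end at t_end, measured from the reference sample at t_ref:

* resistance         RS = 1 - d_max                       (dimensionless, [0, 1])
* displacement speed DS = d_max / (t_max - t_ref)         (h^-1)
* resilience         RL = 2 * d_max / (d_max + d_end) - 1 (dimensionless, [0, 1])
* elasticity         E  = (d_max - d_end) / (t_end - t_max)  (h^-1, recovery only)

RS maps the normalized maximal deviation affinely so that an undisturbed
system scores 1 and a maximally displaced one scores 0.  RL is the
Orwin-Wardle recovery index evaluated at the trace end; because d_max is
the trace maximum, d_end <= d_max and the index cannot go negative, so
RL = 0 means no recovery at all and RL = 1 a perfect return.  E is the
mean speed of travel back from the maximally displaced state and is
reported as not-available (None) rather than zero when no recovery
occurred - zero would be a meaningful (null) speed.

For online monitoring, d_max is replaced by the running maximum M(t) of
the deviation encountered so far: the online resilience is 0 while the
system is still being pushed away (d(t) = M(t)) and positive once it
approaches the reference again; its final value coincides exactly with
the post hoc RL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .containers import EcologicalSituation
from .errors import UndefinedPropertyError
from .reference import DeviationTrace


def resistance(trace: DeviationTrace) -> float:
    """RS = 1 - d_max; close to 1 means essentially unchanged."""
    return 1.0 - trace.d_max


def displacement_speed(trace: DeviationTrace) -> float:
    """DS = d_max / (t_max - t_ref), in h^-1.

    Raises
    ------
    UndefinedPropertyError
        If the maximal deviation occurs at the reference sample itself
        (t_max = t_ref), leaving no displacement interval.
    """
    dt = trace.t_max - trace.t_ref
    if dt <= 0:
        raise UndefinedPropertyError(
            "displacement speed is undefined: maximal deviation occurs at the "
            "reference sample (t_max = t_ref)"
        )
    return trace.d_max / dt


def resilience(trace: DeviationTrace) -> float:
    """Orwin-Wardle recovery index at the trace end, in [0, 1].

    Raises
    ------
    UndefinedPropertyError
        If d_max = 0: the system never left the reference state, recovery
        is meaningless and RS = 1 already tells the whole story.
    """
    d_max = trace.d_max
    if d_max == 0:
        raise UndefinedPropertyError(
            "resilience is undefined for d_max = 0 (system never left the "
            "reference state; resistance is 1)"
        )
    return 2.0 * d_max / (d_max + trace.d_end) - 1.0


def elasticity(trace: DeviationTrace) -> Optional[float]:
    """Recovery speed E in h^-1, or None when no recovery was observed.

    Defined only when the trace actually travels back: d_end < d_max and
    t_end > t_max.
    """
    if trace.d_end < trace.d_max and trace.t_end > trace.t_max:
        return (trace.d_max - trace.d_end) / (trace.t_end - trace.t_max)
    return None


@dataclass(frozen=True)
class OnlineResilienceTrace:
    """Per-sample online resilience based on the running-maximum deviation."""

    times: np.ndarray
    running_max: np.ndarray
    rl_online: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "running_max", np.asarray(self.running_max, dtype=float))
        object.__setattr__(self, "rl_online", np.asarray(self.rl_online, dtype=float))


def online_resilience(trace: DeviationTrace) -> OnlineResilienceTrace:
    """Online resilience: RL with d_max replaced by the running maximum M(t).

    rl_online(t) = 0 wherever d(t) = M(t) (the deviation is at a new or
    tied maximum, i.e. the system is still being pushed away), otherwise
    2*M(t)/(M(t) + d(t)) - 1.  The final value equals the post hoc RL
    exactly, since M(t_end) = d_max.
    """
    d = trace.deviations
    m = np.maximum.accumulate(d)
    rl = np.zeros_like(d)
    improving = d < m
    rl[improving] = 2.0 * m[improving] / (m[improving] + d[improving]) - 1.0
    return OnlineResilienceTrace(times=trace.times, running_max=m, rl_online=rl)


@dataclass(frozen=True)
class StabilityReport:
    """Bundle of the four stability properties plus run metadata.

    ``displacement_speed`` and ``resilience`` are None when mathematically
    undefined (d_max at the reference sample, or d_max = 0 respectively);
    ``elasticity`` is None when no recovery was observed.
    """

    resistance: float
    displacement_speed: Optional[float]
    resilience: Optional[float]
    elasticity: Optional[float]
    resilient_flag: bool
    metric: str
    window_label: str = ""
    situation: EcologicalSituation = EcologicalSituation()
    reference_radius: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "RS": self.resistance,
            "DS": self.displacement_speed,
            "RL": self.resilience,
            "E": self.elasticity,
            "resilient": self.resilient_flag,
            "metric": self.metric,
            "window": self.window_label,
            "reference_radius": self.reference_radius,
        }


def summarize(
    trace: DeviationTrace,
    situation: Optional[EcologicalSituation] = None,
    reference_radius: Optional[float] = None,
) -> StabilityReport:
    """Aggregate RS, DS, RL and E for one disturbance window.

    Undefined component properties become None rather than aborting the
    report; the result is deterministic given the trace.
    """
    rs = resistance(trace)
    try:
        ds = displacement_speed(trace)
    except UndefinedPropertyError:
        ds = None
    try:
        rl = resilience(trace)
    except UndefinedPropertyError:
        rl = None
    e = elasticity(trace)
    return StabilityReport(
        resistance=rs,
        displacement_speed=ds,
        resilience=rl,
        elasticity=e,
        resilient_flag=bool(rl is not None and rl > 0),
        metric=trace.metric,
        window_label=trace.label,
        situation=situation if situation is not None else EcologicalSituation(),
        reference_radius=reference_radius,
    )
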