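"""Synthetic gate-abundance trajectories with known stability properties.

The generator emulates the canonical disturbance-response experiment of
cytometric community monitoring: a community at steady state, a pulse
disturbance that displaces the composition along a chord of the simplex,
optional partial exponential recovery, and compositional measurement
noise of the magnitude seen between technical replicates (mean per-gate
standard deviation of about 0.6%).

The noise-free mean state is the convex combination

    s(t) = (1 - alpha(t)) * s_base + alpha(t) * s_dist

with alpha(t) = 0 before onset, rising linearly to alpha_max at t_peak,
then decaying as alpha_max * exp(-k * (t - t_peak)).  Because states stay
on the simplex and alpha is monotone on each side of the peak, the
maximal deviation and the end deviation - hence resistance, displacement
speed, resilience and elasticity - are available in closed form for any
metric, which makes every downstream computation testable against an
analytic ground truth.

Measurement noise is Dirichlet: an observed state is drawn from
Dirichlet(c * s(t)) with concentration c, under which the per-gate
standard deviation is sqrt(s_i (1 - s_i) / (c + 1)).  The concentration
is calibrated so the mean per-gate sd matches a requested target
(default 0.006) rather than hard-coded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .containers import GateAbundanceSeries, as_composition
from .distances import DEFAULT_METRIC, distance
from .errors import ConfigurationError

#: Mean per-gate standard deviation of technical replicates in the
#: reference experiment (0.6% in abundance-fraction units).
REPLICATE_SD_TARGET = 0.006

#: Number of gates in the reference experiment's gate template.
DEFAULT_N_GATES = 34


def default_composition(n_gates: int = DEFAULT_N_GATES, decay: float = 0.85) -> np.ndarray:
    """Geometric rank-abundance baseline composition.

    A geometric series with ratio *decay* gives a realistic uneven
    community: for 34 gates the dominant gate holds ~15% of cells, the
    rarest ~0.07%, and the average share is 1/34 = 2.94% - in the range
    observed for cytometric gate templates of mixed communities.
    """
    if n_gates < 1:
        raise ConfigurationError("need at least one gate")
    if not 0 < decay < 1:
        raise ConfigurationError("decay must be in (0, 1)")
    p = decay ** np.arange(n_gates, dtype=float)
    return p / p.sum()


def displaced_composition(s_base) -> np.ndarray:
    """A fully displaced counterpart of *s_base*: the rank order reversed.

    Reversal keeps the abundance spectrum identical while rearranging
    which gates are dominant, mimicking a disturbance that restructures
    the community without changing its evenness.
    """
    s = np.asarray(s_base, dtype=float)
    return s[::-1].copy()


def shifted_composition(s_base, fraction: float = 0.5) -> np.ndarray:
    """Mildly perturbed counterpart of *s_base*: mass moved between the two
    dominant gates.

    Unlike a full rank reversal, this leaves rare gates untouched, so even
    the rare-gate-sensitive Canberra deviation stays small - the shape of a
    disturbance a community essentially shrugs off.
    """
    s = np.asarray(s_base, dtype=float).copy()
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must be in (0, 1]")
    i, j = np.argsort(s)[-1], np.argsort(s)[-2]
    moved = fraction * s[i]
    s[i] -= moved
    s[j] += moved
    return s


def concentration_for_sd(s_mean, target_sd: float) -> float:
    """Dirichlet concentration giving a requested mean per-gate sd.

    Under Dirichlet(c * p) the sd of component i is
    sqrt(p_i (1 - p_i) / (c + 1)); solving
    mean_i sqrt(p_i (1 - p_i)) / sqrt(c + 1) = target_sd for c gives the
    calibration.
    """
    if target_sd <= 0:
        raise ConfigurationError("target sd must be positive")
    p = np.asarray(s_mean, dtype=float)
    scale = float(np.mean(np.sqrt(p * (1.0 - p))))
    c = (scale / target_sd) ** 2 - 1.0
    if c <= 0:
        raise ConfigurationError(
            f"target sd {target_sd} is too large for this composition (would need "
            f"concentration <= 0)"
        )
    return c


@dataclass(frozen=True)
class SyntheticTrajectoryConfig:
    """Parameters of one synthetic disturbance-response trajectory.

    Defaults describe the reference experimental conditions: a 34-gate
    uneven steady-state community, a pulse disturbance at 24 h ramping to
    full displacement within 6 h (pulse alterations in such experiments
    last 2-11 h), slow partial recovery (k = 0.005 h^-1) observed every
    3 h up to 120 h, and technical noise calibrated to a 0.6% mean
    per-gate sd.  Set ``noise_target_sd=None`` (and leave
    ``noise_concentration`` unset) for a noise-free trajectory.
    """

    n_gates: int = DEFAULT_N_GATES
    s_base: Optional[np.ndarray] = None
    s_dist: Optional[np.ndarray] = None
    alpha_max: float = 1.0
    t_onset: float = 24.0
    t_peak: float = 30.0
    recovery_rate: float = 0.005
    noise_target_sd: Optional[float] = REPLICATE_SD_TARGET
    noise_concentration: Optional[float] = None
    sampling_times: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        s_base = (
            default_composition(self.n_gates)
            if self.s_base is None
            else as_composition(self.s_base)
        )
        s_dist = (
            displaced_composition(s_base) if self.s_dist is None else as_composition(self.s_dist)
        )
        if s_base.size != s_dist.size:
            raise ConfigurationError("s_base and s_dist must have the same length")
        object.__setattr__(self, "n_gates", int(s_base.size))
        object.__setattr__(self, "s_base", s_base)
        object.__setattr__(self, "s_dist", s_dist)
        times = (
            np.arange(0.0, 120.0 + 1e-9, 3.0)
            if self.sampling_times is None
            else np.asarray(self.sampling_times, dtype=float)
        )
        if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
            raise ConfigurationError("sampling_times must be strictly increasing, length >= 2")
        object.__setattr__(self, "sampling_times", times)
        if not 0.0 <= self.alpha_max <= 1.0:
            raise ConfigurationError("alpha_max must lie in [0, 1]")
        if not self.t_onset < self.t_peak:
            raise ConfigurationError("t_onset must precede t_peak")
        if self.recovery_rate < 0:
            raise ConfigurationError("recovery_rate must be >= 0")
        if self.alpha_max > 0 and np.array_equal(s_base, s_dist):
            raise ConfigurationError("s_dist must differ from s_base when alpha_max > 0")
        if times[0] > self.t_onset or times[-1] < self.t_peak:
            raise ConfigurationError("sampling_times must span from before onset to beyond t_peak")
        if self.noise_concentration is not None and self.noise_concentration <= 0:
            raise ConfigurationError("noise_concentration must be positive")

    # -- derived -----------------------------------------------------------
    @property
    def noise_free(self) -> bool:
        return self.noise_concentration is None and self.noise_target_sd is None

    def concentration(self) -> Optional[float]:
        """Effective Dirichlet concentration (None when noise-free)."""
        if self.noise_concentration is not None:
            return float(self.noise_concentration)
        if self.noise_target_sd is None:
            return None
        return concentration_for_sd(self.s_base, self.noise_target_sd)

    def alpha(self, t) -> np.ndarray:
        """Displacement fraction alpha(t): 0, linear ramp, exponential decay."""
        t = np.asarray(t, dtype=float)
        ramp = self.alpha_max * (t - self.t_onset) / (self.t_peak - self.t_onset)
        decay = self.alpha_max * np.exp(-self.recovery_rate * (t - self.t_peak))
        return np.where(t < self.t_onset, 0.0, np.where(t <= self.t_peak, ramp, decay))

    def mean_state(self, t: float) -> np.ndarray:
        a = float(self.alpha(t))
        return (1.0 - a) * self.s_base + a * self.s_dist


def _dirichlet_around(rng: np.random.Generator, p: np.ndarray, c: float) -> np.ndarray:
    """One Dirichlet(c*p) draw, tolerating exact zeros in p (they stay zero)."""
    x = np.zeros_like(p)
    mask = p > 0
    g = rng.gamma(shape=c * p[mask])
    total = g.sum()
    if total == 0:  # pragma: no cover - essentially impossible at calibrated c
        x[mask] = p[mask]
        return x
    x[mask] = g / total
    return x


def simulate_trajectory(config: SyntheticTrajectoryConfig) -> GateAbundanceSeries:
    """Generate a gate-abundance series from a trajectory configuration.

    Deterministic for a fixed seed; every row is non-negative and sums to 1.
    """
    rng = np.random.default_rng(config.seed)
    c = config.concentration()
    rows = []
    for t in config.sampling_times:
        mean = config.mean_state(float(t))
        if c is None:
            row = mean
        else:
            row = _dirichlet_around(rng, mean, c)
        rows.append(row / row.sum())
    gate_ids = tuple(f"G{i + 1:02d}" for i in range(config.n_gates))
    return GateAbundanceSeries(
        times=config.sampling_times, gate_ids=gate_ids, abundances=np.asarray(rows)
    )


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form stability properties of the noise-free trajectory."""

    expected_d_max: float
    expected_t_max: float
    expected_d_end: float
    expected_RS: float
    expected_RL: Optional[float]
    metric: str
    t_end: float


def analytic_ground_truth(
    config: SyntheticTrajectoryConfig,
    metric: str = DEFAULT_METRIC,
    t_end: Optional[float] = None,
) -> GroundTruth:
    """Exact stability properties of the noise-free mean trajectory.

    Both metrics are monotone in the displacement fraction along the
    s_base -> s_dist chord, so the maximal deviation occurs at t_peak with
    displacement alpha_max, and the end deviation follows from alpha(t_end).
    expected_RL is None when alpha_max = 0 (the system never moves).
    """
    if t_end is None:
        t_end = float(config.sampling_times[-1])
    if t_end < config.t_peak:
        raise ConfigurationError("t_end must be at or after t_peak")
    a_max = config.alpha_max
    d_max = distance(config.s_base, config.mean_state(config.t_peak), metric)
    a_end = float(config.alpha(t_end))
    d_end = distance(
        config.s_base, (1.0 - a_end) * config.s_base + a_end * config.s_dist, metric
    )
    rs = 1.0 - d_max
    rl = None if d_max == 0 else 2.0 * d_max / (d_max + d_end) - 1.0
    return GroundTruth(
        expected_d_max=d_max,
        expected_t_max=float(config.t_peak),
        expected_d_end=d_end,
        expected_RS=rs,
        expected_RL=rl,
        metric=metric,
        t_end=float(t_end),
    )


def make_reference_replicates(
    s_base,
    m: int,
    seed: int = 0,
    target_sd: float = REPLICATE_SD_TARGET,
    noise_concentration: Optional[float] = None,
) -> np.ndarray:
    """m noisy technical-replicate measurements of the same composition.

    Noise is Dirichlet with concentration calibrated so the mean per-gate
    standard deviation approximates *target_sd* (default 0.6%).  With
    ``noise_concentration=math.inf`` the replicates are exact copies.
    Returns an (m, n) matrix.
    """
    if m < 1:
        raise ConfigurationError("need at least one replicate")
    p = as_composition(s_base)
    if noise_concentration is not None and math.isinf(noise_concentration):
        return np.tile(p, (m, 1))
    c = noise_concentration if noise_concentration is not None else concentration_for_sd(p, target_sd)
    rng = np.random.default_rng(seed)
    return np.asarray([_dirichlet_around(rng, p, c) for _ in range(m)])


# -- canonical response scenarios -----------------------------------------

#: Qualitative disturbance-response archetypes, keyed by scenario name:
#: "within_reference"  - high resistance, never exits the reference space;
#: "full_return"       - exits and returns inside the radius (RL near 1);
#: "partial_recovery"  - approaches but ends outside (0 < RL < 1, E defined);
#: "no_recovery"       - deviation plateaus at its maximum (RL = 0, no E).
SCENARIOS = ("within_reference", "full_return", "partial_recovery", "no_recovery")

_SCENARIO_PARAMS = {
    "within_reference": dict(alpha_max=1.0, recovery_rate=0.005),
    "full_return": dict(alpha_max=1.0, recovery_rate=0.05),
    "partial_recovery": dict(alpha_max=1.0, recovery_rate=0.005),
    "no_recovery": dict(alpha_max=1.0, recovery_rate=0.0),
}


def scenario_config(name: str, **overrides) -> SyntheticTrajectoryConfig:
    """Noise-free configuration reproducing one canonical response shape."""
    if name not in _SCENARIO_PARAMS:
        raise ConfigurationError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    params = dict(_SCENARIO_PARAMS[name])
    params.setdefault("noise_target_sd", None)
    if name == "within_reference" and "s_dist" not in overrides:
        # a displacement among dominant gates only: stays near the reference
        n = overrides.get("n_gates", DEFAULT_N_GATES)
        base = overrides.get("s_base", default_composition(n))
        params["s_dist"] = shifted_composition(base)
    params.update(overrides)
    return SyntheticTrajectoryConfig(**params)
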