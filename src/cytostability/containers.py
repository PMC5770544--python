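"""In-memory containers for gate-abundance time series and run metadata.

A cytometric fingerprint reduces each sample to the relative abundances of a
fixed set of gate populations (subclusters in a forward-scatter x DNA-content
dot plot).  A monitored experiment is then a time-indexed matrix of such
compositions: one row per sampling time, one column per gate, rows on the
unit simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputDataError

#: Default tolerance for "this row sums to one".
COMPOSITION_SUM_TOL = 1e-6

#: Recognized disturbance kinds.
DISTURBANCE_KINDS = ("temperature", "pH", "invasion", "other")


def as_composition(values: Iterable[float], tol: float = COMPOSITION_SUM_TOL) -> np.ndarray:
    """Coerce *values* to a valid community state (composition vector).

    Entries must be non-negative and sum to 1 within *tol*; the returned
    vector is renormalized to sum to exactly 1 (removing floating-point
    drift before any distance computation).

    Raises
    ------
    InputDataError
        If entries are negative, non-finite, or the sum is off by more
        than *tol*.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise InputDataError("a community state must be a 1-D vector with at least one gate")
    if not np.all(np.isfinite(v)):
        raise InputDataError("community state contains non-finite entries")
    if np.any(v < 0):
        i = int(np.argmin(v))
        raise InputDataError(f"negative abundance {v[i]!r} at gate index {i}")
    total = v.sum()
    if abs(total - 1.0) > tol:
        raise InputDataError(f"abundances sum to {total!r}, deviating from 1 by more than {tol}")
    return v / total


@dataclass(frozen=True)
class GateAbundanceSeries:
    """Time series of relative gate abundances: the system states s(t).

    Parameters
    ----------
    times
        Sampling times in hours, strictly increasing.
    gate_ids
        Ordered labels of the n gate populations.
    abundances
        Matrix of shape (len(times), len(gate_ids)) with relative abundance
        fractions; each row is a community state summing to 1.
    """

    times: np.ndarray
    gate_ids: tuple
    abundances: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        abund = np.asarray(self.abundances, dtype=float)
        gate_ids = tuple(str(g) for g in self.gate_ids)
        if abund.ndim != 2:
            raise InputDataError("abundances must be a 2-D matrix (times x gates)")
        if times.ndim != 1 or len(times) != abund.shape[0]:
            raise InputDataError(
                f"{len(times)} sampling times but {abund.shape[0]} abundance rows"
            )
        if len(gate_ids) != abund.shape[1]:
            raise InputDataError(
                f"{len(gate_ids)} gate labels but {abund.shape[1]} abundance columns"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "gate_ids", gate_ids)
        object.__setattr__(self, "abundances", abund)

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def n_gates(self) -> int:
        return len(self.gate_ids)

    def state(self, index: int) -> np.ndarray:
        """Community state (row vector) at sample *index*."""
        return self.abundances[index]

    def last_index_before(self, t: float) -> int:
        """Index of the last sample strictly before time *t* (or -1)."""
        idx = np.searchsorted(self.times, t, side="left") - 1
        return int(idx)

    def window_indices(self, start: float, end: float) -> np.ndarray:
        """Indices of samples with start <= time <= end."""
        return np.nonzero((self.times >= start) & (self.times <= end))[0]

    # -- pandas bridge -----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.abundances, columns=list(self.gate_ids))
        df.insert(0, "time_h", self.times)
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        mode: str = "fractions",
        tolerance: float = COMPOSITION_SUM_TOL,
    ) -> "GateAbundanceSeries":
        """Build a series from a table whose first column is time in hours.

        ``mode="counts"`` divides each row by its row sum; ``mode="fractions"``
        rejects rows whose sum deviates from 1 by more than *tolerance* and
        renormalizes the rest to sum exactly 1.
        """
        if df.shape[1] < 2:
            raise InputDataError("table needs a time column and at least one gate column")
        time_col = df.columns[0]
        times = pd.to_numeric(df[time_col], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(times)):
            bad = int(np.nonzero(~np.isfinite(times))[0][0])
            raise InputDataError(f"non-numeric or missing time at row {bad}")
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            i = int(np.nonzero(diffs <= 0)[0][0])
            kind = "duplicate" if diffs[i] == 0 else "decreasing"
            raise InputDataError(
                f"{kind} sampling time at rows {i} and {i + 1} "
                f"(t={times[i]!r}, t={times[i + 1]!r}); times must be strictly increasing"
            )
        try:
            values = df.iloc[:, 1:].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise InputDataError(f"non-numeric abundance entry: {exc}") from exc
        if np.any(~np.isfinite(values)):
            r, c = map(int, np.argwhere(~np.isfinite(values))[0])
            raise InputDataError(f"non-finite abundance at row {r}, column {df.columns[c + 1]!r}")
        if np.any(values < 0):
            r, c = map(int, np.argwhere(values < 0)[0])
            raise InputDataError(
                f"negative abundance {values[r, c]!r} at row {r}, column {df.columns[c + 1]!r}"
            )

        if mode == "counts":
            row_sums = values.sum(axis=1)
            zero = np.nonzero(row_sums == 0)[0]
            if zero.size:
                raise InputDataError(f"all-zero count row at row {int(zero[0])}")
            fractions = values / row_sums[:, None]
        elif mode == "fractions":
            row_sums = values.sum(axis=1)
            off = np.nonzero(np.abs(row_sums - 1.0) > tolerance)[0]
            if off.size:
                r = int(off[0])
                raise InputDataError(
                    f"row {r} sums to {row_sums[r]!r}, deviating from 1 by more than "
                    f"the tolerance {tolerance}"
                )
            fractions = values / row_sums[:, None]
        else:
            raise ConfigurationError(f"unknown table mode {mode!r}; use 'fractions' or 'counts'")

        return cls(times=times, gate_ids=tuple(df.columns[1:]), abundances=fractions)


@dataclass(frozen=True)
class DisturbanceAnnotation:
    """One disturbance event and the observation window attributed to it."""

    label: str
    onset_time: float
    window_end: float
    kind: str = "other"

    def __post_init__(self) -> None:
        kind = str(self.kind)
        canonical = {k.lower(): k for k in DISTURBANCE_KINDS}
        if kind.lower() not in canonical:
            raise ConfigurationError(
                f"disturbance kind {kind!r} not in {DISTURBANCE_KINDS}"
            )
        object.__setattr__(self, "kind", canonical[kind.lower()])
        if not self.onset_time < self.window_end:
            raise ConfigurationError(
                f"disturbance {self.label!r}: onset ({self.onset_time}) must precede "
                f"window end ({self.window_end})"
            )


def check_windows_disjoint(windows: Sequence[DisturbanceAnnotation]) -> list:
    """Sort windows by onset and verify that successive windows do not overlap."""
    ordered = sorted(windows, key=lambda w: w.onset_time)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.onset_time < prev.window_end:
            raise ConfigurationError(
                f"disturbance windows {prev.label!r} and {nxt.label!r} overlap "
                f"({nxt.onset_time} < {prev.window_end})"
            )
    return ordered


@dataclass(frozen=True)
class EcologicalSituation:
    """Six-feature description of the ecological context of a stability claim.

    Stability statements are only interpretable relative to an explicitly
    stated situation; the six features record, in free text, the level of
    description, the variable of interest, the reference, the disturbance,
    and the temporal and spatial scales of the experiment.  All six are
    carried into every report.
    """

    level_of_description: str = ""
    variable_of_interest: str = ""
    reference_description: str = ""
    disturbance_description: str = ""
    temporal_scale: str = ""
    spatial_scale: str = ""

    FIELDS = (
        "level_of_description",
        "variable_of_interest",
        "reference_description",
        "disturbance_description",
        "temporal_scale",
        "spatial_scale",
    )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.FIELDS}
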