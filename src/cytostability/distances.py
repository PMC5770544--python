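"""Bounded distances between community compositions.

Two metrics quantify how far a community state has moved, both normalized
to [0, 1] so that deviations from a reference are directly comparable
across experiments:

* the scaled Euclidean distance
  ``d_e(a, b) = sqrt((1/2) * sum_i (b_i - a_i)**2)``,
  which weights gates by absolute abundance change, and
* the normalized Canberra distance
  ``d_c(a, b) = (1/n) * sum_i |a_i - b_i| / (a_i + b_i)``,
  which evaluates each gate's change relative to its summed abundance and
  therefore registers the doubling or extinction of a rare population as
  strongly as an equal absolute shift in a dominant one.

The 1/2 factor sits inside the square root: for two disjoint compositions
(e.g. (1,0) vs (0,1)) the sum of squares is 2 and d_e attains exactly 1,
which is the stated upper bound.  A Canberra term with a_i + b_i = 0 (a
gate absent from both states) contributes 0, keeping d_c(a, a) = 0 and
d_c <= 1.

The Canberra distance is the recommended default for community monitoring.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError, DimensionMismatchError

DEFAULT_METRIC = "canberra"
SUPPORTED_METRICS = ("canberra", "euclidean")


def _check_pair(a, b) -> tuple:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise DimensionMismatchError("community states must be 1-D vectors")
    if a.shape != b.shape:
        raise DimensionMismatchError(
            f"community states have different lengths ({a.size} vs {b.size})"
        )
    if a.size < 1:
        raise DimensionMismatchError("community states must have at least one gate")
    return a, b


def euclidean_distance(a, b) -> float:
    """Scaled Euclidean distance between two composition vectors, in [0, 1]."""
    a, b = _check_pair(a, b)
    return float(np.sqrt(0.5 * np.sum((b - a) ** 2)))


def canberra_distance(a, b) -> float:
    """Normalized Canberra distance between two composition vectors, in [0, 1].

    Gates absent from both states (a_i + b_i = 0) contribute 0.
    """
    a, b = _check_pair(a, b)
    denom = a + b
    mask = denom > 0
    n = a.size
    return float(np.sum(np.abs(a[mask] - b[mask]) / denom[mask]) / n)


_METRIC_FUNCS = {
    "euclidean": euclidean_distance,
    "canberra": canberra_distance,
}


def distance(a, b, metric: str = DEFAULT_METRIC) -> float:
    """Dispatch to the chosen metric (default: normalized Canberra)."""
    try:
        func = _METRIC_FUNCS[metric]
    except KeyError:
        raise ConfigurationError(
            f"unknown metric {metric!r}; supported: {SUPPORTED_METRICS}"
        ) from None
    return func(a, b)
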