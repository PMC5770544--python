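"""Model/results interface tying the whole stability workflow together.

:class:`StabilityModel` holds a gate-abundance series, its disturbance
annotations and the analysis configuration; :meth:`StabilityModel.fit`
runs the workflow for every annotated disturbance window - build the
predisturbance reference space, check constancy, compute the deviation
trace and its boundary crossings, and derive the four stability
properties plus the online-resilience monitor - and returns a
:class:`StabilityResults` carrying the per-window estimates, a summary
table, and plotting/export helpers.

Reference modes
---------------
``last-sample``
    The reference state is the last sample before each window's onset
    (the convention for consecutive pulse disturbances on one run).
    With a single sample no radius can be derived, so ``fallback_radius``
    is required - typically precomputed from technical replicates.
``preceding-samples``
    All samples between the previous window's end (or the series start)
    and the onset form the reference set; the radius is their maximal
    deviation from the mean.
``replicates``
    An explicit sample set (e.g. technical replicates) supplied as
    ``reference_samples`` defines mean, sigma and radius, identically for
    every window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import (
    DisturbanceAnnotation,
    EcologicalSituation,
    GateAbundanceSeries,
)
from .distances import DEFAULT_METRIC, SUPPORTED_METRICS
from .errors import ConfigurationError, CytostabilityError
from .io import validate_series, write_stability_report
from .metrics import (
    OnlineResilienceTrace,
    StabilityReport,
    online_resilience,
    summarize,
)
from .reference import (
    DEFAULT_CONSTANCY_THRESHOLD,
    ConstancyResult,
    DeviationTrace,
    ReferenceSpace,
    boundary_crossings,
    build_reference,
    constancy_check,
    deviation_trace,
)

REFERENCE_MODES = ("last-sample", "preceding-samples", "replicates")


@dataclass(frozen=True)
class WindowResult:
    """Everything computed for one disturbance window."""

    window: DisturbanceAnnotation
    reference: ReferenceSpace
    constancy: ConstancyResult
    trace: DeviationTrace
    crossings: list
    online: OnlineResilienceTrace
    report: StabilityReport

    @property
    def exited(self) -> bool:
        return any(direction == "exit" for _, direction in self.crossings)

    @property
    def returned(self) -> bool:
        return any(direction == "return" for _, direction in self.crossings)


class StabilityModel:
    """Stability-property analysis of a gate-abundance time series.

    Parameters
    ----------
    series
        The gate-abundance time series (states s(t)).
    disturbances
        Disturbance annotations; windows must not overlap.  Each window is
        clipped to the earlier of its annotated end, the next window's
        onset, and the series end.
    metric
        ``"canberra"`` (default, recommended) or ``"euclidean"``.
    reference_mode, reference_samples, fallback_radius
        See module docstring.
    constancy_threshold
        Bound on the mean per-gate reference sd for the constancy verdict.
    situation
        Six-feature ecological-situation metadata carried into reports.
    """

    def __init__(
        self,
        series: GateAbundanceSeries,
        disturbances: Sequence[DisturbanceAnnotation],
        *,
        metric: str = DEFAULT_METRIC,
        reference_mode: str = "last-sample",
        reference_samples=None,
        fallback_radius: Optional[float] = None,
        constancy_threshold: float = DEFAULT_CONSTANCY_THRESHOLD,
        situation: Optional[EcologicalSituation] = None,
    ) -> None:
        if metric not in SUPPORTED_METRICS:
            raise ConfigurationError(f"unknown metric {metric!r}; supported: {SUPPORTED_METRICS}")
        if reference_mode not in REFERENCE_MODES:
            raise ConfigurationError(
                f"unknown reference mode {reference_mode!r}; supported: {REFERENCE_MODES}"
            )
        if reference_mode == "replicates" and reference_samples is None:
            raise ConfigurationError("reference_mode='replicates' requires reference_samples")
        issues = validate_series(series)
        if issues:
            raise ConfigurationError(
                "input series fails validation:\n  " + "\n  ".join(issues)
            )
        if not disturbances:
            raise ConfigurationError("at least one disturbance annotation is required")
        self.series = series
        # sort by onset; fit() clips each window at the next onset, so an
        # annotated end running past the following disturbance is tolerated
        self.disturbances = sorted(disturbances, key=lambda w: w.onset_time)
        self.metric = metric
        self.reference_mode = reference_mode
        self.reference_samples = (
            None if reference_samples is None else np.asarray(reference_samples, dtype=float)
        )
        self.fallback_radius = fallback_radius
        self.constancy_threshold = constancy_threshold
        self.situation = situation if situation is not None else EcologicalSituation()

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        disturbances: pd.DataFrame,
        mode: str = "fractions",
        **kwargs,
    ) -> "StabilityModel":
        """Build a model from pandas tables (same layouts as the file formats)."""
        series = GateAbundanceSeries.from_dataframe(table, mode=mode)
        windows = [
            DisturbanceAnnotation(
                label=str(row["label"]),
                kind=str(row.get("kind", "other")),
                onset_time=float(row["onset_h"]),
                window_end=float(row["window_end_h"]),
            )
            for _, row in disturbances.iterrows()
        ]
        return cls(series, windows, **kwargs)

    # -----------------------------------------------------------------
    def _reference_for(self, window: DisturbanceAnnotation, prev_end: float) -> ReferenceSpace:
        series = self.series
        if self.reference_mode == "replicates":
            return build_reference(
                list(self.reference_samples), self.metric, self.fallback_radius
            )
        ref_idx = series.last_index_before(window.onset_time)
        if ref_idx < 0:
            raise CytostabilityError(
                f"no sample before onset {window.onset_time} for window {window.label!r}"
            )
        if self.reference_mode == "last-sample":
            samples = [series.state(ref_idx)]
        else:  # preceding-samples
            idx = np.nonzero((series.times > prev_end) & (series.times < window.onset_time))[0]
            samples = [series.state(i) for i in idx] or [series.state(ref_idx)]
        return build_reference(samples, self.metric, self.fallback_radius)

    def _clip_window(
        self, window: DisturbanceAnnotation, next_onset: Optional[float]
    ) -> DisturbanceAnnotation:
        end = min(window.window_end, float(self.series.times[-1]))
        if next_onset is not None:
            end = min(end, next_onset)
        if end <= window.onset_time:
            raise CytostabilityError(
                f"window {window.label!r} is empty after clipping to the series range"
            )
        if end == window.window_end:
            return window
        return DisturbanceAnnotation(
            label=window.label, kind=window.kind, onset_time=window.onset_time, window_end=end
        )

    def fit(self) -> "StabilityResults":
        """Run the full workflow for every annotated disturbance window."""
        results: List[WindowResult] = []
        prev_end = -np.inf
        for i, window in enumerate(self.disturbances):
            next_onset = (
                self.disturbances[i + 1].onset_time if i + 1 < len(self.disturbances) else None
            )
            clipped = self._clip_window(window, next_onset)
            ref = self._reference_for(clipped, prev_end)
            trace = deviation_trace(self.series, ref, clipped)
            results.append(
                WindowResult(
                    window=clipped,
                    reference=ref,
                    constancy=constancy_check(ref, self.constancy_threshold),
                    trace=trace,
                    crossings=boundary_crossings(trace, ref),
                    online=online_resilience(trace),
                    report=summarize(trace, self.situation, reference_radius=ref.radius),
                )
            )
            prev_end = clipped.window_end
        return StabilityResults(self, results)


class StabilityResults:
    """Fitted stability properties for every disturbance window.

    Iterable over :class:`WindowResult`; ``summary()`` renders a text
    table, ``summary_frame()`` the same as a DataFrame, ``save_reports``
    writes one report file per window, and ``plot`` draws the
    deviation-over-time figure for one window.
    """

    def __init__(self, model: StabilityModel, windows: List[WindowResult]) -> None:
        self.model = model
        self.windows = windows

    def __iter__(self):
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)

    def __getitem__(self, i) -> WindowResult:
        return self.windows[i]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.windows:
            rows.append(
                {
                    "window": w.window.label,
                    "kind": w.window.kind,
                    "onset_h": w.window.onset_time,
                    "end_h": w.window.window_end,
                    "metric": w.trace.metric,
                    "radius": w.reference.radius,
                    "mean_sigma_ref": w.constancy.mean_sigma,
                    "constant": w.constancy.constant,
                    "d_max": w.trace.d_max,
                    "t_max_h": w.trace.t_max,
                    "d_end": w.trace.d_end,
                    "RS": w.report.resistance,
                    "DS_per_h": w.report.displacement_speed,
                    "RL": w.report.resilience,
                    "E_per_h": w.report.elasticity,
                    "resilient": w.report.resilient_flag,
                    "exited": w.exited,
                    "returned": w.returned,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary table of the fitted stability properties."""
        df = self.summary_frame()
        lines = [
            "Community stability properties",
            "=" * 78,
            f"metric: {self.model.metric}    reference mode: {self.model.reference_mode}"
            f"    windows: {len(self.windows)}",
        ]
        situation = self.model.situation.as_dict()
        if any(situation.values()):
            lines.append("-" * 78)
            for key, value in situation.items():
                if value:
                    lines.append(f"{key.replace('_', ' ')}: {value}")
        lines.append("-" * 78)
        cols = ["window", "RS", "DS_per_h", "RL", "E_per_h", "radius", "d_max", "t_max_h"]
        with pd.option_context("display.float_format", lambda v: f"{v:.4g}"):
            lines.append(df[cols].to_string(index=False, na_rep="NA"))
        lines.append("=" * 78)
        return "\n".join(lines)

    def save_reports(self, out_dir) -> List[Path]:
        """Write one report file per window plus a summary table; returns paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, w in enumerate(self.windows):
            label = w.window.label.replace(" ", "_").replace("/", "-") or f"window{i}"
            path = out_dir / f"report_{i:02d}_{label}.csv"
            write_stability_report(w.report, w.trace, path)
            paths.append(path)
        summary_path = out_dir / "summary.csv"
        self.summary_frame().to_csv(summary_path, index=False)
        paths.append(summary_path)
        return paths

    def plot(self, index: int = 0, path=None, ax=None):
        """Deviation-over-time figure for window *index* (see plotting module)."""
        from .plotting import plot_deviation

        w = self.windows[index]
        return plot_deviation(w.trace, w.reference, path=path, ax=ax)
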