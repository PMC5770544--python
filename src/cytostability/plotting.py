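"""Deviation-over-time plots with machine-checkable sidecars.

The figure mirrors the standard monitoring view: d(t) against time, a
dashed horizontal line at the reference-space radius, the reference
sample as an open red circle, the maximally deviating sample as a blue
triangle, and the final sample as a filled black circle.  Next to every
image a ``.csv`` sidecar records the plotted numbers so graphical
elements can be tested without pixel comparison.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

from .metrics import online_resilience
from .reference import DeviationTrace, ReferenceSpace


def plot_deviation(trace: DeviationTrace, ref: ReferenceSpace, path=None, ax=None):
    """Render one deviation trace; optionally save to *path* (+ sidecar).

    Returns the matplotlib Axes.  When *path* is given, also writes
    ``<path>.csv`` with the plotted series and marker coordinates.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ax.plot(trace.times, trace.deviations, "-", color="0.2", lw=1.2, zorder=2)
    ax.axhline(ref.radius, color="green", ls="--", lw=1.0, label=f"reference radius r={ref.radius:.3g}")
    ax.plot([trace.t_ref], [trace.deviations[0]], "o", mfc="none", mec="red", ms=9, label="reference sample")
    ax.plot([trace.t_max], [trace.d_max], "^", color="tab:blue", ms=9, label="maximal deviation")
    ax.plot([trace.t_end], [trace.d_end], "o", color="black", ms=7, label="final state")
    ax.set_xlabel("time (h)")
    ax.set_ylabel(f"deviation d(t) ({trace.metric})")
    ax.set_ylim(0, max(1.05 * max(trace.d_max, ref.radius), 0.05))
    title = trace.label or "disturbance response"
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    if path is not None:
        path = Path(path)
        try:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        except OSError as exc:
            raise OSError(f"could not write plot to {path}: {exc}") from exc
        _write_sidecar(trace, ref, path.with_suffix(path.suffix + ".csv"))
        plt.close(ax.figure)
    return ax


def _write_sidecar(trace: DeviationTrace, ref: ReferenceSpace, sidecar_path: Path) -> None:
    online = online_resilience(trace)
    df = pd.DataFrame(
        {
            "time_h": trace.times,
            "deviation": trace.deviations,
            "running_max": online.running_max,
            "rl_online": online.rl_online,
        }
    )
    df["radius"] = ref.radius
    df["t_max"] = trace.t_max
    df["d_max"] = trace.d_max
    df["t_end"] = trace.t_end
    df["d_end"] = trace.d_end
    df.to_csv(sidecar_path, index=False)
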