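"""Visual-inspection plots: block panels and before/after overlays.

Visual inspection works on blocks of 200 beats plotted against beat index;
flagged beats are annotated so the analyst can accept or override the
algorithm's verdicts.  The overlay plot draws the corrected trace against
the ORIGINAL beat index, so deleted beats appear as gaps — never as a shift
of the remaining trace.

Axis labels use 1-based beat numbers (the convention of printed inspection
sheets); all files and logs stay 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import matplotlib

if matplotlib.get_backend().lower() not in ("agg", "module://matplotlib_inline.backend_inline"):
    matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .pipeline import ScanResult
from .series import BeatSeries, CorrectionLog

__all__ = ["PlotSpec", "plot_blocks", "plot_overlay"]


@dataclass(frozen=True)
class PlotSpec:
    """Styling and layout of the inspection plots."""

    block_size: int = 200
    overlay: bool = True
    before_color: str = "red"
    after_color: str = "blue"
    annotate_flags: bool = True

    def __post_init__(self) -> None:
        if self.block_size < 50:
            raise ValueError("block_size must be at least 50 beats")
        for c in (self.before_color, self.after_color):
            try:
                matplotlib.colors.to_rgb(c)
            except ValueError:
                raise ValueError(f"invalid color name {c!r}") from None


def plot_blocks(
    series: BeatSeries,
    scan_result: Optional[ScanResult],
    spec: PlotSpec,
    outdir: Path,
) -> List[Tuple[Path, plt.Figure]]:
    """Plot the series in consecutive blocks, one panel per file.

    Returns the written paths together with the figures (the figures stay
    open so callers/tests can inspect the data layer; close them when done).
    """
    if len(series) == 0:
        raise ValueError("cannot plot an empty series")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bpm = series.to("bpm").values
    flagged = set(scan_result.flagged_indices) if scan_result else set()
    n_panels = math.ceil(len(series) / spec.block_size)
    out: List[Tuple[Path, plt.Figure]] = []
    for p in range(n_panels):
        lo = p * spec.block_size
        hi = min(len(series), lo + spec.block_size)
        idx = np.arange(lo, hi)
        fig, ax = plt.subplots(figsize=(10, 3))
        ax.plot(idx + 1, bpm[lo:hi], lw=0.8, color="0.3", marker=".", ms=2)
        if spec.annotate_flags:
            for i in sorted(f for f in flagged if lo <= f < hi):
                ax.plot([i + 1], [bpm[i]], "o", color=spec.before_color, ms=5)
                ax.annotate(
                    f"{i + 1}: {bpm[i]:.0f}",
                    xy=(i + 1, bpm[i]),
                    textcoords="offset points",
                    xytext=(3, 6),
                    fontsize=7,
                )
        ax.set_xlabel("beat number (1-based)")
        ax.set_ylabel("HR (bpm)")
        ax.set_title(f"{series.label or 'series'} — beats {lo + 1}–{hi}")
        path = outdir / f"block_{p + 1:03d}.png"
        fig.savefig(path, dpi=110)
        out.append((path, fig))
    return out


def plot_overlay(
    before: BeatSeries,
    after_log: CorrectionLog,
    spec: PlotSpec,
    path: Path,
) -> plt.Figure:
    """Overlay the original and corrected traces on the original beat axis.

    The corrected trace is derived by replaying ``after_log`` on ``before``;
    deleted beats are simply absent from it (gaps), so the after-trace can
    never be longer than the before-trace.
    """
    corrected = after_log.replay(before)  # raises if the log does not fit
    surviving = after_log.surviving_indices()
    bpm_before = before.to("bpm").values
    bpm_after = corrected.to("bpm").values
    fig, ax = plt.subplots(figsize=(10, 3))
    x_before = np.arange(len(before)) + 1
    ax.plot(x_before, bpm_before, color=spec.before_color, lw=0.8,
            label="before correction")
    ax.plot(surviving + 1, bpm_after, color=spec.after_color, lw=0.8,
            label="after correction")
    ax.set_xlabel("original beat number (1-based)")
    ax.set_ylabel("HR (bpm)")
    ax.legend(loc="upper right", fontsize=8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110)
    return fig
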