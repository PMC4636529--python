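"""Time-domain HRV parameters and HR descriptive statistics.

Definitions follow the standard task-force time-domain conventions:

* SDNN — sample standard deviation of the RR intervals (ms);
* RMSSD — root mean square of successive RR differences (ms);
* pNN50 — percentage of successive RR differences whose absolute value
  strictly exceeds 50 ms, out of the number of successive pairs (n − 1).

HR descriptive statistics (mean, median, SD) are computed on the
bpm-converted series.  No detrending or artifact interpolation is applied:
the metrics describe the series exactly as passed.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Dict

import numpy as np

from .series import BeatSeries

__all__ = ["HRVSummary", "summarize", "compare_summaries", "UNDEFINED_CHANGE"]

#: Sentinel percent-change for a zero baseline (e.g. pNN50 = 0 before).
UNDEFINED_CHANGE = float("nan")


@dataclass(frozen=True)
class HRVSummary:
    hr_mean: float  # bpm
    hr_median: float  # bpm
    hr_sd: float  # bpm
    sdnn: float  # ms
    rmssd: float  # ms
    pnn50: float  # percent
    n_beats: int

    def as_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def summarize(series: BeatSeries) -> HRVSummary:
    """Compute time-domain HRV and HR statistics for a beat series.

    Requires at least two beats (one successive pair).
    """
    if len(series) < 2:
        raise ValueError("need at least 2 beats to form successive pairs")
    rr = series.to("ms").values
    bpm = series.to("bpm").values
    diffs = np.diff(rr)
    return HRVSummary(
        hr_mean=float(bpm.mean()),
        hr_median=float(np.median(bpm)),
        hr_sd=float(bpm.std(ddof=1)),
        sdnn=float(rr.std(ddof=1)),
        rmssd=float(np.sqrt(np.mean(diffs**2))),
        pnn50=float(100.0 * np.count_nonzero(np.abs(diffs) > 50.0) / diffs.size),
        n_beats=len(series),
    )


def compare_summaries(before: HRVSummary, after: HRVSummary) -> Dict[str, float]:
    """Percent change of each parameter: 100·(after − before)/before.

    A zero baseline yields :data:`UNDEFINED_CHANGE` (NaN), never a division
    error — except that an unchanged zero (0 → 0) reports 0 % change.
    ``n_beats`` is reported as the raw difference instead of a percentage.
    """
    out: Dict[str, float] = {}
    for name, b in before.as_dict().items():
        a = getattr(after, name)
        if name == "n_beats":
            out[name] = float(a - b)
        elif b == 0:
            out[name] = 0.0 if a == 0 else UNDEFINED_CHANGE
        else:
            out[name] = 100.0 * (a - b) / b
    return out
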