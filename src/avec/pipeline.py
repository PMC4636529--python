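"""Whole-series scanning, correction planning, and the perturbation study.

The scan is a single-step procedure: every beat with sufficient context is
tested against its surrounding window computed from the ORIGINAL series, so
the candidate set is fixed in one pass rather than by iterative
delete-and-rescan.  Within overlapping windows, the most extreme candidate
is corrected first and lower-priority candidates are re-tested against the
recombined neighborhood (the window re-formed after higher-priority
deletions) before entering the correction plan.

Corrections either delete flagged beats (the surviving values are an exact
subsequence of the input — no insertion, no time shift) or replace them with
the arithmetic mean of the five preceding and five subsequent surviving
values.  Recordings where the flagged fraction strictly exceeds 5 % are
marked for exclusion from further analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .detection import DetectionConfig, OutlierVerdict, test_candidate
from .metrics import HRVSummary, compare_summaries, summarize
from .series import BeatSeries, CorrectionLog, Edit

__all__ = [
    "ScanResult",
    "ExclusionStatus",
    "PlannedCorrection",
    "scan_series",
    "resolve_overlaps",
    "apply_corrections",
    "apply_manual_deletions",
    "exclusion_check",
    "perturbation_experiment",
    "HRV_PARAMETERS",
]

#: Parameters reported by the perturbation experiment, in table order.
HRV_PARAMETERS = ("hr_mean", "hr_median", "hr_sd", "sdnn", "rmssd", "pnn50")

_SD_FLOOR = 1e-12  # priority denominator floor for zero-spread windows


@dataclass(frozen=True)
class ScanResult:
    """Verdicts for every tested beat of one series."""

    verdicts: Tuple[OutlierVerdict, ...]
    untested_indices: Tuple[int, ...]
    series_length: int

    @property
    def flagged_indices(self) -> Tuple[int, ...]:
        return tuple(v.index for v in self.verdicts if v.is_outlier)

    @property
    def error_fraction(self) -> float:
        if self.series_length == 0:
            return 0.0
        return len(self.flagged_indices) / self.series_length

    def verdict_for(self, index: int) -> OutlierVerdict:
        for v in self.verdicts:
            if v.index == index:
                return v
        raise KeyError(f"beat {index} was not tested")

    def to_frame(self) -> pd.DataFrame:
        """Verdicts as a DataFrame (one row per tested beat)."""
        return pd.DataFrame(
            {
                "index": [v.index for v in self.verdicts],
                "value": [v.candidate_value for v in self.verdicts],
                "window_mean": [v.window_mean for v in self.verdicts],
                "window_sd": [v.window_sd for v in self.verdicts],
                "n_used": [v.n_used for v in self.verdicts],
                "k": [v.k for v in self.verdicts],
                "flagged": [v.is_outlier for v in self.verdicts],
                "method": [v.method for v in self.verdicts],
            }
        )


@dataclass(frozen=True)
class ExclusionStatus:
    error_fraction: float
    threshold: float = 0.05

    @property
    def excluded(self) -> bool:
        # strict inequality: "more than 5 % errors"
        return self.error_fraction > self.threshold


@dataclass(frozen=True)
class PlannedCorrection:
    """One entry of an ordered correction plan."""

    index: int
    verdict: OutlierVerdict
    priority: float  # |x_g − x̄| / max(s, floor); larger = more extreme


def _window_of(values: np.ndarray, i: int, half_window: int) -> np.ndarray:
    lo = max(0, i - half_window)
    hi = min(values.size, i + half_window + 1)
    return np.concatenate([values[lo:i], values[i + 1 : hi]])


def scan_series(series: BeatSeries, config: Optional[DetectionConfig] = None) -> ScanResult:
    """Test every beat with sufficient context against its window.

    All verdicts are computed from the original series in one pass; beats
    closer than ``min_half_window`` to either end are reported as untested
    rather than silently passed.

    Raises ``ValueError`` when the series is shorter than the minimum
    context (2·min_half_window + 1 beats).
    """
    config = config or DetectionConfig()
    n = len(series)
    min_len = 2 * config.min_half_window + 1
    if n < min_len:
        raise ValueError(
            f"series of {n} beats is too short to scan; need at least {min_len}"
        )
    values = series.values
    verdicts: List[OutlierVerdict] = []
    untested: List[int] = []
    m = config.min_half_window
    for i in range(n):
        if i < m or n - 1 - i < m:
            untested.append(i)
            continue
        window = _window_of(values, i, config.half_window)
        verdicts.append(test_candidate(window, values[i], config, index=i))
    return ScanResult(
        verdicts=tuple(verdicts),
        untested_indices=tuple(untested),
        series_length=n,
    )


def exclusion_check(scan_result: ScanResult, threshold: float = 0.05) -> ExclusionStatus:
    """Apply the exclusion rule: more than ``threshold`` flagged → excluded."""
    return ExclusionStatus(
        error_fraction=scan_result.error_fraction, threshold=threshold
    )


def _retest_after_deletions(
    values: np.ndarray,
    index: int,
    deleted: set,
    config: DetectionConfig,
) -> OutlierVerdict:
    """Re-test a candidate against the window re-formed after deletions."""
    keep = [j for j in range(values.size) if j not in deleted or j == index]
    sub = np.asarray([values[j] for j in keep])
    pos = keep.index(index)
    window = _window_of(sub, pos, config.half_window)
    return test_candidate(window, values[index], config, index=index)


def resolve_overlaps(
    scan_result: ScanResult,
    series: BeatSeries,
    config: Optional[DetectionConfig] = None,
) -> List[PlannedCorrection]:
    """Order flagged beats into a correction plan, most extreme first.

    Candidates whose windows overlap are processed in order of decreasing
    standardized deviation |x_g − x̄| / max(s, ε); after each acceptance,
    lower-priority candidates whose windows contain an accepted deletion are
    re-tested against the recombined neighbor context and dropped if no
    longer outlying.  The returned plan lists overlap clusters in series
    order and, within a cluster, the most extreme candidate first.
    """
    config = config or DetectionConfig()
    values = series.values
    flagged = [scan_result.verdict_for(i) for i in scan_result.flagged_indices]
    if not flagged:
        return []

    def priority(v: OutlierVerdict) -> float:
        return v.deviation / max(abs(v.window_sd), _SD_FLOOR)

    order = sorted(flagged, key=lambda v: (-priority(v), v.index))
    reach = 2 * config.half_window  # windows of i and j share beats iff |i−j| ≤ reach
    accepted: List[PlannedCorrection] = []
    accepted_idx: set = set()
    for v in order:
        overlaps = any(abs(v.index - j) <= reach for j in accepted_idx)
        verdict = v
        if overlaps:
            verdict = _retest_after_deletions(values, v.index, accepted_idx, config)
            if not verdict.is_outlier:
                continue
        # priority stays that of the original single-step scan; the re-test
        # only decides whether the candidate is kept
        accepted.append(
            PlannedCorrection(index=v.index, verdict=verdict, priority=priority(v))
        )
        accepted_idx.add(v.index)

    # emit clusters in series order, most-extreme-first within each cluster
    by_index = sorted(accepted, key=lambda p: p.index)
    clusters: List[List[PlannedCorrection]] = []
    for p in by_index:
        if clusters and p.index - clusters[-1][-1].index <= reach:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    plan: List[PlannedCorrection] = []
    for cluster in clusters:
        plan.extend(sorted(cluster, key=lambda p: (-p.priority, p.index)))
    return plan


def _replacement_value(
    values: np.ndarray,
    index: int,
    excluded: set,
    n_side: int = 5,
    min_side: int = 3,
) -> float:
    """Mean of the ``n_side`` preceding and subsequent surviving values."""
    before = [j for j in range(index - 1, -1, -1) if j not in excluded][:n_side]
    after = [j for j in range(index + 1, values.size) if j not in excluded][:n_side]
    if len(before) < min_side or len(after) < min_side:
        raise ValueError(
            f"beat {index}: fewer than {min_side} surviving neighbors on one "
            "side; cannot form a replacement mean"
        )
    neighbors = before + after
    return float(np.mean(values[neighbors]))


def apply_corrections(
    series: BeatSeries,
    plan: Sequence,
    strategy: str = "delete",
    method: str = "algorithm",
) -> Tuple[BeatSeries, CorrectionLog]:
    """Apply a correction plan and return (corrected series, replayable log).

    ``plan`` may be a sequence of :class:`PlannedCorrection` or of plain
    beat indices.  ``strategy`` is ``"delete"`` (remove the beats; output is
    an exact subsequence of the input) or ``"replace_mean"`` (substitute the
    mean of the 5 preceding and 5 subsequent surviving values; length
    unchanged).  No value is ever inserted.
    """
    if strategy not in ("delete", "replace_mean"):
        raise ValueError("strategy must be 'delete' or 'replace_mean'")
    indices = [p.index if isinstance(p, PlannedCorrection) else int(p) for p in plan]
    if len(set(indices)) != len(indices):
        raise ValueError("correction plan contains duplicate indices")
    for i in indices:
        if not 0 <= i < len(series):
            raise ValueError(f"plan index {i} outside series of {len(series)} beats")
    values = series.values
    planned = set(indices)
    edits: List[Edit] = []
    if strategy == "delete":
        for i in indices:
            edits.append(
                Edit(index=i, original_value=float(values[i]), action="delete",
                     method=method)
            )
    else:
        for i in indices:
            repl = _replacement_value(values, i, planned)
            edits.append(
                Edit(index=i, original_value=float(values[i]), action="replace",
                     replacement_value=repl, method=method)
            )
    log = CorrectionLog(edits=tuple(edits), source_length=len(series))
    return log.replay(series), log


def apply_manual_deletions(
    series: BeatSeries, indices: Iterable[int]
) -> Tuple[BeatSeries, CorrectionLog]:
    """Delete visually identified beats before the algorithmic scan.

    The visual pass comes first: sharp, clearly discontinuous excursions are
    removed by the analyst, and the algorithm is then run on the recombined
    series for the unclear cases.
    """
    return apply_corrections(series, list(indices), strategy="delete", method="visual")


def perturbation_experiment(
    series: BeatSeries,
    fractions: Sequence[float] = (0.01, 0.02, 0.03, 0.04, 0.05),
    strategies: Sequence[str] = ("delete", "replace_mean"),
    seed: int = 0,
    edge_margin: int = 5,
) -> pd.DataFrame:
    """Randomly perturb a clean series and report HRV percent changes.

    For each fraction × strategy cell, a seeded uniform draw selects beat
    positions (avoiding the first/last ``edge_margin`` beats so the
    replacement mean is always well-defined); the strategy is applied and
    the percent change of each HR/HRV parameter relative to the unperturbed
    series is tabulated (rows = parameters, columns = strategy × fraction).

    The same positions are used for both strategies at a given fraction, so
    the contrast between deleting and mean-replacing is paired.
    """
    for f in fractions:
        if not 0.0 <= f <= 0.1:
            raise ValueError(f"fractions must lie in [0, 0.1], got {f}")
    n = len(series)
    baseline = summarize(series)
    rng = np.random.default_rng(seed)
    eligible = np.arange(edge_margin, n - edge_margin)
    columns: Dict[Tuple[str, float], Dict[str, float]] = {}
    for frac in fractions:
        n_pick = int(round(frac * n))
        if frac > 0 and n_pick < 1:
            warnings.warn(
                f"fraction {frac} selects no beats in a series of {n}; skipped",
                stacklevel=2,
            )
            continue
        positions = (
            np.sort(rng.choice(eligible, size=n_pick, replace=False))
            if n_pick
            else np.array([], dtype=int)
        )
        for strategy in strategies:
            if n_pick == 0:
                changes = {p: 0.0 for p in HRV_PARAMETERS}
            else:
                perturbed, _ = apply_corrections(series, positions, strategy=strategy)
                changes = compare_summaries(baseline, summarize(perturbed))
            columns[(strategy, frac)] = {p: changes[p] for p in HRV_PARAMETERS}
    if not columns:
        return pd.DataFrame(
            index=list(HRV_PARAMETERS),
            columns=pd.MultiIndex.from_arrays([[], []], names=["strategy", "fraction"]),
        )
    table = pd.DataFrame(columns, index=list(HRV_PARAMETERS))
    table.columns = pd.MultiIndex.from_tuples(
        table.columns, names=["strategy", "fraction"]
    )
    return table
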