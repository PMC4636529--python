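"""Beat-series data model and correction logs.

A recording is an ordered sequence of beat-to-beat measurements, either as
instantaneous heart rate (bpm) or as RR intervals (ms between beats).  The
beat index is the canonical time axis: no timestamps are stored, and elapsed
time, where needed, is the running sum of RR intervals.

All edits made to a series — whether decided by the outlier algorithm, by
visual inspection, or manually — are recorded in a :class:`CorrectionLog`
whose replay on the original series reproduces the corrected series exactly.
The log can only delete or replace beats, never insert them, so a corrected
series is never longer than its source and never time-shifted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "POLAR_DEVICE_RANGE",
    "BeatSeries",
    "Edit",
    "CorrectionLog",
    "convert_unit",
]

#: Recordable HR range of the Polar RS800CX logger, in bpm.
POLAR_DEVICE_RANGE: Tuple[float, float] = (15.0, 240.0)

_UNITS = ("bpm", "ms")
_ACTIONS = ("delete", "replace")
_METHODS = ("algorithm", "visual", "manual")


def _as_bpm(values: np.ndarray, unit: str) -> np.ndarray:
    return values if unit == "bpm" else 60000.0 / values


@dataclass(frozen=True)
class BeatSeries:
    """Ordered beat-to-beat measurements with a unit.

    Parameters
    ----------
    values
        Strictly positive, finite measurements in recording order.
    unit
        ``"bpm"`` (instantaneous heart rate) or ``"ms"`` (RR interval).
    label
        Free-text subject/session identifier.
    device_range
        Optional ``(min, max)`` recordable HR in bpm.  When set to the Polar
        default ``(15, 240)``, all bpm-converted values must lie inside it.
    """

    values: np.ndarray
    unit: str
    label: str = ""
    device_range: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("BeatSeries values must be one-dimensional")
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("BeatSeries values must be finite")
        if vals.size and not np.all(vals > 0):
            bad = int(np.flatnonzero(vals <= 0)[0])
            raise ValueError(
                f"BeatSeries values must be strictly positive; "
                f"value {vals[bad]!r} at beat {bad} is not"
            )
        if self.unit not in _UNITS:
            raise ValueError(f"unit must be one of {_UNITS}, got {self.unit!r}")
        if self.device_range is not None:
            lo, hi = self.device_range
            bpm = _as_bpm(vals, self.unit)
            if vals.size and (bpm.min() < lo - 1e-9 or bpm.max() > hi + 1e-9):
                raise ValueError(
                    f"values outside device range [{lo}, {hi}] bpm "
                    f"(observed {bpm.min():.3f}..{bpm.max():.3f} bpm)"
                )
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.values.size)

    def to(self, unit: str) -> "BeatSeries":
        """Return the series converted to ``unit`` (bpm <-> ms)."""
        if unit not in _UNITS:
            raise ValueError(f"unit must be one of {_UNITS}, got {unit!r}")
        if unit == self.unit:
            return self
        return _dc_replace(self, values=60000.0 / self.values, unit=unit)

    def with_values(self, values: Iterable[float]) -> "BeatSeries":
        """Return a copy of the series with replaced values."""
        return _dc_replace(self, values=np.asarray(list(values), dtype=float))

    @property
    def elapsed_s(self) -> np.ndarray:
        """Cumulative elapsed time at each beat (s), from the RR running sum."""
        rr = self.to("ms").values
        return np.cumsum(rr) / 1000.0


def convert_unit(series: BeatSeries, target_unit: str) -> BeatSeries:
    """Convert a series between bpm and ms (``hr_bpm = 60000 / rr_ms``).

    The conversion is an involution up to floating-point round-off.
    """
    return series.to(target_unit)


@dataclass(frozen=True)
class Edit:
    """A single recorded correction of one beat in the original series."""

    index: int
    original_value: float
    action: str  # "delete" | "replace"
    replacement_value: Optional[float] = None
    method: str = "algorithm"  # "algorithm" | "visual" | "manual"

    def __post_init__(self) -> None:
        if self.action not in _ACTIONS:
            raise ValueError(f"action must be one of {_ACTIONS}")
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.action == "replace" and self.replacement_value is None:
            raise ValueError("replace edit requires a replacement_value")
        if self.action == "delete" and self.replacement_value is not None:
            raise ValueError("delete edit must not carry a replacement_value")


@dataclass(frozen=True)
class CorrectionLog:
    """Ordered, replayable record of edits against one source series.

    Invariants: every edit index is unique and within the source length;
    replaying on the source reproduces the corrected series exactly; no edit
    inserts a value, so the corrected length never exceeds ``source_length``.
    """

    edits: Tuple[Edit, ...]
    source_length: int
    excluded: bool = False

    def __post_init__(self) -> None:
        edits = tuple(self.edits)
        idx = [e.index for e in edits]
        if len(set(idx)) != len(idx):
            raise ValueError("edit indices must be unique")
        for e in edits:
            if not (0 <= e.index < self.source_length):
                raise ValueError(
                    f"edit index {e.index} outside source [0, {self.source_length})"
                )
        object.__setattr__(self, "edits", edits)

    def __len__(self) -> int:
        return len(self.edits)

    def replay(self, source: BeatSeries) -> BeatSeries:
        """Apply the log to its source series and return the corrected series.

        Raises ``ValueError`` if the source does not match the log (wrong
        length, or an original value disagrees with the recorded one).
        """
        if len(source) != self.source_length:
            raise ValueError(
                f"log was made for a series of length {self.source_length}, "
                f"got {len(source)}"
            )
        vals = source.values.copy()
        delete_mask = np.zeros(len(source), dtype=bool)
        for e in self.edits:
            if not np.isclose(vals_orig := source.values[e.index], e.original_value):
                raise ValueError(
                    f"beat {e.index}: series value {vals_orig} does not match "
                    f"logged original {e.original_value}"
                )
            if e.action == "delete":
                delete_mask[e.index] = True
            else:
                vals[e.index] = e.replacement_value
        return source.with_values(vals[~delete_mask])

    def surviving_indices(self) -> np.ndarray:
        """Original-series indices that survive replay (replacements survive)."""
        deleted = {e.index for e in self.edits if e.action == "delete"}
        return np.array(
            [i for i in range(self.source_length) if i not in deleted], dtype=int
        )
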