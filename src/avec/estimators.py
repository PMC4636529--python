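"""Scikit-learn-style estimators wrapping the detection/correction pipeline.

:class:`GrafHenningDetector` is an outlier detector over a 1-D beat series
(fit + predict with the sklearn outlier-label convention: −1 outlier,
+1 inlier; here additionally 0 for beats too close to the boundary to be
tested).  :class:`AvecCorrector` is a transformer: fit scans the series and
builds the ordered correction plan, transform applies it.

Both compose with ``sklearn.base.clone`` and ``get_params``/``set_params``;
the fitted state lives in trailing-underscore attributes.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .detection import DetectionConfig
from .pipeline import (
    apply_corrections,
    exclusion_check,
    resolve_overlaps,
    scan_series,
)
from .series import BeatSeries

try:  # sklearn is optional: fall back to a minimal param-handling base
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    import inspect

    class BaseEstimator:  # type: ignore[no-redef]
        def get_params(self, deep=True):
            sig = inspect.signature(type(self).__init__)
            return {
                name: getattr(self, name)
                for name in sig.parameters
                if name != "self"
            }

        def set_params(self, **params):
            for key, val in params.items():
                if key not in self.get_params():
                    raise ValueError(f"invalid parameter {key!r}")
                setattr(self, key, val)
            return self

__all__ = ["GrafHenningDetector", "AvecCorrector"]


def _as_series(X, unit: str) -> BeatSeries:
    if isinstance(X, BeatSeries):
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr[:, 0]
    if arr.ndim != 1:
        raise ValueError(
            f"expected a 1-D beat series (or a single-column 2-D array), "
            f"got shape {arr.shape}"
        )
    return BeatSeries(values=arr, unit=unit)


class GrafHenningDetector(BaseEstimator):
    """Windowed outlier detector for beat-to-beat heart-rate series.

    Parameters
    ----------
    p_level : float, default 0.75
        Confidence level P of the criterion; lower narrows the tolerance
        band and flags more beats.
    half_window : int, default 20
        Beats on each side of the candidate.
    min_half_window : int, default 10
        Minimum one-sided context; beats nearer the boundary stay untested.
    lambda_mode, lambda_a, lambda_b
        ``"equal"`` derives λ_a = λ_b from ``p_level``; ``"explicit"`` uses
        the given pair.
    n_convention : str
        Whether the candidate counts toward n in the k formula.
    exclusion_threshold : float, default 0.05
        Flagged fraction above which (strictly) the recording is marked for
        exclusion.
    unit : str, default "bpm"
        Unit assumed for plain-array input.

    Attributes
    ----------
    scan_result_ : ScanResult
        Per-beat verdicts from the single-step scan.
    flagged_indices_ : ndarray of int
        Beats flagged as outliers.
    error_fraction_ : float
    excluded_ : bool
        Whether the 5 % exclusion rule fires.
    labels_ : ndarray of int
        +1 inlier, −1 outlier, 0 untested, aligned with the input beats.
    """

    def __init__(
        self,
        p_level: float = 0.75,
        half_window: int = 20,
        min_half_window: int = 10,
        lambda_mode: str = "equal",
        lambda_a: Optional[float] = None,
        lambda_b: Optional[float] = None,
        n_convention: str = "exclude_candidate",
        exclusion_threshold: float = 0.05,
        unit: str = "bpm",
    ):
        self.p_level = p_level
        self.half_window = half_window
        self.min_half_window = min_half_window
        self.lambda_mode = lambda_mode
        self.lambda_a = lambda_a
        self.lambda_b = lambda_b
        self.n_convention = n_convention
        self.exclusion_threshold = exclusion_threshold
        self.unit = unit

    def _config(self) -> DetectionConfig:
        return DetectionConfig(
            p_level=self.p_level,
            half_window=self.half_window,
            min_half_window=self.min_half_window,
            lambda_mode=self.lambda_mode,
            lambda_a=self.lambda_a,
            lambda_b=self.lambda_b,
            n_convention=self.n_convention,
        )

    def fit(self, X, y=None):
        series = _as_series(X, self.unit)
        self.series_ = series
        self.scan_result_ = scan_series(series, self._config())
        self.flagged_indices_ = np.asarray(
            self.scan_result_.flagged_indices, dtype=int
        )
        self.error_fraction_ = self.scan_result_.error_fraction
        self.excluded_ = exclusion_check(
            self.scan_result_, self.exclusion_threshold
        ).excluded
        labels = np.ones(len(series), dtype=int)
        labels[list(self.scan_result_.untested_indices)] = 0
        labels[self.flagged_indices_] = -1
        self.labels_ = labels
        return self

    def predict(self, X=None) -> np.ndarray:
        """Outlier labels for the fitted series (−1/+1/0).

        When ``X`` is given it must match the fitted series; detection is
        windowed and local, so labels are only defined for a full series.
        """
        if not hasattr(self, "labels_"):
            raise RuntimeError("detector is not fitted; call fit first")
        if X is not None:
            series = _as_series(X, self.unit)
            if len(series) != len(self.series_) or not np.array_equal(
                series.values, self.series_.values
            ):
                raise ValueError("predict expects the series the detector was fit on")
        return self.labels_.copy()

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict()


class AvecCorrector(GrafHenningDetector):
    """Detector plus correction: fit builds the plan, transform applies it.

    Additional parameter ``strategy``: ``"delete"`` removes flagged beats
    (output shorter, an exact subsequence of the input); ``"replace_mean"``
    substitutes the mean of the five surviving neighbors on each side
    (length preserved).

    Additional fitted attributes: ``plan_`` (ordered, most extreme first
    within overlap clusters), ``corrected_series_``, ``log_``.
    """

    def __init__(
        self,
        p_level: float = 0.75,
        half_window: int = 20,
        min_half_window: int = 10,
        lambda_mode: str = "equal",
        lambda_a: Optional[float] = None,
        lambda_b: Optional[float] = None,
        n_convention: str = "exclude_candidate",
        exclusion_threshold: float = 0.05,
        unit: str = "bpm",
        strategy: str = "delete",
    ):
        super().__init__(
            p_level=p_level,
            half_window=half_window,
            min_half_window=min_half_window,
            lambda_mode=lambda_mode,
            lambda_a=lambda_a,
            lambda_b=lambda_b,
            n_convention=n_convention,
            exclusion_threshold=exclusion_threshold,
            unit=unit,
        )
        self.strategy = strategy

    def fit(self, X, y=None):
        super().fit(X)
        self.plan_ = resolve_overlaps(self.scan_result_, self.series_, self._config())
        self.corrected_series_, self.log_ = apply_corrections(
            self.series_, self.plan_, strategy=self.strategy
        )
        return self

    def transform(self, X) -> np.ndarray:
        """Apply the fitted correction plan to ``X`` (the fitted series)."""
        if not hasattr(self, "plan_"):
            raise RuntimeError("corrector is not fitted; call fit first")
        series = _as_series(X, self.unit)
        if not np.array_equal(series.values, self.series_.values):
            raise ValueError("transform expects the series the corrector was fit on")
        return self.corrected_series_.values.copy()

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)
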