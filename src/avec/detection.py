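"""Windowed outlier criterion for beat-to-beat data (Graf–Henning test).

A candidate beat ``x_g`` is compared against the sample mean ``x̄`` and
sample standard deviation ``s`` of its surrounding window (the candidate
itself excluded).  It is flagged as an outlier when

    |x_g − x̄| > k·|s|,

where the multiplier ``k`` is derived from a confidence level ``P`` through
the two-sided standard-normal mass

    Erf(λ/√2) = (1/√(2π)) ∫_{−λ}^{+λ} e^{−t²/2} dt = P,

and the finite-sample correction

    k = [2(n−1) / (2(n−1) − λ_b²)] ·
        [λ_a + λ_b · √((n·λ_a² + 2(n−1) − λ_b²) / (2n(n−1)))],

with ``n`` the number of window values.  With λ_b = 0 the correction
vanishes and k = λ_a; as n → ∞, k → λ_a.  By default λ_a = λ_b = λ(P), the
normal quantile solving the Erf relation; a user may supply an explicit
(λ_a, λ_b) pair instead.

``P`` sets the width of the tolerance band: a beat is flagged when it falls
outside the two-sided band holding probability P under the window's normal
fit.  Lowering P narrows the band and flags MORE beats — conservative in
the sense that missing a true artifact is treated as worse than deleting a
genuine beat.  The default P = 0.75 with a window of 20 beats on each side
suits data with pronounced respiratory sinus arrhythmia, where the natural
beat-to-beat variability is large and the local window must stay short.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "gauss_error_probability",
    "solve_lambda",
    "compute_k",
    "DetectionConfig",
    "OutlierVerdict",
    "test_candidate",
]

_LAMBDA_BRACKET = (0.0, 40.0)


def gauss_error_probability(lam: float) -> float:
    """Two-sided standard-normal probability mass within ±λ.

    Equals ``erf(λ/√2)``; strictly increasing in λ, 0 at λ = 0, and → 1 as
    λ → ∞ (λ = 40 already returns 1 to machine precision).

    Raises ``ValueError`` for negative λ.
    """
    if lam < 0:
        raise ValueError(f"lambda must be nonnegative, got {lam}")
    return math.erf(lam / math.sqrt(2.0))


@lru_cache(maxsize=256)
def solve_lambda(p: float) -> float:
    """Invert the Erf relation: the λ with ``gauss_error_probability(λ) = p``.

    Solved by bracketing root-finding on [0, 40] to absolute tolerance well
    below 1e-10.  Raises ``ValueError`` for p outside the open interval (0, 1).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {p}")
    return float(
        brentq(lambda lam: gauss_error_probability(lam) - p, *_LAMBDA_BRACKET,
               xtol=1e-12, rtol=8.9e-16)
    )


@lru_cache(maxsize=4096)
def compute_k(lambda_a: float, lambda_b: float, n: int) -> float:
    """Finite-sample threshold multiplier k(λ_a, λ_b, n).

    Requires n ≥ 3 and λ_b² < 2(n−1); otherwise the leading factor of the
    expression is undefined or negative and a ``ValueError`` is raised.
    """
    if n < 3:
        raise ValueError(f"n must be at least 3, got {n}")
    if lambda_a < 0 or lambda_b < 0:
        raise ValueError("lambda_a and lambda_b must be nonnegative")
    two_nm1 = 2.0 * (n - 1)
    if lambda_b**2 >= two_nm1:
        raise ValueError(
            f"constraint lambda_b^2 < 2(n-1) violated: "
            f"{lambda_b**2:.6g} >= {two_nm1:.6g}"
        )
    prefactor = two_nm1 / (two_nm1 - lambda_b**2)
    inner = (n * lambda_a**2 + two_nm1 - lambda_b**2) / (2.0 * n * (n - 1))
    return prefactor * (lambda_a + lambda_b * math.sqrt(inner))


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the windowed outlier criterion.

    Attributes
    ----------
    p_level
        Confidence level P in (0, 1); lower narrows the tolerance band and
        flags more beats.
    half_window
        Beats on each side of the candidate (default 20, i.e. a 41-beat
        neighborhood, ≈ 30 s of dog HR).
    min_half_window
        Smallest acceptable one-sided context near the series boundaries;
        beats with less context are reported as untested.
    lambda_mode
        ``"equal"`` sets λ_a = λ_b = λ(P); ``"explicit"`` uses the supplied
        ``lambda_a``/``lambda_b`` pair.
    n_convention
        ``"exclude_candidate"`` takes n = number of window values actually
        used for x̄ and s (the default, matching the mean "excluding x_g");
        ``"include_candidate"`` adds one.
    """

    p_level: float = 0.75
    half_window: int = 20
    min_half_window: int = 10
    lambda_mode: str = "equal"
    lambda_a: Optional[float] = None
    lambda_b: Optional[float] = None
    n_convention: str = "exclude_candidate"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_level < 1.0:
            raise ValueError(f"p_level must be in (0, 1), got {self.p_level}")
        if not self.half_window >= self.min_half_window >= 2:
            raise ValueError(
                "need half_window >= min_half_window >= 2, got "
                f"{self.half_window} / {self.min_half_window}"
            )
        if self.lambda_mode not in ("equal", "explicit"):
            raise ValueError("lambda_mode must be 'equal' or 'explicit'")
        if self.lambda_mode == "explicit":
            if self.lambda_a is None or self.lambda_b is None:
                raise ValueError("explicit mode requires lambda_a and lambda_b")
            if not (
                0 < self.lambda_a < math.inf and 0 <= self.lambda_b < math.inf
            ):
                raise ValueError("explicit lambdas must be positive and finite")
        if self.n_convention not in ("exclude_candidate", "include_candidate"):
            raise ValueError(
                "n_convention must be 'exclude_candidate' or 'include_candidate'"
            )

    def lambdas(self) -> Tuple[float, float]:
        """Resolve (λ_a, λ_b) for the configured mode."""
        if self.lambda_mode == "explicit":
            return float(self.lambda_a), float(self.lambda_b)
        lam = solve_lambda(self.p_level)
        return lam, lam

    def k_for(self, n_window: int) -> float:
        """Threshold multiplier for a window of ``n_window`` values."""
        la, lb = self.lambdas()
        n = n_window if self.n_convention == "exclude_candidate" else n_window + 1
        return compute_k(la, lb, n)


@dataclass(frozen=True)
class OutlierVerdict:
    """Outcome of testing one candidate beat against its window."""

    index: int
    candidate_value: float
    window_mean: float
    window_sd: float
    n_used: int
    k: float
    is_outlier: bool
    method: str = "algorithm"

    @property
    def deviation(self) -> float:
        return abs(self.candidate_value - self.window_mean)


def test_candidate(
    window_values: Sequence[float],
    candidate_value: float,
    config: DetectionConfig,
    index: int = -1,
) -> OutlierVerdict:
    """Apply the outlier criterion to one candidate given its window.

    ``window_values`` must exclude the candidate itself; x̄ and s are
    computed over the window only (sample SD, n−1 denominator).  A window of
    zero spread flags any nonzero deviation (|x_g − x̄| > k·0) and keeps an
    exactly equal candidate.

    Raises ``ValueError`` when the window is shorter than twice the
    configured minimum one-sided context.
    """
    w = np.asarray(window_values, dtype=float)
    if w.size < 2 * config.min_half_window:
        raise ValueError(
            f"window of {w.size} values is too short; need at least "
            f"{2 * config.min_half_window}"
        )
    mean = float(w.mean())
    sd = float(w.std(ddof=1))
    k = config.k_for(int(w.size))
    is_outlier = abs(candidate_value - mean) > k * abs(sd)
    return OutlierVerdict(
        index=index,
        candidate_value=float(candidate_value),
        window_mean=mean,
        window_sd=sd,
        n_used=int(w.size),
        k=k,
        is_outlier=bool(is_outlier),
    )


# not a pytest test, despite the name
test_candidate.__test__ = False  # type: ignore[attr-defined]
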