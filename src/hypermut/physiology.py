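"""Closed-form photosynthesis physiology calculations.

Three small, exactly specified computations used around the evolved-strain
phenotyping: chlorophyll-a quantification from a methanol extract
(12.9447 x (A665 - A720) ug/mL), relative transcript abundance from qPCR
cycle thresholds (2^-ddCt), and P700 absorbance-trace processing — window
normalization for far-red (FR) re-reduction and actinic-light (AL) redox
protocols, followed by initial-rate extraction as the slope of a linear fit
over the first instants after light-off, gated at R^2 >= 0.99.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy.stats import linregress

__all__ = [
    "AbsorbancePair",
    "ExpressionMeasurement",
    "KineticTrace",
    "QualityError",
    "NormalizationError",
    "chlorophyll_a",
    "fold_expression",
    "normalize_p700",
    "initial_rereduction_rate",
]

CHLOROPHYLL_COEFF = 12.9447  # ug/mL per absorbance unit of (A665 - A720)


class NormalizationError(ValueError):
    """Trace has no dynamic range in the normalization window."""


class QualityError(ValueError):
    """No fit window reaches the R^2 quality gate."""

    def __init__(self, message: str, best_r2: float):
        super().__init__(message)
        self.best_r2 = best_r2


@dataclass(frozen=True)
class AbsorbancePair:
    A665: float
    A720: float

    def __post_init__(self) -> None:
        if self.A665 < 0 or self.A720 < 0:
            raise ValueError("absorbances must be >= 0")


@dataclass(frozen=True)
class ExpressionMeasurement:
    """Ct quartet for one target/reference gene pair in test vs control."""

    Ct_target_test: float
    Ct_ref_test: float
    Ct_target_control: float
    Ct_ref_control: float

    def __post_init__(self) -> None:
        for v in (self.Ct_target_test, self.Ct_ref_test,
                  self.Ct_target_control, self.Ct_ref_control):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("Ct values must be finite and > 0")


@dataclass
class KineticTrace:
    """A time-resolved absorbance signal with labelled light events (s)."""

    time: np.ndarray
    signal: np.ndarray
    events: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.size < 10:
            raise ValueError("trace needs at least 10 samples")
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal lengths differ")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        for name, t in self.events.items():
            if not (self.time[0] <= t <= self.time[-1]):
                raise ValueError(f"event {name!r} at {t} outside the time range")


def chlorophyll_a(pair: AbsorbancePair) -> float:
    """Chlorophyll-a concentration (ug/mL) of a methanol extract.

    Negative values can only arise from measurement noise; they are flagged
    with a warning but returned unclamped.
    """
    value = CHLOROPHYLL_COEFF * (pair.A665 - pair.A720)
    if value < 0:
        warnings.warn(
            f"negative chlorophyll-a ({value:.4g} ug/mL): A720 exceeds A665, "
            "likely measurement noise", stacklevel=2,
        )
    return value


def fold_expression(m: ExpressionMeasurement) -> float:
    """Relative expression fold change by the 2^-ddCt method."""
    ddct = (m.Ct_target_test - m.Ct_ref_test) - (m.Ct_target_control - m.Ct_ref_control)
    return float(2.0 ** (-ddct))


def _require_event(trace: KineticTrace, name: str) -> float:
    if name not in trace.events:
        raise KeyError(f"trace is missing required event {name!r}")
    return trace.events[name]


def normalize_p700(
    trace: KineticTrace, mode: Literal["FR-rereduction", "AL-redox"]
) -> KineticTrace:
    """Normalize a P700 absorbance trace by its protocol's window extrema.

    FR-rereduction: divide so the maximum within the 1 s window ending at
    ``light_off`` equals 1.  AL-redox: affine map so the post-``light_off``
    minimum goes to 0 and the maximum of the 3 s window before ``light_off``
    goes to 1.
    """
    t_off = _require_event(trace, "light_off")
    t, y = trace.time, trace.signal
    if mode == "FR-rereduction":
        window = (t >= t_off - 1.0) & (t <= t_off)
        if not window.any():
            raise NormalizationError("no samples in the 1 s pre-light-off window")
        peak = y[window].max()
        if peak == 0:
            raise NormalizationError("pre-light-off maximum is 0; cannot scale")
        return KineticTrace(t.copy(), y / peak, dict(trace.events))
    if mode == "AL-redox":
        pre = (t >= t_off - 3.0) & (t <= t_off)
        post = t > t_off
        if not pre.any() or not post.any():
            raise NormalizationError("windows around light_off are empty")
        lo, hi = y[post].min(), y[pre].max()
        if hi == lo:
            raise NormalizationError("zero dynamic range (max equals min)")
        return KineticTrace(t.copy(), (y - lo) / (hi - lo), dict(trace.events))
    raise ValueError(f"unknown mode {mode!r}")


def initial_rereduction_rate(
    trace: KineticTrace,
    r2_min: float = 0.99,
    min_points: int = 5,
    max_window: float = 0.3,
) -> float:
    """Initial slope (1/s) of a normalized FR re-reduction trace.

    Least-squares lines are fitted over expanding windows anchored at
    ``light_off``; the slope of the longest window with fit R^2 >= ``r2_min``
    is returned.  Windows are limited to ``max_window`` seconds (default
    0.3 s) so that the estimate reflects the *initial* rate: on a saturating
    recovery curve, unbounded windows can satisfy the R^2 gate while
    systematically underestimating the tangent slope at light-off.
    A :class:`QualityError` carrying the best achieved R^2 is raised when no
    window of at least ``min_points`` samples passes the gate.
    """
    t_off = _require_event(trace, "light_off")
    mask = (trace.time >= t_off) & (trace.time <= t_off + max_window)
    t, y = trace.time[mask], trace.signal[mask]
    if t.size < min_points:
        raise ValueError(
            f"only {t.size} samples within {max_window} s after light_off; "
            f"need at least {min_points}"
        )
    best_slope = None
    best_r2 = -np.inf
    for n in range(min_points, t.size + 1):
        fit = linregress(t[:n], y[:n])
        r2 = fit.rvalue**2
        best_r2 = max(best_r2, r2)
        if r2 >= r2_min:
            best_slope = fit.slope  # longest qualifying window wins
    if best_slope is None:
        raise QualityError(
            f"no window of >= {min_points} points reaches R^2 >= {r2_min} "
            f"(best {best_r2:.4f})", best_r2=float(best_r2),
        )
    return float(best_slope)
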