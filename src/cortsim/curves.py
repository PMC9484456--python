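"""Seven-parameter acute response curves.

An acute glucocorticoid response is modelled phenomenologically as a
piecewise-linear trajectory through five turning points — pre-stressor
baseline, onset of the rise, arrival at maximum, end of the plateau, and
recovery — determined by seven parameters: baseline level ``B``, onset
delay ``T_on``, time to maximum ``T_max``, maximum level ``M``, plateau
duration ``D``, return duration ``T_ret`` and post-response level ``E``.
The piecewise-linear skeleton is smoothed with locally weighted linear
regression (lowess) on a 1-minute grid to yield a realistic curve; the
rate of initial increase is implied as ``(M - B) / (T_max - T_on)``.

Concentrations are in ng/µl, times in minutes from stressor onset (t=0).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "PARAM_NAMES",
    "ResponseParams",
    "ResponseCurve",
    "turning_points",
    "build_curve",
    "auc",
    "DEFAULT_T_END",
    "DEFAULT_SMOOTH_SPAN",
]

#: Canonical parameter order used throughout the package.
PARAM_NAMES = (
    "baseline",
    "onset_delay",
    "time_to_max",
    "max_value",
    "plateau_duration",
    "return_duration",
    "end_value",
)

#: Default length of the simulated response window (minutes).
DEFAULT_T_END = 120

#: Default lowess span: bandwidth as a proportion of the 120-min reference
#: window (i.e. an absolute bandwidth of ``span * 120`` minutes).
DEFAULT_SMOOTH_SPAN = 0.3

# Number of grid points in the reference window (0..120 inclusive).
_REFERENCE_GRID_N = DEFAULT_T_END + 1


class ParameterError(ValueError):
    """A response parameter violates its physiological constraints."""


@dataclass(frozen=True)
class ResponseParams:
    """True (or expressed) parameters of one acute response.

    Attributes
    ----------
    baseline : float
        Pre-stressor glucocorticoid level B (ng/µl), >= 0.
    onset_delay : float
        Minutes after the stressor before the rise begins (T_on), >= 0.
    time_to_max : float
        Minutes from stressor onset to the maximum (T_max), > onset_delay.
    max_value : float
        Maximum level reached M (ng/µl), >= baseline.
    plateau_duration : float
        Minutes spent at the maximum (D), >= 0.
    return_duration : float
        Minutes from end of plateau to recovery (T_ret), > 0.
    end_value : float
        Post-response recovery level E (ng/µl), >= 0.
    """

    baseline: float
    onset_delay: float
    time_to_max: float
    max_value: float
    plateau_duration: float
    return_duration: float
    end_value: float

    def __post_init__(self) -> None:
        vals = self.to_array()
        if not np.all(np.isfinite(vals)):
            bad = PARAM_NAMES[int(np.flatnonzero(~np.isfinite(vals))[0])]
            raise ParameterError(f"{bad} is not finite")
        for field in ("baseline", "end_value", "plateau_duration"):
            if getattr(self, field) < 0:
                raise ParameterError(f"{field} must be >= 0")
        if self.onset_delay < 0:
            raise ParameterError("onset_delay must be >= 0")
        if not self.onset_delay < self.time_to_max:
            raise ParameterError(
                "onset_delay must be strictly less than time_to_max"
            )
        if not self.return_duration > 0:
            raise ParameterError("return_duration must be > 0")
        if self.max_value < self.baseline:
            raise ParameterError("max_value must be >= baseline")

    def to_array(self) -> np.ndarray:
        """Parameter values as a float array in :data:`PARAM_NAMES` order."""
        return np.array(
            [getattr(self, name) for name in PARAM_NAMES], dtype=float
        )

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ResponseParams":
        """Build from a length-7 array in :data:`PARAM_NAMES` order."""
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} values")
        return cls(*(float(v) for v in values))


def params_valid_mask(matrix: np.ndarray) -> np.ndarray:
    """Vectorised validity check for an (n, 7) parameter matrix.

    Returns a boolean mask of rows that satisfy every
    :class:`ResponseParams` invariant.
    """
    m = np.asarray(matrix, dtype=float)
    b, t_on, t_max, mx, d, t_ret, e = (m[:, i] for i in range(7))
    return (
        np.all(np.isfinite(m), axis=1)
        & (b >= 0)
        & (e >= 0)
        & (mx >= b)
        & (t_on > 0)  # strict: curve construction needs distinct points
        & (t_on < t_max)
        & (d >= 0)
        & (t_ret > 0)
    )


@dataclass(frozen=True)
class ResponseCurve:
    """A smoothed minute-resolution response curve.

    ``times`` is the integer minute grid 0..t_end and ``values`` the
    smoothed non-negative concentrations; ``params`` records the
    generating :class:`ResponseParams`.
    """

    times: np.ndarray
    values: np.ndarray
    params: ResponseParams

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")

    def value_at(self, t) -> np.ndarray:
        """Curve value(s) at arbitrary time(s) by linear interpolation."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            raise ValueError("time outside the curve grid")
        return np.interp(t, self.times, self.values)


def turning_points(params: ResponseParams) -> np.ndarray:
    """The five (time, concentration) turning points of a response.

    Returns an array of shape (5, 2):
    ``(0, B), (T_on, B), (T_max, M), (T_max+D, M), (T_max+D+T_ret, E)``.
    """
    p = params
    if p.onset_delay == 0:
        raise ParameterError(
            "onset_delay must be > 0: the pre-stressor point and the "
            "onset turning point would coincide in time"
        )
    pts = np.array(
        [
            (0.0, p.baseline),
            (p.onset_delay, p.baseline),
            (p.time_to_max, p.max_value),
            (p.time_to_max + p.plateau_duration, p.max_value),
            (
                p.time_to_max + p.plateau_duration + p.return_duration,
                p.end_value,
            ),
        ]
    )
    # plateau_duration == 0 collapses points 3 and 4; interpolation copes,
    # but times must otherwise be non-decreasing.
    return pts


def _smooth(raw: np.ndarray, grid: np.ndarray, span: float) -> np.ndarray:
    # Absolute bandwidth: span is a proportion of the 121-point reference
    # grid, so smoothing does not change when t_end is extended.
    window = max(3, int(round(span * _REFERENCE_GRID_N)))
    frac = min(1.0, window / len(grid))
    return lowess(raw, grid, frac=frac, it=0, return_sorted=False)


def build_curve(
    params: ResponseParams,
    t_end: int = DEFAULT_T_END,
    smooth_span: float = DEFAULT_SMOOTH_SPAN,
) -> ResponseCurve:
    """Realize a smoothed minute-resolution curve from parameters.

    The turning points are linearly interpolated onto the integer grid
    ``0..t_end`` (held at ``end_value`` beyond the final turning point),
    smoothed with locally weighted linear regression, and clamped at 0.

    Parameters
    ----------
    t_end : int
        Last minute of the grid; should normally cover
        ``time_to_max + plateau_duration + return_duration``.
    smooth_span : float
        Lowess bandwidth as a proportion of the 120-min reference window,
        in (0, 1].
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if not 0 < smooth_span <= 1:
        raise ValueError("smooth_span must be in (0, 1]")
    grid = np.arange(0, int(t_end) + 1, dtype=float)
    pts = turning_points(params)
    raw = np.interp(grid, pts[:, 0], pts[:, 1])
    values = np.clip(_smooth(raw, grid, smooth_span), 0.0, None)
    return ResponseCurve(times=grid, values=values, params=params)


def build_curves(
    matrix: np.ndarray,
    t_end: int = DEFAULT_T_END,
    smooth_span: float = DEFAULT_SMOOTH_SPAN,
) -> np.ndarray:
    """Smoothed curves for an (n, 7) parameter matrix.

    Returns an (n, t_end+1) array of values on the shared grid. Used by
    the simulation loops, which validate parameters upstream.
    """
    matrix = np.asarray(matrix, dtype=float)
    grid = np.arange(0, int(t_end) + 1, dtype=float)
    out = np.empty((matrix.shape[0], grid.size))
    for i, row in enumerate(matrix):
        b, t_on, t_max, mx, d, t_ret, e = row
        tp_t = (0.0, t_on, t_max, t_max + d, t_max + d + t_ret)
        tp_v = (b, b, mx, mx, e)
        raw = np.interp(grid, tp_t, tp_v)
        out[i] = np.clip(_smooth(raw, grid, smooth_span), 0.0, None)
    return out


def auc(points, mode: str = "ground") -> float:
    """Trapezoidal area under a sampled response (ng·min/µl).

    Parameters
    ----------
    points : array-like
        Either an (n, 2) array of (time, concentration) pairs or a
        ``(times, values)`` tuple; times must be strictly increasing,
        with at least two points.
    mode : {"ground", "increase"}
        ``ground`` integrates above zero (AUC_G); ``increase`` integrates
        above the first sample's value (AUC_I, may be negative).
    """
    if isinstance(points, tuple) and len(points) == 2:
        t = np.asarray(points[0], dtype=float)
        v = np.asarray(points[1], dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("expected (n, 2) array of (time, value) pairs")
        t, v = arr[:, 0], arr[:, 1]
    if t.size < 2:
        raise ValueError("auc requires at least two points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    area = float(np.trapezoid(v, t))
    if mode == "ground":
        return area
    if mode == "increase":
        return area - float(v[0]) * float(t[-1] - t[0])
    raise ValueError(f"unknown auc mode: {mode!r}")


def params_to_dict(params: ResponseParams) -> dict:
    """Plain-dict form of a :class:`ResponseParams` (for serialization)."""
    return dataclasses.asdict(params)
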