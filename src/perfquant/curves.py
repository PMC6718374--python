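"""Time-series carriers shared by every stage of the pipeline.

A :class:`SampledCurve` holds any ROI-level dynamic — an arterial input
function, a myocardial tissue curve, an MR signal-intensity series — as a
strictly increasing time axis plus values in a declared unit.  PET frame
data travel as a :class:`FramedTAC`: frame definitions (:class:`FrameScheme`)
plus frame-mean activities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "VALID_UNITS",
    "InvalidInputError",
    "CoverageError",
    "SampledCurve",
    "FrameScheme",
    "FramedTAC",
    "exp_convolve",
]

#: units a curve may declare: MR signal (arbitrary units), gadolinium
#: concentration, radioactivity concentration, or dimensionless
VALID_UNITS = ("a.u.", "mmol/L", "kBq/mL", "1")


class InvalidInputError(ValueError):
    """An input violates a documented precondition or invariant."""


class CoverageError(InvalidInputError):
    """A requested time span is not covered by the supplied data."""


@dataclass(frozen=True)
class SampledCurve:
    """A time-ordered series of (time, value) samples with a declared unit.

    Parameters
    ----------
    times
        Seconds since the protocol clock origin, strictly increasing.
    values
        Sample magnitudes, same length as ``times``.
    unit
        One of :data:`VALID_UNITS`.
    """

    times: np.ndarray
    values: np.ndarray
    unit: str = "1"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise InvalidInputError("times and values must be 1-D and equal length")
        if len(t) < 2:
            raise InvalidInputError("a curve needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            i = int(np.argmax(np.diff(t) <= 0))
            raise InvalidInputError(
                f"times must be strictly increasing (first violation at row {i + 1})"
            )
        if self.unit not in VALID_UNITS:
            raise InvalidInputError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> np.ndarray:
        return np.diff(self.times)

    def is_uniform(self, rtol: float = 1e-9) -> bool:
        d = self.dt
        return bool(np.allclose(d, d[0], rtol=rtol, atol=1e-12))

    def integral(self) -> float:
        """Trapezoidal time-integral over the sampled span."""
        return float(np.trapezoid(self.values, self.times))

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "SampledCurve":
        return replace(self, values=np.asarray(values, float),
                       unit=self.unit if unit is None else unit)

    def shifted(self, dt: float) -> "SampledCurve":
        return replace(self, times=self.times + dt)

    def crop(self, t_min: float = -np.inf, t_max: float = np.inf) -> "SampledCurve":
        m = (self.times >= t_min) & (self.times <= t_max)
        if m.sum() < 2:
            raise CoverageError(f"crop to [{t_min}, {t_max}] leaves fewer than 2 samples")
        return replace(self, times=self.times[m], values=self.values[m])

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Piecewise-linear interpolation, zero outside the sampled span."""
        return np.interp(np.asarray(t, float), self.times, self.values, left=0.0, right=0.0)


@dataclass(frozen=True)
class FrameScheme:
    """Contiguous, non-overlapping PET time frames (start, duration) in s."""

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.starts, dtype=float)
        d = np.asarray(self.durations, dtype=float)
        if s.ndim != 1 or d.ndim != 1 or len(s) != len(d) or len(s) == 0:
            raise InvalidInputError("starts and durations must be equal-length 1-D arrays")
        if np.any(d <= 0):
            raise InvalidInputError("frame durations must be positive")
        if not np.allclose(s[1:], s[:-1] + d[:-1], rtol=0, atol=1e-9):
            raise InvalidInputError("frames must be contiguous and non-overlapping")
        object.__setattr__(self, "starts", s)
        object.__setattr__(self, "durations", d)

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def midpoints(self) -> np.ndarray:
        return self.starts + self.durations / 2.0

    @property
    def span(self) -> float:
        """Total duration covered, first frame start to last frame end."""
        return float(self.ends[-1] - self.starts[0])


@dataclass(frozen=True)
class FramedTAC:
    """Frame-mean time-activity curve on a :class:`FrameScheme` grid.

    ``reference_time`` is the protocol-clock time of the decay reference
    (conventionally the injection, which coincides with frame 0 start).
    """

    scheme: FrameScheme
    mean_activity: np.ndarray
    decay_corrected: bool = False
    reference_time: float = 0.0
    unit: str = "kBq/mL"

    def __post_init__(self) -> None:
        a = np.asarray(self.mean_activity, dtype=float)
        if a.ndim != 1 or len(a) != len(self.scheme):
            raise InvalidInputError("mean_activity length must match the frame scheme")
        object.__setattr__(self, "mean_activity", a)

    def __len__(self) -> int:
        return len(self.scheme)

    def with_activity(self, activity: np.ndarray, decay_corrected: bool | None = None) -> "FramedTAC":
        return replace(
            self,
            mean_activity=np.asarray(activity, float),
            decay_corrected=self.decay_corrected if decay_corrected is None else decay_corrected,
        )


def exp_convolve(times: np.ndarray, values: np.ndarray, rate: float) -> np.ndarray:
    """``y(t_i) = int_0^{t_i} x(u) exp(-rate (t_i - u)) du`` on the input grid.

    Exact for a piecewise-linear ``x``: each segment of the integrand is
    integrated against the exponential kernel in closed form and the results
    chained by the one-step recursion ``y_{i+1} = y_i e^{-k dt} + seg_i``.
    This avoids the rectangle-rule bias a naive discrete convolution has at
    coarse (heartbeat-level) sampling.  ``rate <= 0`` degenerates to the
    running trapezoidal integral.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != x.shape or len(t) < 2:
        raise InvalidInputError("times and values must be equal-length 1-D arrays")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise InvalidInputError("times must be strictly increasing")
    y = np.zeros_like(x)
    if rate <= 0:
        np.cumsum(0.5 * dt * (x[1:] + x[:-1]), out=y[1:])
        return y
    k = float(rate)
    E = np.exp(-k * dt)
    slope = np.diff(x) / dt
    # closed-form integral of (x_i + slope*s) * exp(-k (dt - s)) over s in [0, dt]
    seg = x[:-1] * (1.0 - E) / k + slope * (dt * (1.0 - E) / k - (1.0 - (1.0 + k * dt) * E) / k**2)
    if np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        # uniform grid: the recursion is a first-order IIR filter
        y[1:] = lfilter([1.0], [1.0, -E[0]], seg)
    else:
        acc = 0.0
        for i in range(len(seg)):
            acc = acc * E[i] + seg[i]
            y[i + 1] = acc
    return y
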