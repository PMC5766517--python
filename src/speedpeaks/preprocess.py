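"""Triangular velocity smoothing, its frequency response, and speed profiles.

The smoother is a normalized symmetric triangular moving average of odd
length ``2d+1`` with weight ``d+1-|k|`` at offset ``k``. Component
velocities are smoothed independently and the per-frame Euclidean norm of
the smoothed components gives the speed profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SpeedPeaksError
from .io_model import Recording

__all__ = [
    "SmoothingKernel",
    "SpeedSeries",
    "make_kernel",
    "smooth",
    "frequency_response_db",
    "continuous_response_db",
    "differentiate",
    "speed_profile",
]


@dataclass(frozen=True)
class SmoothingKernel:
    """Normalized triangular FIR kernel of odd length ``2d+1``."""

    window: int
    half_width_d: int
    weights: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))

    def tau(self, sample_rate: float) -> float:
        """Half-base (seconds) of the continuous triangle approximating the
        kernel: the discrete weights vanish at offset ``±(d+1)``."""
        return (self.half_width_d + 1) / sample_rate


@dataclass(frozen=True)
class SpeedSeries:
    """Per-frame smoothed speed with its smoothed component velocities."""

    speed: np.ndarray
    velocity: np.ndarray  # shape (n, 3), m/s
    sample_rate: float

    def __post_init__(self):
        object.__setattr__(self, "speed", np.asarray(self.speed, dtype=float))
        object.__setattr__(self, "velocity", np.asarray(self.velocity, dtype=float))

    @property
    def n_frames(self) -> int:
        return self.speed.shape[0]

    @property
    def mean_speed(self) -> float:
        return float(self.speed.mean())


def make_kernel(window: int) -> SmoothingKernel:
    """Build the normalized triangular kernel for an odd ``window`` >= 3.

    Weights are proportional to ``d+1-|k|`` for ``k = -d..d`` with
    ``d = (window-1)//2`` and sum to 1 exactly.
    """
    if not isinstance(window, (int, np.integer)):
        raise SpeedPeaksError(f"window must be an integer, got {window!r}")
    if window < 3 or window % 2 == 0:
        raise SpeedPeaksError(f"window must be odd and >= 3, got {window}")
    d = (window - 1) // 2
    k = np.arange(-d, d + 1)
    raw = (d + 1 - np.abs(k)).astype(float)
    return SmoothingKernel(window=int(window), half_width_d=d, weights=raw / raw.sum())


def smooth(series: np.ndarray, kernel: SmoothingKernel) -> np.ndarray:
    """Apply the triangular moving average, preserving length.

    Near the boundaries the kernel is truncated to the available samples and
    renormalized, so DC gain stays 1 everywhere.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise SpeedPeaksError("smooth expects a 1-D series")
    if x.shape[0] < kernel.window:
        raise SpeedPeaksError(
            f"series of length {x.shape[0]} shorter than window {kernel.window}"
        )
    num = np.convolve(x, kernel.weights, mode="same")
    den = np.convolve(np.ones_like(x), kernel.weights, mode="same")
    return num / den


def frequency_response_db(
    kernel: SmoothingKernel, sample_rate: float, f: float
) -> float:
    """Exact discrete power response of the kernel in dB at frequency ``f``.

    Returns ``10*log10 |H(f)|^2`` where ``H`` is the kernel's discrete-time
    transfer function. ``f`` must lie in ``[0, sample_rate/2]``. ``-inf`` is
    returned at exact transfer-function zeros.
    """
    if not 0 <= f <= sample_rate / 2:
        raise SpeedPeaksError(
            f"frequency {f} Hz outside Nyquist band [0, {sample_rate / 2}]"
        )
    d = kernel.half_width_d
    k = np.arange(-d, d + 1)
    h = float(np.sum(kernel.weights * np.cos(2.0 * np.pi * f * k / sample_rate)))
    power = h * h
    if power == 0.0:
        return float("-inf")
    return float(10.0 * np.log10(power))


def continuous_response_db(
    kernel: SmoothingKernel, sample_rate: float, f: float
) -> float:
    """Continuous-triangle approximation of the power response in dB.

    The unit-area triangle of half-base ``tau`` has transform
    ``(sin(pi f tau) / (pi f tau))^2``, giving the power ratio
    ``sin^4(pi f tau) / (pi f tau)^4``.
    """
    if not 0 <= f <= sample_rate / 2:
        raise SpeedPeaksError(
            f"frequency {f} Hz outside Nyquist band [0, {sample_rate / 2}]"
        )
    if f == 0:
        return 0.0
    x = np.pi * f * kernel.tau(sample_rate)
    power = np.sin(x) ** 4 / x**4
    if power == 0.0:
        return float("-inf")
    return float(10.0 * np.log10(power))


def differentiate(rec: Recording) -> np.ndarray:
    """Finite-difference component velocities, shape ``(n, 3)`` in m/s.

    Central differences in the interior, one-sided at the two ends.
    """
    dt = 1.0 / rec.sample_rate
    return np.gradient(rec.position, dt, axis=0, edge_order=1)


def speed_profile(rec: Recording, kernel: SmoothingKernel) -> SpeedSeries:
    """Differentiate, smooth each velocity component, and take the norm."""
    if rec.n_frames < kernel.window:
        raise SpeedPeaksError(
            f"recording of {rec.n_frames} frames shorter than "
            f"smoothing window {kernel.window}"
        )
    vel = differentiate(rec)
    smoothed = np.column_stack([smooth(vel[:, j], kernel) for j in range(3)])
    speed = np.linalg.norm(smoothed, axis=1)
    return SpeedSeries(speed=speed, velocity=smoothed, sample_rate=rec.sample_rate)
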