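"""Minimum-jerk reaching simulator with rest gaps and AWGN at fixed SNR.

Each forward (or backward) stroke follows the asymmetric two-piece bell
``v = (4*tau*(1-tau))^2`` with ``tau`` spanning [0, 1/2] over the ``T1``
frames before the peak and [1/2, 1] over the ``T2`` frames after it, so the
peak value 1 sits exactly at frame ``T1`` and the endpoints are 0. A
session is ``n_cycles`` repetitions of [rest, forward, rest, backward]
plus a trailing rest. The literal reading of the published two-piece
parametrization (which re-zeros at the T1/T2 junction, producing two bells
per stroke) is available behind ``literal_two_bells=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, UndefinedRError
from .io_model import PipelineConfig, Recording
from .preprocess import make_kernel, smooth
from .fluctuations import (
    build_histogram,
    compute_R,
    compute_sipis,
    fit_exponential,
    peaks_in_windows,
)

__all__ = [
    "SimConfig",
    "SessionTruth",
    "bell_stroke",
    "simulate_speed_session",
    "add_awgn",
    "snr_sweep",
    "synth_recording",
]

log = logging.getLogger("speedpeaks.simulator")


@dataclass(frozen=True)
class SimConfig:
    """Session layout and noise settings.

    Defaults follow the validation protocol: 300 cycles of two 240-frame
    strokes separated by 20-frame rests; the stroke peak sits at ``T1``
    frames (asymmetric 0.4/0.6 split by default). ``snr_db=None`` disables
    noise.
    """

    n_cycles: int = 300
    T1: int = 96
    T2: int = 144
    rest: int = 20
    snr_db: float | None = None
    seed: int = 0
    amplitude: float = 1.0

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")
        if self.T1 < 2 or self.T2 < 2:
            raise ConfigError("T1 and T2 must both be >= 2")
        if self.rest < 0:
            raise ConfigError("rest must be >= 0")
        if self.amplitude <= 0:
            raise ConfigError("amplitude must be positive")

    @property
    def stroke_T(self) -> int:
        return self.T1 + self.T2


@dataclass(frozen=True)
class SessionTruth:
    """Ground-truth annotations for a simulated session (all frames)."""

    stroke_windows: tuple[tuple[int, int], ...]  # inclusive (start, stop)
    stroke_peaks: tuple[int, ...]
    cycle_windows: tuple[tuple[int, int], ...]  # fwd start .. bwd stop
    touch_frames: tuple[int, ...]  # midpoint of each top rest
    n_frames: int


def bell_stroke(
    T1: int, T2: int, literal_two_bells: bool = False
) -> np.ndarray:
    """Asymmetric minimum-jerk bell of length ``T1 + T2``.

    Frames ``0..T1`` ramp up (``tau`` in [0, 1/2]), frames ``T1..T1+T2-1``
    ramp down (``tau`` in [1/2, 1]); peak 1.0 at frame ``T1``, endpoints 0.
    """
    if T1 < 2 or T2 < 2:
        raise ConfigError("T1 and T2 must both be >= 2")
    t = np.arange(T1 + T2, dtype=float)
    tau = np.empty_like(t)
    if literal_two_bells:
        # published parametrization taken literally: tau restarts at T1
        tau[: T1] = t[: T1] / T1
        tau[T1:] = (t[T1:] - T1) / T2
    else:
        tau[: T1 + 1] = t[: T1 + 1] / (2.0 * T1)
        tau[T1 + 1 :] = 0.5 + (t[T1 + 1 :] - T1) / (2.0 * (T2 - 1))
    return (4.0 * tau * (1.0 - tau)) ** 2


def simulate_speed_session(
    cfg: SimConfig, literal_two_bells: bool = False
) -> tuple[np.ndarray, SessionTruth]:
    """Noiseless-or-noisy speed session plus ground-truth annotations.

    Layout: ``n_cycles`` repeats of [rest, forward, rest, backward] and one
    trailing rest; total length ``n_cycles*(2*stroke_T + 2*rest) + rest``.
    Noise (if ``cfg.snr_db`` is set) is added over the whole session,
    rests included, seeded by ``cfg.seed``.
    """
    stroke = cfg.amplitude * bell_stroke(cfg.T1, cfg.T2, literal_two_bells)
    T, r = cfg.stroke_T, cfg.rest
    chunks: list[np.ndarray] = []
    stroke_windows: list[tuple[int, int]] = []
    stroke_peaks: list[int] = []
    cycle_windows: list[tuple[int, int]] = []
    touch_frames: list[int] = []
    pos = 0
    rest_chunk = np.zeros(r)
    for _ in range(cfg.n_cycles):
        chunks.append(rest_chunk)
        pos += r
        fwd_start = pos
        chunks.append(stroke)
        stroke_windows.append((pos, pos + T - 1))
        stroke_peaks.append(pos + cfg.T1)
        pos += T
        touch_frames.append(pos + r // 2)  # middle of the top rest
        chunks.append(rest_chunk)
        pos += r
        chunks.append(stroke)
        stroke_windows.append((pos, pos + T - 1))
        stroke_peaks.append(pos + cfg.T1)
        pos += T
        cycle_windows.append((fwd_start, pos - 1))
    chunks.append(rest_chunk)
    pos += r
    speed = np.concatenate(chunks)
    assert speed.size == pos
    truth = SessionTruth(
        stroke_windows=tuple(stroke_windows),
        stroke_peaks=tuple(stroke_peaks),
        cycle_windows=tuple(cycle_windows),
        touch_frames=tuple(touch_frames),
        n_frames=pos,
    )
    if cfg.snr_db is not None and np.isfinite(cfg.snr_db):
        speed = add_awgn(speed, cfg.snr_db, cfg.seed)
    return speed, truth


def add_awgn(series: np.ndarray, snr_db: float, seed: int) -> np.ndarray:
    """Add white Gaussian noise at the requested SNR.

    Noise variance is ``mean(series**2) / 10**(snr_db/10)``, the signal
    power taken over the whole series (rests included). ``snr_db=inf``
    returns the series unchanged. Noisy values are not clipped at zero.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ConfigError("series must be nonempty")
    if np.isinf(snr_db):
        return series.copy()
    p_signal = float(np.mean(series**2))
    sigma = np.sqrt(p_signal / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    return series + rng.normal(0.0, sigma, series.size)


def _session_r(
    cfg: SimConfig,
    pipeline_cfg: PipelineConfig,
    smooth_window: int | None = 25,
) -> float:
    """R of one simulated session; peaks restricted to the known stroke
    windows (mirroring the empirical rest-period exclusion)."""
    speed, truth = simulate_speed_session(cfg)
    if smooth_window is not None:
        speed = smooth(speed, make_kernel(smooth_window))
    train = peaks_in_windows(speed, truth.stroke_windows)
    hist = fit_exponential(build_histogram(compute_sipis(train), pipeline_cfg), pipeline_cfg)
    return compute_R(hist)


def snr_sweep(
    cfg: SimConfig,
    snr_list: list[float],
    n_seeds: int,
    pipeline_cfg: PipelineConfig | None = None,
    smooth_window: int | None = 25,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Tidy (snr_db, seed, R) table over an SNR and seed grid.

    Each run regenerates the session with its own noise seed, smooths the
    noisy speed with the triangular kernel (``smooth_window=None``
    disables this, but then raw white noise dominates the peak train at
    every SNR and R loses its SNR sensitivity), and computes R from the
    within-stroke peak train. Runs with undefined R record NaN.
    """
    if not snr_list:
        raise ConfigError("snr_list must be nonempty")
    if base_seed is None:
        base_seed = cfg.seed
    rows = []
    for snr in snr_list:
        for s in range(n_seeds):
            seed = base_seed + s
            run_cfg = SimConfig(
                n_cycles=cfg.n_cycles,
                T1=cfg.T1,
                T2=cfg.T2,
                rest=cfg.rest,
                snr_db=snr,
                seed=seed,
                amplitude=cfg.amplitude,
            )
            try:
                r = _session_r(run_cfg, pipeline_cfg or PipelineConfig(), smooth_window)
            except UndefinedRError:
                log.info("undefined R at snr=%s seed=%d; recorded as NaN", snr, seed)
                r = float("nan")
            rows.append({"snr_db": snr, "seed": seed, "R": r})
    return pd.DataFrame(rows, columns=["snr_db", "seed", "R"])


def synth_recording(
    cfg: SimConfig,
    reach_amplitude_m: float = 0.3,
    sample_rate: float = 240.0,
    position_noise_sd: float = 0.0,
    cycle_speed_scales: np.ndarray | None = None,
    cycle_mid_rests: np.ndarray | None = None,
    seed: int | None = None,
    subject_id: str = "synthetic",
    screen_axis: str = "z",
) -> tuple[Recording, SessionTruth]:
    """3D-position analogue of a speed session, for segmentation tests.

    The screen-axis position is the running integral of the signed speed
    (forward strokes approach the screen, backward strokes return); the
    other two axes carry small smooth curvature. Peak stroke speed is set
    so each full-scale stroke covers ``reach_amplitude_m``. Optional
    per-cycle overrides: ``cycle_speed_scales`` multiplies both strokes of
    a cycle; ``cycle_mid_rests`` replaces the top-rest duration.
    """
    dt = 1.0 / sample_rate
    base = bell_stroke(cfg.T1, cfg.T2)
    peak_speed = reach_amplitude_m / (base.sum() * dt)
    stroke = peak_speed * base
    r = cfg.rest
    scales = np.ones(cfg.n_cycles) if cycle_speed_scales is None else np.asarray(
        cycle_speed_scales, dtype=float
    )
    mid_rests = (
        np.full(cfg.n_cycles, r, dtype=int)
        if cycle_mid_rests is None
        else np.asarray(cycle_mid_rests, dtype=int)
    )
    if scales.size != cfg.n_cycles or mid_rests.size != cfg.n_cycles:
        raise ConfigError("per-cycle overrides must have n_cycles entries")

    T = cfg.stroke_T
    chunks: list[np.ndarray] = []
    stroke_windows: list[tuple[int, int]] = []
    stroke_peaks: list[int] = []
    cycle_windows: list[tuple[int, int]] = []
    touch_frames: list[int] = []
    pos = 0
    for i in range(cfg.n_cycles):
        chunks.append(np.zeros(r))
        pos += r
        fwd_start = pos
        chunks.append(scales[i] * stroke)  # toward the screen
        stroke_windows.append((pos, pos + T - 1))
        stroke_peaks.append(pos + cfg.T1)
        pos += T
        mid = int(mid_rests[i])
        touch_frames.append(pos + mid // 2)
        chunks.append(np.zeros(mid))
        pos += mid
        chunks.append(-scales[i] * stroke)  # back to rest
        stroke_windows.append((pos, pos + T - 1))
        stroke_peaks.append(pos + cfg.T1)
        pos += T
        cycle_windows.append((fwd_start, pos - 1))
    chunks.append(np.zeros(r))
    pos += r
    signed_v = np.concatenate(chunks)
    n = signed_v.size
    truth = SessionTruth(
        stroke_windows=tuple(stroke_windows),
        stroke_peaks=tuple(stroke_peaks),
        cycle_windows=tuple(cycle_windows),
        touch_frames=tuple(touch_frames),
        n_frames=n,
    )

    t = np.arange(n) * dt
    z = np.cumsum(signed_v) * dt
    # small smooth off-axis curvature so the motion is genuinely 3D
    x = 0.02 * np.sin(2.0 * np.pi * 0.11 * t)
    y = 0.015 * np.cos(2.0 * np.pi * 0.07 * t)
    position = np.column_stack([x, y, z])
    order = ["x", "y", "z"].index(screen_axis)
    if order != 2:
        position[:, [order, 2]] = position[:, [2, order]]
    if position_noise_sd > 0:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        position = position + rng.normal(0.0, position_noise_sd, position.shape)
    rec = Recording(
        time=t,
        position=position,
        sample_rate=sample_rate,
        screen_axis=screen_axis,
        subject_id=subject_id,
    )
    return rec, truth
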