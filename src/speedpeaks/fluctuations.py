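"""s-Peak trains, inter-peak-interval statistics, and the R-parameter.

The R-parameter quantifies how far the within-cycle speed-peak intervals
(s-IPIs) depart from an exponential (fully random) law:

    R = sum_j n_out_j * v_j^2 / sum_i n_i * v_i      over bins j with v_j > cutoff

where ``n_i`` are binned interval counts at bin value ``v_i``, and
``n_out_j = max(0, n_j - A*exp(-lambda*v_j))`` are the counts in excess of
an exponential fitted to the short-interval bins. R is 0 when every
interval follows the exponential and has units of frames.

Binning convention: with bin width ``w`` the i-th bin covers the half-open
interval ``(w*(i-1), w*i]`` and carries bin value ``v_i = w*i`` (its upper
edge). With the default width 2 and integer intervals the bin value is the
largest interval the bin holds, which keeps the hand-computable identities
exact (ten 20-frame intervals with no exponential mass give R = 20).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import PipelineError, UndefinedRError
from .io_model import PipelineConfig, Recording
from .preprocess import SpeedSeries, frequency_response_db, make_kernel, speed_profile
from .segmentation import CycleSet, detect_touches, remove_outlier_cycles, select_cycles

__all__ = [
    "SPeakTrain",
    "SPeakMatrix",
    "IPIHistogramFit",
    "local_maxima",
    "detect_speaks",
    "peaks_in_windows",
    "build_matrix",
    "compute_sipis",
    "build_histogram",
    "fit_exponential",
    "residual_counts",
    "compute_R",
    "AnalysisReport",
    "analyze_recording",
]

log = logging.getLogger("speedpeaks.fluctuations")


@dataclass(frozen=True)
class SPeakTrain:
    """Ordered s-Peak frame indices per cycle (absolute frames).

    ``bounds`` holds the (start, stop) frames of each owning cycle;
    ``touches`` the per-cycle touch frame where known (simulated stroke
    windows have none).
    """

    peaks_by_cycle: tuple[np.ndarray, ...]
    bounds: tuple[tuple[int, int], ...]
    touches: tuple[int, ...] | None = None

    def __post_init__(self):
        peaks = tuple(np.asarray(p, dtype=int) for p in self.peaks_by_cycle)
        object.__setattr__(self, "peaks_by_cycle", peaks)
        if len(peaks) != len(self.bounds):
            raise PipelineError("one peak list per cycle required")
        for p, (s, e) in zip(peaks, self.bounds):
            if p.size and (p.min() < s or p.max() > e):
                raise PipelineError("s-Peak outside its cycle bounds")
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise PipelineError("s-Peaks must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return len(self.peaks_by_cycle)

    @property
    def n_peaks(self) -> int:
        return int(sum(p.size for p in self.peaks_by_cycle))


@dataclass(frozen=True)
class SPeakMatrix:
    """Binary cycles-by-frames raster of s-Peak occurrences."""

    matrix: np.ndarray  # (N_i, N_j) of 0/1
    alignment: str  # 'touch' or 'mean-length'
    touch_column: int | None = None

    @property
    def column_counts(self) -> np.ndarray:
        """Per-frame s-Peak counts across cycles (raster bottom panel)."""
        return self.matrix.sum(axis=0)


@dataclass(frozen=True)
class IPIHistogramFit:
    """Binned s-IPI counts with an optional short-interval exponential fit."""

    bin_width: int
    bin_values: np.ndarray  # upper bin edges, frames
    counts: np.ndarray
    fit_cutoff: int
    amplitude: float | None = None  # A in A*exp(-lambda*v)
    rate: float | None = None  # lambda, per frame
    rate_stderr: float | None = None

    @property
    def n_intervals(self) -> int:
        return int(self.counts.sum())

    @property
    def fitted_counts(self) -> np.ndarray:
        if self.amplitude is None or self.rate is None:
            raise PipelineError("exponential fit not computed yet")
        return self.amplitude * np.exp(-self.rate * self.bin_values)


def local_maxima(x: np.ndarray) -> np.ndarray:
    """Strict local maxima of a 1-D series; a flat plateau that is higher
    than both neighbors counts once, at its first frame. Endpoints never
    qualify."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        return np.array([], dtype=int)
    d = np.diff(x)
    if not np.any(d == 0.0):
        return np.flatnonzero((d[:-1] > 0) & (d[1:] < 0)) + 1
    peaks = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(peaks, dtype=int)


def detect_speaks(speed: SpeedSeries, cs: CycleSet) -> SPeakTrain:
    """All speed local maxima falling inside cycle bounds (rest excluded)."""
    peaks = local_maxima(speed.speed)
    by_cycle = []
    for s, _, e in cs.cycles:
        by_cycle.append(peaks[(peaks >= s) & (peaks <= e)])
    return SPeakTrain(
        peaks_by_cycle=tuple(by_cycle),
        bounds=tuple((s, e) for (s, _, e) in cs.cycles),
        touches=tuple(t for (_, t, _) in cs.cycles),
    )


def peaks_in_windows(
    speed: np.ndarray, windows: tuple[tuple[int, int], ...]
) -> SPeakTrain:
    """Peak train over explicit (start, stop) inclusion windows.

    Used for simulated sessions where the stroke windows are known exactly
    and no segmentation is needed.
    """
    peaks = local_maxima(np.asarray(speed, dtype=float))
    by_window = tuple(peaks[(peaks >= s) & (peaks <= e)] for s, e in windows)
    return SPeakTrain(peaks_by_cycle=by_window, bounds=tuple(windows))


def build_matrix(
    train: SPeakTrain, alignment: str, cfg: PipelineConfig
) -> SPeakMatrix:
    """Raster matrix M(i, j) = 1 iff cycle i has an s-Peak at column j.

    ``'touch'`` alignment centers each row on its touch frame with
    ``raster_halfwidth`` columns on either side; ``'mean-length'`` alignment
    indexes columns from each cycle start over the mean cycle length.
    """
    if train.n_cycles == 0:
        raise PipelineError("cannot build a raster from an empty peak train")
    if alignment == "touch":
        if train.touches is None:
            raise PipelineError("touch alignment needs per-cycle touch frames")
        half = cfg.raster_halfwidth
        n_j = 2 * half
        m = np.zeros((train.n_cycles, n_j), dtype=np.int8)
        for i, (p, t) in enumerate(zip(train.peaks_by_cycle, train.touches)):
            cols = p - t + half
            cols = cols[(cols >= 0) & (cols < n_j)]
            m[i, cols] = 1
        return SPeakMatrix(matrix=m, alignment="touch", touch_column=half)
    if alignment == "mean-length":
        lengths = [e - s + 1 for s, e in train.bounds]
        n_j = int(round(float(np.mean(lengths))))
        m = np.zeros((train.n_cycles, n_j), dtype=np.int8)
        for i, (p, (s, _)) in enumerate(zip(train.peaks_by_cycle, train.bounds)):
            cols = p - s
            cols = cols[(cols >= 0) & (cols < n_j)]
            m[i, cols] = 1
        return SPeakMatrix(matrix=m, alignment="mean-length")
    raise PipelineError(f"unknown alignment {alignment!r}")


def compute_sipis(train: SPeakTrain) -> np.ndarray:
    """Nearest-neighbor s-Peak intervals (frames), within cycles only."""
    diffs = [np.diff(p) for p in train.peaks_by_cycle if p.size > 1]
    if not diffs:
        return np.array([], dtype=int)
    return np.concatenate(diffs)


def build_histogram(
    intervals: np.ndarray, cfg: PipelineConfig
) -> IPIHistogramFit:
    """Bin intervals into ``(w*(i-1), w*i]`` bins; trailing empties trimmed."""
    w = cfg.ipi_bin_width
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size and intervals.min() <= 0:
        raise PipelineError("intervals must be positive")
    if intervals.size == 0:
        return IPIHistogramFit(
            bin_width=w,
            bin_values=np.array([], dtype=float),
            counts=np.array([], dtype=int),
            fit_cutoff=cfg.fit_cutoff,
        )
    idx = np.ceil(intervals / w).astype(int) - 1  # 0-based bin index
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    values = w * (np.arange(n_bins) + 1.0)
    return IPIHistogramFit(
        bin_width=w,
        bin_values=values,
        counts=counts,
        fit_cutoff=cfg.fit_cutoff,
    )


def fit_exponential(hist: IPIHistogramFit, cfg: PipelineConfig) -> IPIHistogramFit:
    """Least-squares fit of log counts over the short-interval bins.

    Fit region: nonzero bins with value <= ``fit_cutoff``. Fewer than two
    such bins yields the degenerate fit A = 0, lambda = 0 (all mass above
    the cutoff becomes residual)."""
    sel = (hist.bin_values <= cfg.fit_cutoff) & (hist.counts > 0)
    v = hist.bin_values[sel]
    c = hist.counts[sel].astype(float)
    if v.size < 2:
        log.info("degenerate exponential fit: %d nonzero fit-region bins", v.size)
        return replace(hist, amplitude=0.0, rate=0.0, rate_stderr=None)
    logc = np.log(c)
    slope, icept = np.polyfit(v, logc, 1)
    stderr = None
    if v.size > 2:
        resid = logc - (slope * v + icept)
        sxx = float(np.sum((v - v.mean()) ** 2))
        s2 = float(np.sum(resid**2)) / (v.size - 2)
        stderr = float(np.sqrt(s2 / sxx))
    return replace(
        hist,
        amplitude=float(np.exp(icept)),
        rate=float(-slope),
        rate_stderr=stderr,
    )


def residual_counts(hist: IPIHistogramFit) -> np.ndarray:
    """Per-bin counts in excess of the fitted exponential, clipped at 0,
    for bins with value above the fit cutoff (0 elsewhere)."""
    fitted = hist.fitted_counts
    out = np.maximum(0.0, hist.counts - fitted)
    out[hist.bin_values <= hist.fit_cutoff] = 0.0
    return out


def compute_R(hist: IPIHistogramFit) -> float:
    """Residual non-exponential interval mass, squared-interval weighted,
    normalized by the interval-weighted total count. Units: frames."""
    if hist.n_intervals == 0:
        raise UndefinedRError("no s-IPIs: R is undefined")
    out = residual_counts(hist)
    above = hist.bin_values > hist.fit_cutoff
    numerator = float(np.sum(out[above] * hist.bin_values[above] ** 2))
    denominator = float(np.sum(hist.counts * hist.bin_values))
    if denominator == 0.0:
        raise UndefinedRError("zero interval-weighted count: R is undefined")
    return numerator / denominator


@dataclass(frozen=True)
class AnalysisReport:
    """End-to-end per-recording analysis products."""

    subject_id: str
    n_frames: int
    n_touches: int
    cycles: CycleSet
    n_cycles_rejected: int
    train: SPeakTrain
    matrix: SPeakMatrix
    histogram: IPIHistogramFit
    r_value: float
    response_20hz_db: float
    response_60hz_db: float

    def summary(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "n_frames": self.n_frames,
            "n_touches": self.n_touches,
            "n_cycles": self.cycles.n_cycles,
            "n_cycles_rejected": self.n_cycles_rejected,
            "mean_cycle_length": self.cycles.mean_cycle_length,
            "n_speaks": self.train.n_peaks,
            "n_sipis": self.histogram.n_intervals,
            "fit_amplitude": self.histogram.amplitude,
            "fit_rate": self.histogram.rate,
            "R": self.r_value,
            "response_20hz_db": self.response_20hz_db,
            "response_60hz_db": self.response_60hz_db,
        }


def analyze_recording(
    rec: Recording,
    cfg: PipelineConfig | None = None,
    alignment: str = "mean-length",
) -> AnalysisReport:
    """Run the full pipeline on one recording; deterministic given inputs."""
    cfg = cfg or PipelineConfig()
    kernel = make_kernel(cfg.smoothing_window)
    log.info(
        "smoothing window %d: response %.2f dB @20 Hz, %.2f dB @60 Hz",
        cfg.smoothing_window,
        frequency_response_db(kernel, rec.sample_rate, 20.0),
        frequency_response_db(kernel, rec.sample_rate, 60.0),
    )
    speed = speed_profile(rec, kernel)
    touches = detect_touches(rec, speed, cfg)
    if touches.size < 2:
        raise PipelineError(
            f"found {touches.size} touch point(s); at least 2 are needed to "
            "bound a cycle — check screen_axis and the recording content"
        )
    selected = select_cycles(rec, speed, touches, cfg)
    cycles = remove_outlier_cycles(selected, speed, cfg)
    if cycles.n_cycles == 0:
        raise PipelineError(
            "no cycles survived selection/outlier rules — the recording may "
            "be too short, too slow, or mis-axed"
        )
    train = detect_speaks(speed, cycles)
    matrix = build_matrix(train, alignment, cfg)
    intervals = compute_sipis(train)
    hist = fit_exponential(build_histogram(intervals, cfg), cfg)
    r_value = compute_R(hist)
    return AnalysisReport(
        subject_id=rec.subject_id,
        n_frames=rec.n_frames,
        n_touches=int(touches.size),
        cycles=cycles,
        n_cycles_rejected=selected.n_cycles - cycles.n_cycles,
        train=train,
        matrix=matrix,
        histogram=hist,
        r_value=r_value,
        response_20hz_db=frequency_response_db(kernel, rec.sample_rate, 20.0),
        response_60hz_db=frequency_response_db(kernel, rec.sample_rate, 60.0),
    )
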