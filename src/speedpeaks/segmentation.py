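"""Touch detection, forward-and-backward cycle selection, outlier removal.

Touches are high extremes of the screen-normal position; cycle start/stop
frames are screen-axis velocity reversals near the rest posture, picked
nearest to each touch subject to gap, displacement and speed rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import SpeedPeaksError
from .io_model import PipelineConfig, Recording
from .preprocess import SpeedSeries

__all__ = [
    "CycleSet",
    "detect_touches",
    "velocity_sign_changes",
    "select_cycles",
    "remove_outlier_cycles",
]

log = logging.getLogger("speedpeaks.segmentation")


@dataclass(frozen=True)
class CycleSet:
    """Time-ordered, non-overlapping (start, touch, stop) frame triples."""

    cycles: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        cycles = tuple(
            (int(s), int(t), int(e)) for (s, t, e) in self.cycles
        )
        object.__setattr__(self, "cycles", cycles)
        for s, t, e in cycles:
            if not s < t < e:
                raise SpeedPeaksError(f"cycle ({s}, {t}, {e}) is not ordered")
        for (_, _, e0), (s1, _, _) in zip(cycles, cycles[1:]):
            if s1 < e0:
                raise SpeedPeaksError("cycles overlap or are out of order")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def durations(self) -> np.ndarray:
        """Frame counts per cycle, start and stop inclusive."""
        return np.array([e - s + 1 for (s, _, e) in self.cycles], dtype=int)

    @property
    def mean_cycle_length(self) -> float:
        if not self.cycles:
            return 0.0
        return float(self.durations.mean())

    @property
    def touches(self) -> np.ndarray:
        return np.array([t for (_, t, _) in self.cycles], dtype=int)


def detect_touches(
    rec: Recording, speed: SpeedSeries | None, cfg: PipelineConfig
) -> np.ndarray:
    """Frame indices of screen touches.

    Local maxima of the screen-axis position kept only if above
    ``mean + touch_height_sd * SD`` of the whole recording's screen-axis
    position, with successive touches at least ``touch_min_separation``
    frames apart (of two closer candidates the higher survives). ``speed``
    is accepted for interface symmetry but unused: touches come from the
    positional trajectory alone.
    """
    pos = rec.screen_position
    height = pos.mean() + cfg.touch_height_sd * pos.std()
    peaks, _ = find_peaks(pos, height=height, distance=cfg.touch_min_separation)
    if peaks.size == 0:
        log.warning("no touch points detected (threshold %.4g m)", height)
    return peaks.astype(int)


def velocity_sign_changes(v: np.ndarray) -> np.ndarray:
    """Frames where a 1-D velocity changes direction.

    A strict sign flip between consecutive frames marks the first frame
    carrying the new sign; a run of exact zeros after a nonzero value marks
    the first zero frame.
    """
    v = np.asarray(v, dtype=float)
    out = []
    prev_sign = 0.0
    for i in range(len(v)):
        s = np.sign(v[i])
        if prev_sign != 0.0 and s != prev_sign:
            out.append(i)
        if s != 0.0:
            prev_sign = s
        elif prev_sign != 0.0:
            prev_sign = 0.0  # zero run: only its first frame is a candidate
    return np.asarray(out, dtype=int)


def select_cycles(
    rec: Recording,
    speed: SpeedSeries,
    touches: np.ndarray,
    cfg: PipelineConfig,
) -> CycleSet:
    """Pick a (start, touch, stop) triple per touch from velocity reversals.

    Candidates must (1) be screen-axis velocity direction changes, (2) lie
    at least ``startstop_min_gap`` frames from the touch (inclusive), (3)
    sit within ``displacement_fraction`` of the inter-touch reach amplitude
    from the rest extreme, (4) have speed below the reference average; among
    survivors the candidate nearest the touch wins. Touches with no
    qualifying start or stop are skipped and logged.
    """
    touches = np.asarray(touches, dtype=int)
    if touches.size < 2:
        if touches.size == 1:
            log.info("only one touch: no flanking structure, empty cycle set")
        return CycleSet(cycles=())

    n = rec.n_frames
    vz = speed.velocity[:, rec.screen_index]
    pos = rec.screen_position
    # recording edges count as candidates: the hand starts and ends at rest,
    # where a noiseless velocity has no crossing to flag
    candidates = np.unique(
        np.concatenate([[0], velocity_sign_changes(vz), [n - 1]])
    )
    mean_speed_recording = speed.mean_speed

    cycles: list[tuple[int, int, int]] = []
    prev_stop = -1
    for idx, touch in enumerate(touches):
        lo = int(touches[idx - 1]) if idx > 0 else 0
        hi = int(touches[idx + 1]) if idx + 1 < len(touches) else n - 1

        start = _pick_candidate(
            candidates, pos, speed, cfg, touch, lo, hi,
            side="start", mean_speed_recording=mean_speed_recording,
        )
        stop = _pick_candidate(
            candidates, pos, speed, cfg, touch, lo, hi,
            side="stop", mean_speed_recording=mean_speed_recording,
        )
        if start is None or stop is None:
            log.info(
                "touch at frame %d skipped: no qualifying %s",
                touch,
                "start" if start is None else "stop",
            )
            continue
        # a single rest between two cycles may host one shared reversal:
        # stop of one cycle and start of the next may coincide (interiors
        # stay disjoint); true interleaving is rejected
        if start < prev_stop or (cycles and start < cycles[-1][1]):
            log.info(
                "cycle at touch %d overlaps previous cycle; skipped", touch
            )
            continue
        cycles.append((start, int(touch), stop))
        prev_stop = stop
    return CycleSet(cycles=tuple(cycles))


def _pick_candidate(
    candidates: np.ndarray,
    pos: np.ndarray,
    speed: SpeedSeries,
    cfg: PipelineConfig,
    touch: int,
    lo: int,
    hi: int,
    side: str,
    mean_speed_recording: float,
) -> int | None:
    """Nearest qualifying start (before) or stop (after) frame for a touch."""
    if side == "start":
        region = candidates[(candidates >= lo) & (candidates < touch)]
        segment = slice(lo, touch + 1)
    else:
        region = candidates[(candidates > touch) & (candidates <= hi)]
        segment = slice(touch, hi + 1)
    if region.size == 0:
        return None

    # reach amplitude within the flanking segment, measured from the rest
    # extreme (segment minimum of the screen-axis position) up to the touch
    baseline = pos[segment].min()
    max_disp = pos[touch] - baseline
    if max_disp <= 0:
        return None

    mean_speed = mean_speed_recording
    if cfg.speed_reference == "segment":
        mean_speed = float(speed.speed[segment].mean())

    ok = (
        (np.abs(region - touch) >= cfg.startstop_min_gap)
        & (pos[region] - baseline <= cfg.displacement_fraction * max_disp)
        & (speed.speed[region] < mean_speed)
    )
    qualified = region[ok]
    if qualified.size == 0:
        return None
    nearest = qualified[np.argmin(np.abs(qualified - touch))]
    return int(nearest)


def remove_outlier_cycles(
    cs: CycleSet, speed: SpeedSeries, cfg: PipelineConfig
) -> CycleSet:
    """Drop cycles longer than ``cycle_max_duration`` frames or whose peak
    speed falls below ``cycle_min_maxspeed``."""
    kept = []
    n_long = n_slow = 0
    for s, t, e in cs.cycles:
        if e - s + 1 > cfg.cycle_max_duration:
            n_long += 1
            continue
        if float(speed.speed[s : e + 1].max()) < cfg.cycle_min_maxspeed:
            n_slow += 1
            continue
        kept.append((s, t, e))
    if n_long or n_slow:
        log.info(
            "outlier removal: %d over-long, %d under-speed cycles dropped",
            n_long,
            n_slow,
        )
    return CycleSet(cycles=tuple(kept))
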