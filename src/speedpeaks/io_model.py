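"""Data model and text I/O for 3D reaching kinematics.

The on-disk format is a minimal UTF-8 CSV dialect: a header row
``time,x,y,z``, one frame per row, SI units (seconds, meters). Optional
``#``-prefixed comment lines before the header carry ``subject_id``,
``sample_rate`` and ``screen_axis`` metadata as ``# key: value`` pairs.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, FormatError, RecordingValidationError

__all__ = [
    "AXES",
    "Recording",
    "PipelineConfig",
    "read_recording",
    "write_recording",
    "load_config",
    "setup_logging",
]

AXES = ("x", "y", "z")

#: relative tolerance on the uniformity of the time grid
TIME_RTOL = 1e-6

log = logging.getLogger("speedpeaks")


def setup_logging(verbose: bool = False) -> None:
    """Route timestamped log lines to stderr; ``verbose`` enables DEBUG."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("speedpeaks")
    root.handlers[:] = [handler]
    root.setLevel(logging.DEBUG if verbose else logging.INFO)


@dataclass(frozen=True)
class Recording:
    """Uniformly sampled 3D hand-position time series.

    Parameters
    ----------
    time
        Sample times in seconds, strictly increasing on a uniform grid of
        step ``1/sample_rate``.
    position
        Array of shape ``(n, 3)`` holding x, y, z positions in meters.
    sample_rate
        Sampling frequency in Hz.
    screen_axis
        Which coordinate (``'x'``, ``'y'`` or ``'z'``) is perpendicular to
        the touch screen.
    subject_id
        Free-text identifier.
    """

    time: np.ndarray
    position: np.ndarray
    sample_rate: float = 240.0
    screen_axis: str = "z"
    subject_id: str = ""

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        position = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "position", position)
        if position.ndim != 2 or position.shape[1] != 3:
            raise RecordingValidationError(
                f"position must have shape (n, 3), got {position.shape}"
            )
        if time.ndim != 1 or time.shape[0] != position.shape[0]:
            raise RecordingValidationError(
                "time and position must have the same number of frames"
            )
        if len(time) < 2:
            raise RecordingValidationError("a Recording needs at least 2 frames")
        if self.screen_axis not in AXES:
            raise RecordingValidationError(
                f"screen_axis must be one of {AXES}, got {self.screen_axis!r}"
            )
        if not np.isfinite(self.sample_rate) or self.sample_rate <= 0:
            raise RecordingValidationError("sample_rate must be positive and finite")
        dt = 1.0 / self.sample_rate
        diffs = np.diff(time)
        bad = np.flatnonzero(np.abs(diffs - dt) > TIME_RTOL * dt)
        if bad.size:
            i = int(bad[0])
            raise RecordingValidationError(
                f"non-uniform sampling at frame {i + 1}: step {diffs[i]:.9g} s "
                f"vs expected {dt:.9g} s (sample_rate {self.sample_rate:g} Hz)",
                frame=i + 1,
            )

    @property
    def n_frames(self) -> int:
        return self.time.shape[0]

    @property
    def screen_index(self) -> int:
        return AXES.index(self.screen_axis)

    @property
    def screen_position(self) -> np.ndarray:
        """Position component perpendicular to the screen."""
        return self.position[:, self.screen_index]


@dataclass(frozen=True)
class PipelineConfig:
    """Numeric constants of the analysis pipeline.

    Frame-count fields are counts (durations), not indices; frames are
    0-indexed internally. One frame is ``1/sample_rate`` seconds.
    """

    smoothing_window: int = 25
    ipi_bin_width: int = 2
    fit_cutoff: int = 10
    touch_min_separation: int = 300
    touch_height_sd: float = 1.0
    startstop_min_gap: int = 100
    displacement_fraction: float = 1.0 / 3.0
    cycle_max_duration: int = 600
    cycle_min_maxspeed: float = 0.2
    raster_halfwidth: int = 400
    # 'recording' = mean speed over the whole recording (default reading of
    # the start/stop speed rule); 'segment' = mean over each inter-touch span
    speed_reference: str = "recording"

    def __post_init__(self):
        if self.smoothing_window < 3 or self.smoothing_window % 2 == 0:
            raise ConfigError("smoothing_window must be odd and >= 3")
        for name in (
            "ipi_bin_width",
            "fit_cutoff",
            "touch_min_separation",
            "startstop_min_gap",
            "cycle_max_duration",
            "raster_halfwidth",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if not 0.0 < self.displacement_fraction < 1.0:
            raise ConfigError("displacement_fraction must be in (0, 1)")
        if self.touch_height_sd < 0:
            raise ConfigError("touch_height_sd must be nonnegative")
        if self.cycle_min_maxspeed < 0:
            raise ConfigError("cycle_min_maxspeed must be nonnegative")
        if self.speed_reference not in ("recording", "segment"):
            raise ConfigError("speed_reference must be 'recording' or 'segment'")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML key/value file.

    ``overrides`` (e.g. CLI flags) take precedence over file values; ``None``
    overrides are ignored.
    """
    values: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise FormatError(f"config file {path} must contain a mapping")
        unknown = set(loaded) - {f.name for f in dataclasses.fields(PipelineConfig)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)


_META_KEYS = ("subject_id", "sample_rate", "screen_axis")


def read_recording(path: str | Path, config: PipelineConfig | None = None) -> Recording:
    """Parse a kinematics CSV file into a validated :class:`Recording`.

    Raises :class:`FormatError` on structural problems (bad header, missing
    or non-numeric fields) and :class:`RecordingValidationError` when the
    parsed values violate Recording invariants.
    """
    meta: dict = {}
    header_seen = False
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                for sep in (":", "="):
                    if sep in body:
                        key, _, val = body.partition(sep)
                        key = key.strip()
                        if key in _META_KEYS:
                            meta[key] = val.strip()
                        break
                continue
            fields = [f.strip() for f in line.split(",")]
            if not header_seen:
                if fields != ["time", "x", "y", "z"]:
                    raise FormatError(
                        f"{path}:{lineno}: expected header 'time,x,y,z', "
                        f"got {line!r}"
                    )
                header_seen = True
                continue
            if len(fields) != 4 or any(f == "" for f in fields):
                raise FormatError(
                    f"{path}:{lineno}: expected 4 comma-separated values, got {line!r}"
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
    if not header_seen:
        raise FormatError(f"{path}: missing 'time,x,y,z' header")
    if len(rows) < 2:
        raise RecordingValidationError(f"{path}: fewer than 2 data rows")
    data = np.asarray(rows, dtype=float)
    sample_rate = float(meta.get("sample_rate", 240.0))
    return Recording(
        time=data[:, 0],
        position=data[:, 1:4],
        sample_rate=sample_rate,
        screen_axis=meta.get("screen_axis", "z"),
        subject_id=meta.get("subject_id", ""),
    )


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write ``rec`` so that :func:`read_recording` reproduces it.

    Floats are stored in shortest round-trip form (lossless, so re-read
    values are equal well beyond 9 significant digits).
    """
    with open(path, "w", encoding="utf-8") as fh:
        if rec.subject_id:
            fh.write(f"# subject_id: {rec.subject_id}\n")
        fh.write(f"# sample_rate: {float(rec.sample_rate)!r}\n")
        fh.write(f"# screen_axis: {rec.screen_axis}\n")
        fh.write("time,x,y,z\n")
        for t, (x, y, z) in zip(rec.time, rec.position):
            fh.write(f"{float(t)!r},{float(x)!r},{float(y)!r},{float(z)!r}\n")
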