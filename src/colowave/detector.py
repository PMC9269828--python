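"""Exponential-smoothing outlier detection on the image maximum amplitude.

Absolute image amplitudes are not comparable between trajectories (different
colons, different wall distances), so a polyp is flagged *relative to the
recent history of its own trajectory*: the maximum amplitude ``y_n`` of each
reconstructed frame is forecast by simple exponential smoothing,

    s_{n+1} = alpha * y_n + (1 - alpha) * s_n,

with a confidence band built from the exponentially smoothed absolute
one-step deviation,

    w_{n+1} = alpha * |y_n - s_{n+1}| + (1 - alpha) * w_n,
    band_{n+1} = s_{n+1} +- delta * w_{n+1},      delta > 1.

A frame whose observed maximum lies strictly above the band forecast for it
raises the polyp alarm (the acoustic signal in the clinical device).  The
trigger is scale-free: multiplying every ``y_n`` of a trajectory by a positive
constant leaves the alarm set unchanged.

The state is seeded with the first scored frame (``s = y_1``, ``w = 0``) and a
short warm-up suppresses alarms while the band adapts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import calibrate_trajectory
from .focuser import ImageGrid, reconstruct
from .frames_io import Trajectory

__all__ = [
    "DetectorConfig",
    "DetectorState",
    "FrameScore",
    "DetectionResult",
    "update_level",
    "update_band",
    "score_frame",
    "score_series",
    "run_detector",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Tuning constants of the alarm detector.

    ``alpha`` in [0, 1] sets the forecast memory (1 = track the last value);
    ``delta`` > 1 the band half-width in smoothed-deviation units; alarms are
    suppressed for the first ``warmup_frames`` scored frames.  With
    ``upper_only`` (default) only excursions above the band alarm — a lesion
    raises the amplitude, it never lowers it.  ``deviation_reference``
    selects whether the deviation recursion measures ``|y - s_{n+1}|``
    (default) or ``|y - s_n|``.
    """

    alpha: float = 0.3
    delta: float = 3.0
    warmup_frames: int = 3
    upper_only: bool = True
    deviation_reference: str = "next_level"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not self.delta > 1.0:
            raise ValueError("delta must be greater than 1")
        if self.warmup_frames < 1:
            raise ValueError("warmup_frames must be at least 1")
        if self.deviation_reference not in ("next_level", "level"):
            raise ValueError("deviation_reference must be 'next_level' or 'level'")


@dataclass(frozen=True)
class DetectorState:
    """Running level and deviation estimates."""

    level: float
    deviation: float = 0.0
    frame_count: int = 0

    def __post_init__(self) -> None:
        if self.deviation < 0:
            raise ValueError("deviation must be non-negative")
        if not np.isfinite(self.level):
            raise ValueError("level must be finite")


def update_level(level: float, y: float, alpha: float) -> float:
    """s_{n+1} = alpha * y_n + (1 - alpha) * s_n."""
    return alpha * y + (1.0 - alpha) * level


def update_band(
    deviation: float,
    y: float,
    next_level: float,
    alpha: float,
    delta: float,
) -> tuple[float, float, float]:
    """Advance the deviation and return (band_low, band_high, next_deviation).

    The band is symmetric about ``next_level`` with half-width
    ``delta * w_{n+1}``; it collapses to a point on constant input.
    """
    next_dev = alpha * abs(y - next_level) + (1.0 - alpha) * deviation
    half = delta * next_dev
    return next_level - half, next_level + half, next_dev


def score_frame(
    state: DetectorState, y: float, config: DetectorConfig
) -> tuple[bool, DetectorState]:
    """Score one observation against the band forecast by ``state``.

    The alarm fires on ``y`` strictly above the forecast upper band (and, with
    ``upper_only=False``, also strictly below the lower band); it is forced
    false during warm-up.  The state is then advanced with the smoothing
    recursions.
    """
    band_high = state.level + config.delta * state.deviation
    band_low = state.level - config.delta * state.deviation
    alarm = y > band_high or (not config.upper_only and y < band_low)
    if state.frame_count < config.warmup_frames:
        alarm = False
    next_level = update_level(state.level, y, config.alpha)
    ref = next_level if config.deviation_reference == "next_level" else state.level
    next_dev = config.alpha * abs(y - ref) + (1.0 - config.alpha) * state.deviation
    return alarm, DetectorState(
        level=next_level, deviation=next_dev, frame_count=state.frame_count + 1
    )


@dataclass(frozen=True)
class FrameScore:
    """Per-frame detection record; ``scored`` is false for frame 0 and warm-up."""

    frame_index: int
    z_mm: float
    y: float
    level: float
    band_low: float
    band_high: float
    alarm: bool
    scored: bool


@dataclass
class DetectionResult:
    """Per-frame alarm records for one trajectory."""

    records: list[FrameScore]
    config: DetectorConfig

    @property
    def alarm_frames(self) -> set[int]:
        return {r.frame_index for r in self.records if r.alarm}

    @property
    def scored_frames(self) -> set[int]:
        return {r.frame_index for r in self.records if r.scored}

    def y_series(self) -> np.ndarray:
        return np.array([r.y for r in self.records])

    def to_rows(self) -> list[dict]:
        return [
            {
                "frame_index": r.frame_index,
                "z_mm": r.z_mm,
                "y": r.y,
                "level": r.level,
                "band_low": r.band_low,
                "band_high": r.band_high,
                "alarm": int(r.alarm),
            }
            for r in self.records
        ]


def score_series(
    ys: np.ndarray,
    config: DetectorConfig,
    z_mm: np.ndarray | None = None,
    first_index: int = 1,
) -> list[FrameScore]:
    """Run the smoothing recursion over a series of image maxima.

    ``ys[0]`` corresponds to frame ``first_index`` (frame 0 is never scored).
    The state is initialised at the first observation, so the first record's
    band collapses onto it.
    """
    ys = np.asarray(ys, dtype=float)
    if z_mm is None:
        z_mm = np.full(len(ys), np.nan)
    records: list[FrameScore] = []
    state = None
    for i, y in enumerate(ys):
        if state is None:
            state = DetectorState(level=float(y), deviation=0.0, frame_count=0)
        band_high = state.level + config.delta * state.deviation
        band_low = state.level - config.delta * state.deviation
        level = state.level
        in_warmup = state.frame_count < config.warmup_frames
        alarm, state = score_frame(state, float(y), config)
        records.append(
            FrameScore(
                frame_index=first_index + i,
                z_mm=float(z_mm[i]),
                y=float(y),
                level=level,
                band_low=band_low,
                band_high=band_high,
                alarm=alarm,
                scored=not in_warmup,
            )
        )
    return records


def run_detector(
    traj: Trajectory,
    config: DetectorConfig | None = None,
    grid: ImageGrid | None = None,
    metric: str = "mhd",
    pool_window: int | None = None,
    field_power: int = 2,
) -> DetectionResult:
    """Full per-frame pipeline: calibrate → reconstruct → score.

    Frame 0 has no reference and is reported unscored with ``y = 0`` and no
    alarm.  Deterministic given the trajectory and configuration.
    """
    if config is None:
        config = DetectorConfig()
    if grid is None:
        grid = ImageGrid()
    min_len = config.warmup_frames + 2
    if len(traj) < min_len:
        raise ValueError(
            f"trajectory has {len(traj)} frames; the detector needs at least "
            f"{min_len} (warmup_frames + 2)"
        )
    cals = calibrate_trajectory(traj, metric=metric, pool_window=pool_window)
    ys = []
    for cal in cals[1:]:
        img = reconstruct(cal, traj.geometry, grid, traj.frequency_hz,
                          field_power=field_power)
        ys.append(img.max_amplitude)
    z = traj.z_positions()
    records = [
        FrameScore(
            frame_index=0, z_mm=float(z[0]), y=0.0, level=0.0,
            band_low=0.0, band_high=0.0, alarm=False, scored=False,
        )
    ]
    records.extend(score_series(np.array(ys), config, z_mm=z[1:], first_index=1))
    return DetectionResult(records=records, config=config)
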