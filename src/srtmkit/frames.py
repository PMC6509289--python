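"""Acquisition frame schedules and SIF-style timing files.

A dynamic PET acquisition is divided into contiguous frames of increasing
duration (short frames early to capture tracer delivery, long frames late).
:class:`FrameSchedule` is the shared time grid for every curve and image in
a study; schedules are stored in seconds and converted to minutes at the
kinetic-model boundary, where rate constants are per-minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Tuple

import numpy as np

from .exceptions import ScheduleError

__all__ = ["FrameSchedule", "make_frame_schedule", "read_sif", "write_sif"]


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame start times and durations, in seconds.

    Frames must be positive-duration, time-ordered and non-overlapping;
    midpoints are therefore strictly increasing.
    """

    frame_start_s: np.ndarray
    frame_duration_s: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.frame_start_s, dtype=float)
        dur = np.asarray(self.frame_duration_s, dtype=float)
        object.__setattr__(self, "frame_start_s", start)
        object.__setattr__(self, "frame_duration_s", dur)
        if start.ndim != 1 or dur.shape != start.shape:
            raise ScheduleError("frame starts and durations must be 1-D and equal length")
        if start.size == 0:
            raise ScheduleError("schedule needs at least one frame")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(dur)):
            raise ScheduleError("frame times must be finite")
        if np.any(dur <= 0):
            raise ScheduleError("frame durations must be positive")
        ends = start + dur
        if np.any(start[1:] < ends[:-1] - 1e-9) or np.any(np.diff(start) <= 0):
            raise ScheduleError("frames must be time-ordered and non-overlapping")

    @property
    def n_frames(self) -> int:
        return self.frame_start_s.size

    @property
    def frame_end_s(self) -> np.ndarray:
        return self.frame_start_s + self.frame_duration_s

    @property
    def mid_s(self) -> np.ndarray:
        return self.frame_start_s + 0.5 * self.frame_duration_s

    @property
    def mid_min(self) -> np.ndarray:
        """Frame midpoints in minutes — the model's sampling grid."""
        return self.mid_s / 60.0

    @property
    def duration_min(self) -> np.ndarray:
        return self.frame_duration_s / 60.0

    @property
    def total_duration_s(self) -> float:
        return float(self.frame_duration_s.sum())

    def same_grid(self, other: "FrameSchedule", atol: float = 1e-6) -> bool:
        return (
            self.n_frames == other.n_frames
            and np.allclose(self.frame_start_s, other.frame_start_s, atol=atol)
            and np.allclose(self.frame_duration_s, other.frame_duration_s, atol=atol)
        )


def make_frame_schedule(blocks: Sequence[Tuple[int, float]]) -> FrameSchedule:
    """Build a contiguous schedule starting at t=0 from (count, duration_s) blocks.

    ``make_frame_schedule([(30, 10), (15, 60), (5, 300)])`` reproduces a
    45-minute small-animal acquisition with 50 frames.
    """
    if not blocks:
        raise ScheduleError("empty frame specification")
    durations = []
    for count, dur in blocks:
        if count <= 0 or dur <= 0:
            raise ScheduleError(f"invalid block ({count}, {dur}): counts and durations must be positive")
        durations.extend([float(dur)] * int(count))
    dur = np.array(durations)
    start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
    return FrameSchedule(start, dur)


def write_sif(schedule: FrameSchedule, path) -> None:
    """Write a SIF-style timing file: one ``start end`` row per frame, seconds."""
    lines = [
        f"{s:.6g}\t{e:.6g}"
        for s, e in zip(schedule.frame_start_s, schedule.frame_end_s)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sif(path) -> FrameSchedule:
    """Read a SIF-style timing file (start/end seconds per row).

    Leading header lines that do not parse as two numbers are skipped;
    extra trailing columns are ignored.
    """
    starts, ends = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) < 2:
            continue
        try:
            s, e = float(parts[0]), float(parts[1])
        except ValueError:
            continue
        starts.append(s)
        ends.append(e)
    if not starts:
        raise ScheduleError(f"no frame rows found in {path}")
    start = np.array(starts)
    end = np.array(ends)
    return FrameSchedule(start, end - start)
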