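"""Frame schedules, time-activity curves, and radioactive-decay bookkeeping.

Dynamic PET acquisitions are rebinned into frames of variable duration;
a long protocol may be split into two acquisition parts with a break in
between (e.g. a 90-min scan, a 60-min gap, then a 75-min scan).  All
downstream kinetic modelling works on region-level time-activity curves
(TACs) defined on such a schedule, decay-corrected to a common reference
time so that both parts live on one radioactivity scale.

Internal time unit is minutes post injection; file formats carry seconds
(the unit in which frame durations are conventionally listed) and are
converted at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PART1",
    "PART2",
    "F18_HALF_LIFE_MIN",
    "DecayConstants",
    "FrameSchedule",
    "TimeActivityCurve",
    "ScheduleConflictError",
    "build_frame_schedule",
    "frame_midtimes",
    "decay_correct",
    "concatenate_sessions",
]

PART1 = "PART1"
PART2 = "PART2"

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.771


class ScheduleConflictError(ValueError):
    """Raised when frame intervals overlap or parts are ordered wrongly."""


@dataclass(frozen=True)
class DecayConstants:
    """Half-life (minutes) and the derived decay constant lambda (1/min)."""

    half_life: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if not (self.half_life > 0 and math.isfinite(self.half_life)):
            raise ValueError(f"half_life must be positive, got {self.half_life}")

    @property
    def lam(self) -> float:
        return math.log(2.0) / self.half_life


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered PET frame timing across up to two acquisition parts.

    Frames are half-open intervals ``[start, end)`` in seconds post
    injection.  Within a part frames are contiguous; all PART1 frames
    precede all PART2 frames, with an arbitrary gap in between.
    """

    starts_s: np.ndarray
    ends_s: np.ndarray
    part_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts_s, dtype=float)
        ends = np.asarray(self.ends_s, dtype=float)
        object.__setattr__(self, "starts_s", starts)
        object.__setattr__(self, "ends_s", ends)
        if starts.shape != ends.shape or starts.ndim != 1:
            raise ValueError("starts and ends must be 1-D arrays of equal length")
        if len(self.part_labels) != starts.size:
            raise ValueError("one part label per frame required")
        if starts.size == 0:
            return
        if not np.all(ends > starts):
            raise ScheduleConflictError("every frame needs strictly positive duration")
        if not np.all(np.diff(starts) > 0):
            raise ScheduleConflictError("frame starts must be strictly increasing")
        if not np.all(starts[1:] >= ends[:-1] - 1e-9):
            raise ScheduleConflictError("frames must not overlap")
        labels = self.part_labels
        if any(lab not in (PART1, PART2) for lab in labels):
            raise ValueError(f"part labels must be {PART1!r} or {PART2!r}")
        # PART1 block strictly before PART2 block
        seen2 = False
        for lab in labels:
            if lab == PART2:
                seen2 = True
            elif seen2:
                raise ScheduleConflictError("all PART1 frames must precede PART2")
        # contiguity within each part
        for i in range(1, starts.size):
            if labels[i] == labels[i - 1] and abs(starts[i] - ends[i - 1]) > 1e-9:
                raise ScheduleConflictError(
                    f"frames {i - 1} and {i} in {labels[i]} are not contiguous"
                )

    def __len__(self) -> int:
        return int(self.starts_s.size)

    @property
    def durations_s(self) -> np.ndarray:
        return self.ends_s - self.starts_s

    @property
    def starts_min(self) -> np.ndarray:
        return self.starts_s / 60.0

    @property
    def ends_min(self) -> np.ndarray:
        return self.ends_s / 60.0

    @property
    def durations_min(self) -> np.ndarray:
        return self.durations_s / 60.0

    @property
    def part_boundary_s(self) -> float | None:
        """End of PART1 in seconds, or None if the schedule has one part."""
        mask = np.array([lab == PART1 for lab in self.part_labels])
        if mask.all() or not mask.any():
            return None
        return float(self.ends_s[mask][-1])


@dataclass
class TimeActivityCurve:
    """Per-region decay-corrected activity (kBq/mL) on a frame schedule.

    ``values`` is (n_frames, n_regions); ``reference_time_s`` is the decay
    reference (0 = start of the first acquisition part).  Small negative
    values are tolerated up to ``noise_floor`` (reconstruction noise).
    """

    schedule: FrameSchedule
    regions: tuple[str, ...]
    values: np.ndarray
    reference_time_s: float = 0.0
    noise_floor: float = field(default=5.0, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames x regions)")
        if self.values.shape != (len(self.schedule), len(self.regions)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.schedule)} frames x {len(self.regions)} regions"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activities must be finite")
        if self.values.size and self.values.min() < -abs(self.noise_floor):
            raise ValueError(
                f"negative activity {self.values.min():.3g} exceeds the "
                f"noise floor {self.noise_floor:.3g}"
            )

    def region_values(self, region: str) -> np.ndarray:
        try:
            j = self.regions.index(region)
        except ValueError:
            raise KeyError(f"unknown region {region!r}") from None
        return self.values[:, j]


def build_frame_schedule(
    part1_durations_s: Sequence[float],
    part2_durations_s: Sequence[float] = (),
    part2_start_s: float | None = None,
) -> FrameSchedule:
    """Build a schedule from per-part frame durations (seconds).

    Part 1 starts at 0; part 2, if present, starts at ``part2_start_s``
    which must not fall before the end of part 1.
    """
    d1 = np.asarray(part1_durations_s, dtype=float)
    d2 = np.asarray(part2_durations_s, dtype=float)
    if d1.size and d1.min() <= 0 or d2.size and d2.min() <= 0:
        raise ValueError("frame durations must be positive")
    ends1 = np.cumsum(d1)
    starts1 = ends1 - d1
    if d2.size:
        if part2_start_s is None:
            raise ValueError("part2_start_s required when part 2 has frames")
        end1 = ends1[-1] if d1.size else 0.0
        if part2_start_s < end1:
            raise ScheduleConflictError(
                f"part 2 start {part2_start_s} s lies inside part 1 (ends {end1} s)"
            )
        ends2 = part2_start_s + np.cumsum(d2)
        starts2 = ends2 - d2
    else:
        starts2 = ends2 = np.empty(0)
    return FrameSchedule(
        starts_s=np.concatenate([starts1, starts2]),
        ends_s=np.concatenate([ends1, ends2]),
        part_labels=(PART1,) * d1.size + (PART2,) * d2.size,
    )


def frame_midtimes(schedule: FrameSchedule) -> np.ndarray:
    """Frame interval midpoints in minutes post injection."""
    return (schedule.starts_s + schedule.ends_s) / 2.0 / 60.0


def decay_correct(
    values: np.ndarray,
    times_min: np.ndarray,
    constants: DecayConstants = DecayConstants(),
    reference_time_min: float = 0.0,
) -> np.ndarray:
    """Decay-correct activities measured at ``times_min`` to a reference time.

    Multiplies by exp(lambda * (t - t_ref)); the inverse transform (swap of
    sign) recovers the input exactly.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times_min, dtype=float)
    if not (np.all(np.isfinite(values)) and np.all(np.isfinite(times))):
        raise ValueError("non-finite inputs to decay correction")
    return values * np.exp(constants.lam * (times - reference_time_min))


def concatenate_sessions(
    tac1: TimeActivityCurve, tac2: TimeActivityCurve
) -> TimeActivityCurve:
    """Join the two acquisition parts of a split protocol into one TAC.

    Both inputs must share region labels and decay reference time, and
    every frame of ``tac2`` must start after the last frame of ``tac1``
    ends; the gap between parts simply contains no frames.
    """
    if tac1.regions != tac2.regions:
        raise ValueError("region lists differ between sessions")
    if abs(tac1.reference_time_s - tac2.reference_time_s) > 1e-9:
        raise ValueError("sessions are decay-corrected to different reference times")
    if len(tac2.schedule) == 0:
        return tac1
    if len(tac1.schedule) and tac2.schedule.starts_s[0] < tac1.schedule.ends_s[-1]:
        raise ScheduleConflictError("part 2 frames overlap part 1")
    n1 = len(tac1.schedule)
    schedule = FrameSchedule(
        starts_s=np.concatenate([tac1.schedule.starts_s, tac2.schedule.starts_s]),
        ends_s=np.concatenate([tac1.schedule.ends_s, tac2.schedule.ends_s]),
        part_labels=(PART1,) * n1 + (PART2,) * len(tac2.schedule),
    )
    return TimeActivityCurve(
        schedule=schedule,
        regions=tac1.regions,
        values=np.vstack([tac1.values, tac2.values]),
        reference_time_s=tac1.reference_time_s,
        noise_floor=max(tac1.noise_floor, tac2.noise_floor),
    )
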