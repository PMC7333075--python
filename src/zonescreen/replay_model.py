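"""Replay data model and preprocessing.

A *replay* is the stored recording of one assessment drive: an ordered
sequence of multichannel frames (vehicle pose, pedal and steering inputs,
lane offset, turn-signal and scan-button state, posted speed limit) captured
at roughly 10 Hz after on-capture downsampling from 60 Hz.  This module owns
the on-disk dialect (JSONL, one frame per line), the cohort outcome table,
and the preprocessing applied before any analysis: subsampling, truncation
to the first frame in motion, and workflow-completion filtering.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FRAME_COLUMNS",
    "TURN_SIGNAL_STATES",
    "Frame",
    "DriveRecording",
    "CohortRecord",
    "ReplayParseError",
    "ReplayValidationError",
    "EmptyDriveError",
    "read_replay",
    "write_replay",
    "downsample",
    "truncate_at_motion",
    "apply_sample_filters",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: Column order of the frame table; also the JSONL key set.
FRAME_COLUMNS = (
    "t",
    "x",
    "y",
    "heading",
    "speed",
    "brake",
    "throttle",
    "steering",
    "lane_offset",
    "turn_signal",
    "scan_left",
    "scan_right",
    "posted_limit",
)

TURN_SIGNAL_STATES = ("none", "left", "right")

_FLOAT_COLS = ("t", "x", "y", "heading", "speed", "brake", "throttle",
               "steering", "lane_offset", "posted_limit")
_BOOL_COLS = ("scan_left", "scan_right")


class ReplayParseError(ValueError):
    """A replay file line could not be parsed."""


class ReplayValidationError(ValueError):
    """A parsed recording violates a frame or recording invariant."""


class EmptyDriveError(ValueError):
    """Preprocessing left no usable frames; the sample should be excluded."""


@dataclass(frozen=True)
class Frame:
    """One sampled instant of a drive.

    Units: seconds, metres, radians, m/s.  ``brake`` and ``throttle`` are
    fractions of full pedal depression in [0, 1]; ``steering`` is the signed
    fraction of full wheel rotation in [-1, 1] (negative = left);
    ``lane_offset`` is the signed lateral distance from the lane centreline
    in metres (positive = right of centre).
    """

    t: float
    x: float
    y: float
    heading: float
    speed: float
    brake: float
    throttle: float
    steering: float
    lane_offset: float
    turn_signal: str = "none"
    scan_left: bool = False
    scan_right: bool = False
    posted_limit: float = 15.6464  # 35 mph

    def __post_init__(self) -> None:
        if not 0.0 <= self.brake <= 1.0:
            raise ReplayValidationError(f"brake {self.brake} outside [0, 1]")
        if not 0.0 <= self.throttle <= 1.0:
            raise ReplayValidationError(f"throttle {self.throttle} outside [0, 1]")
        if not -1.0 <= self.steering <= 1.0:
            raise ReplayValidationError(f"steering {self.steering} outside [-1, 1]")
        if self.speed < 0.0:
            raise ReplayValidationError(f"speed {self.speed} negative")
        if self.posted_limit <= 0.0:
            raise ReplayValidationError(f"posted_limit {self.posted_limit} not positive")
        if self.turn_signal not in TURN_SIGNAL_STATES:
            raise ReplayValidationError(f"turn_signal {self.turn_signal!r} invalid")


@dataclass
class DriveRecording:
    """Ordered frames of one assessment drive.

    ``frames`` is a DataFrame with columns :data:`FRAME_COLUMNS`; times are
    strictly increasing.  ``nominal_rate`` is the approximate post-capture
    sampling rate in Hz (the true elapsed time between frames is kept in
    ``t``; frames are never resampled onto a uniform grid).
    """

    drive_id: str
    environment_id: int
    frames: pd.DataFrame
    nominal_rate: float = 10.0

    def __post_init__(self) -> None:
        self.frames = self.frames.reset_index(drop=True)
        validate_frames(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def channel(self, name: str) -> np.ndarray:
        return self.frames[name].to_numpy()

    def replace_frames(self, frames: pd.DataFrame) -> "DriveRecording":
        return DriveRecording(self.drive_id, self.environment_id, frames,
                              self.nominal_rate)


def validate_frames(frames: pd.DataFrame) -> None:
    """Check recording-level invariants; raise ReplayValidationError."""
    missing = [c for c in FRAME_COLUMNS if c not in frames.columns]
    if missing:
        raise ReplayValidationError(f"missing frame columns: {missing}")
    if len(frames) == 0:
        raise ReplayValidationError("recording has no frames")
    t = frames["t"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        bad = int(np.argmin(np.diff(t) > 0))
        raise ReplayValidationError(
            f"frame times not strictly increasing at index {bad + 1}")
    for col, lo, hi in (("brake", 0.0, 1.0), ("throttle", 0.0, 1.0),
                        ("steering", -1.0, 1.0)):
        v = frames[col].to_numpy(dtype=float)
        if np.any(v < lo) or np.any(v > hi):
            raise ReplayValidationError(f"{col} outside [{lo}, {hi}]")
    if np.any(frames["speed"].to_numpy(dtype=float) < 0):
        raise ReplayValidationError("negative speed")
    if np.any(frames["posted_limit"].to_numpy(dtype=float) <= 0):
        raise ReplayValidationError("non-positive posted_limit")
    bad_signal = ~frames["turn_signal"].isin(TURN_SIGNAL_STATES)
    if bool(bad_signal.any()):
        raise ReplayValidationError("invalid turn_signal state")


@dataclass(frozen=True)
class CohortRecord:
    """Workflow-completion flags and road-exam score for one applicant."""

    drive_id: str
    ore_score: int
    completed_practice: bool = True
    completed_comprehension: bool = True
    completed_assessment: bool = True
    replay_uploaded: bool = True

    def __post_init__(self) -> None:
        if self.ore_score < 0:
            raise ValueError(f"ore_score {self.ore_score} negative")


# ---------------------------------------------------------------------------
# Replay I/O (JSONL dialect)

def read_replay(path: str | Path) -> DriveRecording:
    """Read a replay JSONL file into a :class:`DriveRecording`.

    The first line is a header object ``{"drive_id", "environment_id",
    "nominal_rate"}``; each subsequent line is one frame object keyed by
    :data:`FRAME_COLUMNS`.
    """
    path = Path(path)
    rows: list[dict] = []
    header: dict | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ReplayParseError(
                    f"{path.name}: malformed JSON on line {lineno}: {exc}") from exc
            if header is None:
                if "drive_id" not in obj:
                    raise ReplayParseError(
                        f"{path.name}: line 1 must be a header with drive_id")
                header = obj
                continue
            missing = [k for k in FRAME_COLUMNS if k not in obj]
            if missing:
                raise ReplayParseError(
                    f"{path.name}: line {lineno} missing keys {missing}")
            rows.append(obj)
    if header is None or not rows:
        raise ReplayParseError(f"{path.name}: no frames")
    frames = pd.DataFrame(rows, columns=list(FRAME_COLUMNS))
    for c in _FLOAT_COLS:
        frames[c] = frames[c].astype(float)
    for c in _BOOL_COLS:
        frames[c] = frames[c].astype(bool)
    frames["turn_signal"] = frames["turn_signal"].astype(str)
    return DriveRecording(
        drive_id=str(header["drive_id"]),
        environment_id=int(header.get("environment_id", 0)),
        frames=frames,
        nominal_rate=float(header.get("nominal_rate", 10.0)),
    )


def write_replay(rec: DriveRecording, path: str | Path) -> None:
    """Write a recording in the JSONL replay dialect (inverse of read)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(json.dumps({
            "drive_id": rec.drive_id,
            "environment_id": rec.environment_id,
            "nominal_rate": rec.nominal_rate,
        }) + "\n")
        cols = list(FRAME_COLUMNS)
        for row in rec.frames[cols].itertuples(index=False):
            obj = OrderedDict(zip(cols, row))
            for c in _BOOL_COLS:
                obj[c] = bool(obj[c])
            fh.write(json.dumps(obj) + "\n")


# ---------------------------------------------------------------------------
# Preprocessing

def downsample(rec: DriveRecording, keep_every: int = 6) -> DriveRecording:
    """Keep every ``keep_every``-th frame starting at index 0.

    Original timestamps are preserved — frames are subsampled, never
    averaged or interpolated, so elapsed time between retained frames
    remains exact.
    """
    if keep_every < 1:
        raise ValueError(f"keep_every must be >= 1, got {keep_every}")
    if len(rec) == 0:
        raise EmptyDriveError("cannot downsample an empty recording")
    out = rec.frames.iloc[::keep_every]
    return rec.replace_frames(out)


def truncate_at_motion(rec: DriveRecording, v_min: float = 0.5) -> DriveRecording:
    """Drop leading frames until the vehicle first exceeds ``v_min`` m/s.

    Aligns replays on a common starting condition (vehicle in motion).
    Raises :class:`EmptyDriveError` when no frame exceeds the threshold, in
    which case the caller excludes the sample.
    """
    speed = rec.channel("speed")
    moving = np.flatnonzero(speed > v_min)
    if moving.size == 0:
        raise EmptyDriveError(
            f"{rec.drive_id}: no frame with speed > {v_min} m/s")
    return rec.replace_frames(rec.frames.iloc[int(moving[0]):])


#: Exclusion reasons, checked in workflow order; first failing flag wins.
EXCLUSION_REASONS = (
    ("practice_incomplete", "completed_practice"),
    ("comprehension_incomplete", "completed_comprehension"),
    ("assessment_incomplete", "completed_assessment"),
    ("replay_missing", "replay_uploaded"),
)


def apply_sample_filters(
    cohort: Sequence[CohortRecord],
) -> tuple[list[CohortRecord], dict[str, int]]:
    """Split a cohort into the analyzable sample and an exclusion tally.

    A record is retained only when the applicant completed the practice
    drive, the comprehension test and the assessment drive, and the replay
    file was uploaded.  Each excluded record is tallied under exactly one
    reason — the first failing check in workflow order.
    """
    tally = {reason: 0 for reason, _ in EXCLUSION_REASONS}
    analyzable: list[CohortRecord] = []
    for rec in cohort:
        for reason, attr in EXCLUSION_REASONS:
            if not getattr(rec, attr):
                tally[reason] += 1
                break
        else:
            analyzable.append(rec)
    return analyzable, tally


# ---------------------------------------------------------------------------
# Cohort table I/O

_COHORT_COLS = ("drive_id", "ore_score", "completed_practice",
                "completed_comprehension", "completed_assessment",
                "replay_uploaded")


def write_cohort_csv(cohort: Iterable[CohortRecord], path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in _COHORT_COLS} for r in cohort],
                      columns=list(_COHORT_COLS))
    df.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[CohortRecord]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        out.append(CohortRecord(
            drive_id=str(row.drive_id),
            ore_score=int(row.ore_score),
            completed_practice=bool(row.completed_practice),
            completed_comprehension=bool(row.completed_comprehension),
            completed_assessment=bool(row.completed_assessment),
            replay_uploaded=bool(row.replay_uploaded),
        ))
    return out
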