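"""Stimulus–rest delivery paradigm and epoch extraction.

The olfactometer delivers two odorants — phenethyl alcohol (PEA, rose) and
amyl acetate (banana, trigeminal) — in a programmed block design.  One *run*
is a fixed 70 s sequence of stimulation and rest blocks; a session repeats
the run back-to-back.  This module models that schedule as plain data, writes
and reads it as a TSV event table, and cuts a continuous sensor recording
into fixed-length, condition-labelled epochs that never cross a block
boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np


class ConditionLabel(str, Enum):
    """Experimental condition of a schedule segment or epoch."""

    PEA = "PEA"
    AMYL_ACETATE = "AMYL_ACETATE"
    REST = "REST"
    EMPTY_ROOM = "EMPTY_ROOM"


#: Conditions that may appear inside a run schedule (EMPTY_ROOM may not).
RUN_CONDITIONS = (ConditionLabel.PEA, ConditionLabel.AMYL_ACETATE, ConditionLabel.REST)


@dataclass(frozen=True)
class ScheduleSegment:
    """One contiguous block of a single condition.

    Parameters
    ----------
    condition : ConditionLabel
        Condition delivered during the block.
    onset : float
        Seconds from recording start.
    duration : float
        Block length in seconds, strictly positive.
    run_index : int
        Zero-based index of the run this block belongs to.
    """

    condition: ConditionLabel
    onset: float
    duration: float
    run_index: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"segment duration must be > 0, got {self.duration}")
        if self.run_index < 0:
            raise ValueError(f"run_index must be >= 0, got {self.run_index}")
        if self.condition is ConditionLabel.EMPTY_ROOM:
            raise ValueError("EMPTY_ROOM may not appear inside a run schedule")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered, non-overlapping condition segments across runs."""

    segments: tuple[ScheduleSegment, ...]
    n_runs: int

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        for a, b in zip(segs, segs[1:]):
            if b.onset < a.end - 1e-9:
                raise ValueError(
                    f"segments overlap or are unordered: {a} followed by {b}"
                )

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def span(self) -> float:
        """Total time covered, from first onset to last segment end (s)."""
        if not self.segments:
            return 0.0
        return self.segments[-1].end - self.segments[0].onset

    @property
    def end(self) -> float:
        return self.segments[-1].end if self.segments else 0.0

    def for_condition(self, condition: ConditionLabel) -> tuple[ScheduleSegment, ...]:
        return tuple(s for s in self.segments if s.condition is condition)

    def total_duration(self, condition: ConditionLabel) -> float:
        return sum(s.duration for s in self.for_condition(condition))


def build_default_run_template() -> list[tuple[ConditionLabel, float]]:
    """Return the printed 70 s run template as (condition, duration) pairs.

    The sequence is: 5 s PEA, 5 s rest, 5 s amyl acetate, 5 s rest, 5 s PEA,
    5 s rest, 10 s amyl acetate, 10 s rest, 10 s PEA, 10 s rest — ten blocks,
    70 s total, of which 20 s PEA, 15 s amyl acetate and 35 s rest.
    """
    P, A, R = ConditionLabel.PEA, ConditionLabel.AMYL_ACETATE, ConditionLabel.REST
    return [
        (P, 5.0), (R, 5.0),
        (A, 5.0), (R, 5.0),
        (P, 5.0), (R, 5.0),
        (A, 10.0), (R, 10.0),
        (P, 10.0), (R, 10.0),
    ]


def build_schedule(
    template: Sequence[tuple[ConditionLabel, float]] | None = None,
    n_runs: int = 4,
    start: float = 0.0,
) -> StimulusSchedule:
    """Concatenate ``n_runs`` copies of a run template into a schedule.

    Runs are contiguous: run *k* starts where run *k − 1* ended.  The default
    template is :func:`build_default_run_template` and the default run count
    is four, matching the delivery protocol.
    """
    if n_runs < 0:
        raise ValueError(f"n_runs must be >= 0, got {n_runs}")
    if template is None:
        template = build_default_run_template()
    for cond, dur in template:
        if dur <= 0:
            raise ValueError(f"template durations must be > 0, got {dur} for {cond}")
    segments: list[ScheduleSegment] = []
    t = float(start)
    for run in range(n_runs):
        for cond, dur in template:
            segments.append(ScheduleSegment(cond, t, float(dur), run))
            t += float(dur)
    return StimulusSchedule(tuple(segments), n_runs)


# ---------------------------------------------------------------------------
# Event-table I/O (TSV: onset, duration, condition, run)

_EVENT_HEADER = ["onset", "duration", "condition", "run"]


def write_events(schedule: StimulusSchedule, path: str | Path) -> None:
    """Write a schedule as a UTF-8 TSV event table (header required)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_EVENT_HEADER) + "\n")
        for seg in schedule.segments:
            fh.write(
                f"{seg.onset:.3f}\t{seg.duration:.3f}\t{seg.condition.value}\t{seg.run_index}\n"
            )


def read_events(path: str | Path) -> StimulusSchedule:
    """Read a TSV event table back into a :class:`StimulusSchedule`.

    Raises
    ------
    ValueError
        Naming the offending line number for malformed rows, and on
        overlapping/unordered segments (invariant enforcement).
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file (header row required)")
    header = lines[0].rstrip("\n").split("\t")
    if [h.strip() for h in header] != _EVENT_HEADER:
        raise ValueError(f"{path}: line 1: expected header {_EVENT_HEADER}, got {header}")
    segments: list[ScheduleSegment] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}: line {lineno}: expected 4 columns, got {len(parts)}")
        try:
            onset = float(parts[0])
            duration = float(parts[1])
            condition = ConditionLabel(parts[2].strip())
            run = int(parts[3])
            segments.append(ScheduleSegment(condition, onset, duration, run))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    n_runs = 1 + max((s.run_index for s in segments), default=-1)
    return StimulusSchedule(tuple(segments), n_runs)


# ---------------------------------------------------------------------------
# Epoch extraction


@dataclass(frozen=True)
class EpochProvenance:
    """Where an epoch came from: run, segment index in schedule, offset (s)."""

    run_index: int
    segment_index: int
    offset: float


@dataclass
class EpochSet:
    """Fixed-length epochs of one condition, with provenance.

    ``epochs`` is an ``(n_epochs, n_channels, n_samples)`` array; every epoch
    has identical shape and lies entirely inside one schedule segment.
    """

    condition: ConditionLabel
    epoch_length: float
    sampling_rate: float
    epochs: np.ndarray
    provenance: list[EpochProvenance] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        n_samp = int(round(self.epoch_length * self.sampling_rate))
        if self.epochs.shape[0] and self.epochs.shape[2] != n_samp:
            raise ValueError(
                f"epoch sample count {self.epochs.shape[2]} != "
                f"round(epoch_length*rate) = {n_samp}"
            )
        if len(self.provenance) != self.epochs.shape[0]:
            raise ValueError("provenance length must match epoch count")

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


def extract_epochs(
    recording,
    schedule: StimulusSchedule,
    condition: ConditionLabel,
    epoch_length: float = 1.0,
) -> EpochSet:
    """Cut a recording into per-condition epochs aligned to block onsets.

    Each segment of the requested condition contributes
    ``floor(duration / epoch_length)`` non-overlapping epochs starting at the
    segment onset; tail samples shorter than ``epoch_length`` are discarded.
    Epochs are returned in time order.

    Parameters
    ----------
    recording : SensorRecording
        Continuous multichannel recording spanning the schedule.
    schedule : StimulusSchedule
        Block design realized in the recording.
    condition : ConditionLabel
        Which condition's blocks to segment.
    epoch_length : float
        Epoch duration in seconds (default 1 s, the analysis standard).
    """
    if epoch_length <= 0:
        raise ValueError(f"epoch_length must be > 0, got {epoch_length}")
    rate = recording.sampling_rate
    n_samp = int(round(epoch_length * rate))
    data = recording.data
    total = data.shape[1]
    chunks: list[np.ndarray] = []
    prov: list[EpochProvenance] = []
    for seg_idx, seg in enumerate(schedule.segments):
        if seg.condition is not condition:
            continue
        n_ep = math.floor(seg.duration / epoch_length + 1e-9)
        for k in range(n_ep):
            t0 = seg.onset - recording.start + k * epoch_length
            i0 = int(round(t0 * rate))
            i1 = i0 + n_samp
            if i0 < 0 or i1 > total:
                raise ValueError(
                    f"schedule segment {seg_idx} ({seg.condition.value} at "
                    f"{seg.onset:.3f}s) extends past the recording "
                    f"({total / rate:.3f}s)"
                )
            chunks.append(data[:, i0:i1])
            prov.append(EpochProvenance(seg.run_index, seg_idx, k * epoch_length))
    if chunks:
        arr = np.stack(chunks, axis=0)
    else:
        arr = np.empty((0, data.shape[0], n_samp))
    return EpochSet(condition, epoch_length, rate, arr, prov)
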