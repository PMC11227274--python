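"""Data model and CSV I/O for footfall event tables.

A *footfall event* is one ground-contact interval of one foot: the time the
foot hits the ground (foot-on) and the time it leaves it (foot-off), in
seconds within the source video.  A *trial* is a cyclic sequence of one or
more steady strides from a single individual; a *dataset* is a collection of
trials.  All downstream stride parameters (limb phases, duty factors, stride
frequencies) are computed from these intervals alone, so the pipeline is
invariant to shifting every time in a trial by a constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "LimbId",
    "FootfallEvent",
    "TrialRecord",
    "Dataset",
    "ValidationIssue",
    "FootfallFormatError",
    "FootfallValidationError",
    "read_events_csv",
    "write_events_csv",
    "validate_trial",
]

#: canonical column order of the events CSV
EVENT_COLUMNS = ["trial_id", "individual_id", "limb", "on_time_s", "off_time_s"]
OPTIONAL_COLUMNS = ["fps", "source"]


class FootfallFormatError(ValueError):
    """Raised when an events file is structurally malformed (missing columns)."""


class FootfallValidationError(ValueError):
    """Raised when event data violate an invariant (bad times, unknown limb)."""


class LimbId(str, Enum):
    """The four limbs of a quadruped, in hind-before-fore, left-before-right order."""

    LH = "LH"  # left hind (the phase reference limb)
    LF = "LF"  # left fore
    RH = "RH"  # right hind
    RF = "RF"  # right fore

    @classmethod
    def parse(cls, code: str) -> "LimbId":
        try:
            return cls(str(code).strip().upper())
        except ValueError:
            raise FootfallValidationError(
                f"unknown limb code {code!r}; expected one of LH, LF, RH, RF"
            ) from None


@dataclass(frozen=True)
class FootfallEvent:
    """One ground-contact interval of one foot."""

    limb: LimbId
    on_time: float  # s, foot-on
    off_time: float  # s, foot-off

    def __post_init__(self) -> None:
        if not (math.isfinite(self.on_time) and math.isfinite(self.off_time)):
            raise FootfallValidationError(f"non-finite event times for {self.limb}")
        if self.on_time < 0:
            raise FootfallValidationError(
                f"negative on_time {self.on_time} for {self.limb}"
            )
        if self.off_time <= self.on_time:
            raise FootfallValidationError(
                f"off_time {self.off_time} must exceed on_time {self.on_time} "
                f"for {self.limb}"
            )

    @property
    def duration(self) -> float:
        """Stance (ground contact) duration in seconds."""
        return self.off_time - self.on_time


@dataclass
class TrialRecord:
    """A cyclic sequence of footfall events from one individual.

    Events are stored sorted per limb by foot-on time.  ``frame_rate`` is the
    source video's frame rate in Hz when known (timings are then quantized to
    multiples of 1/frame_rate); ``source`` records provenance, e.g.
    ``"internet"`` or ``"zoo"``.
    """

    trial_id: str
    individual_id: str
    events: list[FootfallEvent] = field(default_factory=list)
    source: str = ""
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.limb.value, e.on_time))

    def events_for(self, limb: LimbId) -> list[FootfallEvent]:
        return [e for e in self.events if e.limb == limb]

    def shifted(self, dt: float) -> "TrialRecord":
        """A copy with every event time translated by ``dt`` seconds."""
        return replace(
            self,
            events=[
                FootfallEvent(e.limb, e.on_time + dt, e.off_time + dt)
                for e in self.events
            ],
        )


@dataclass
class Dataset:
    """A collection of trials with unique trial ids."""

    trials: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FootfallValidationError(f"duplicate trial_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def get(self, trial_id: str) -> TrialRecord:
        for t in self.trials:
            if t.trial_id == trial_id:
                return t
        raise KeyError(trial_id)


@dataclass(frozen=True)
class ValidationIssue:
    """A structured problem found in a trial; issues are data, not exceptions."""

    kind: str  # "overlap" | "unsorted" | "missing-limb" | "duplicate-on"
    limb: LimbId | None
    message: str


def validate_trial(trial: TrialRecord) -> list[ValidationIssue]:
    """Check a trial's invariants without mutating it.

    Returns an empty list for an analyzable trial: per limb the contact
    intervals must be sorted, non-overlapping and free of duplicate foot-on
    times, and every limb must have at least one event.
    """
    issues: list[ValidationIssue] = []
    for limb in LimbId:
        evs = trial.events_for(limb)
        if not evs:
            issues.append(
                ValidationIssue("missing-limb", limb, f"no events for limb {limb.value}")
            )
            continue
        for prev, cur in zip(evs, evs[1:]):
            if cur.on_time < prev.on_time:
                issues.append(
                    ValidationIssue(
                        "unsorted", limb, f"{limb.value} events not sorted by on_time"
                    )
                )
            if cur.on_time == prev.on_time:
                issues.append(
                    ValidationIssue(
                        "duplicate-on",
                        limb,
                        f"{limb.value} has two contacts starting at {cur.on_time} s",
                    )
                )
            elif cur.on_time < prev.off_time:
                issues.append(
                    ValidationIssue(
                        "overlap",
                        limb,
                        f"{limb.value} contacts [{prev.on_time}, {prev.off_time}] and "
                        f"[{cur.on_time}, {cur.off_time}] overlap",
                    )
                )
    return issues


def read_events_csv(path: str | Path) -> Dataset:
    """Read a footfall events CSV into a :class:`Dataset`.

    Required columns: trial_id, individual_id, limb, on_time_s, off_time_s.
    Optional: fps (video frame rate, Hz), source.  Limb codes are accepted
    case-insensitively.  Rows are grouped by trial (order of first
    appearance preserved) and sorted per limb by foot-on time.
    """
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FootfallFormatError(f"events file {path} lacks columns: {missing}")

    trials: dict[str, TrialRecord] = {}
    for idx, row in df.iterrows():
        try:
            event = FootfallEvent(
                limb=LimbId.parse(row["limb"]),
                on_time=float(row["on_time_s"]),
                off_time=float(row["off_time_s"]),
            )
        except FootfallValidationError as err:
            raise FootfallValidationError(f"row {idx}: {err}") from None
        tid = str(row["trial_id"])
        if tid not in trials:
            fps = row.get("fps") if "fps" in df.columns else None
            trials[tid] = TrialRecord(
                trial_id=tid,
                individual_id=str(row["individual_id"]),
                source=str(row["source"]) if "source" in df.columns else "",
                frame_rate=float(fps) if fps is not None and pd.notna(fps) else None,
            )
        trials[tid].events.append(event)

    records = []
    for trial in trials.values():
        trial.__post_init__()  # re-sort after appending
        for issue in validate_trial(trial):
            if issue.kind in ("overlap", "duplicate-on"):
                raise FootfallValidationError(
                    f"trial {trial.trial_id}: {issue.message}"
                )
        records.append(trial)
    return Dataset(trials=records)


def write_events_csv(data: Dataset, path: str | Path) -> None:
    """Write a dataset to the canonical events CSV.

    Row order is (trial, limb, on_time); times carry 6 decimal places so a
    write→read round trip preserves the dataset to well under 1e-4 s.
    """
    limb_order = {l: i for i, l in enumerate(LimbId)}
    rows = []
    for trial in data:
        for e in sorted(trial.events, key=lambda e: (limb_order[e.limb], e.on_time)):
            rows.append(
                {
                    "trial_id": trial.trial_id,
                    "individual_id": trial.individual_id,
                    "limb": e.limb.value,
                    "on_time_s": f"{e.on_time:.6f}",
                    "off_time_s": f"{e.off_time:.6f}",
                    "fps": "" if trial.frame_rate is None else f"{trial.frame_rate:g}",
                    "source": trial.source,
                }
            )
    pd.DataFrame(rows, columns=EVENT_COLUMNS + OPTIONAL_COLUMNS).to_csv(
        path, index=False
    )
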