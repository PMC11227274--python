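"""Stride segmentation and stride-parameter computation.

A stride runs from one left-hind (LH) foot-on to the next.  Each other limb
is attributed its first foot-on at or after the stride start; its *limb
phase* is that foot-on expressed as a fraction of the stride, with LH = 0 by
convention.  Duty factor (DF) is stance duration over stride duration,
stride frequency (SF) is 1/stride duration.  Trial-level summaries average
phases circularly (phases live on the unit circle: 0.96 and 0.04 average to
0.0, not 0.5) and scalar parameters arithmetically.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from statistics import fmean

import numpy as np
from scipy.stats import circmean, circstd

from .events import FootfallEvent, LimbId, TrialRecord

__all__ = [
    "Stride",
    "StrideParams",
    "TrialSummary",
    "ExcludedCycle",
    "segment_strides",
    "stride_params",
    "trial_means",
    "circular_mean",
    "circular_std",
]

log = logging.getLogger(__name__)

NONREFERENCE_LIMBS = (LimbId.LF, LimbId.RH, LimbId.RF)


def circular_mean(phases) -> float:
    """Mean of stride-fraction phases on the unit circle, mapped to [0, 1)."""
    return float(circmean(np.asarray(phases, dtype=float), high=1.0, low=0.0)) % 1.0


def circular_std(phases) -> float:
    """Circular standard deviation of stride-fraction phases."""
    return float(circstd(np.asarray(phases, dtype=float), high=1.0, low=0.0))


@dataclass(frozen=True)
class Stride:
    """One reference-limb cycle with each limb's attributed contact interval."""

    t0: float  # s, LH foot-on starting the stride
    duration: float  # s, to the next LH foot-on
    contacts: dict[LimbId, FootfallEvent]

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"stride duration must be positive, got {self.duration}")


@dataclass(frozen=True)
class ExcludedCycle:
    """A reference-limb cycle dropped because some limb had no foot-on in it."""

    t0: float
    duration: float
    missing: tuple[LimbId, ...]


@dataclass(frozen=True)
class StrideParams:
    """Per-stride kinematic parameters.

    ``phases`` maps each limb to its foot-on phase in [0, 1) (LH = 0.0);
    ``duty_factors`` to stance/stride-duration; ``stance``/``swing`` to
    durations in seconds.  ``stride_frequency`` is in Hz.
    """

    duration: float
    phases: dict[LimbId, float]
    duty_factors: dict[LimbId, float]
    stance: dict[LimbId, float]
    swing: dict[LimbId, float]

    @property
    def stride_frequency(self) -> float:
        return 1.0 / self.duration

    @property
    def df_mean(self) -> float:
        return fmean(self.duty_factors.values())

    @property
    def df_fore(self) -> float:
        return 0.5 * (self.duty_factors[LimbId.LF] + self.duty_factors[LimbId.RF])

    @property
    def df_hind(self) -> float:
        return 0.5 * (self.duty_factors[LimbId.LH] + self.duty_factors[LimbId.RH])

    @property
    def phase_lf(self) -> float:
        return self.phases[LimbId.LF]

    @property
    def phase_rh(self) -> float:
        return self.phases[LimbId.RH]

    @property
    def phase_rf(self) -> float:
        return self.phases[LimbId.RF]


@dataclass(frozen=True)
class TrialSummary:
    """Trial means of stride parameters (phases averaged circularly)."""

    n_strides: int
    phases: dict[LimbId, float]
    phase_sd: dict[LimbId, float]
    duty_factors: dict[LimbId, float]
    df_mean: float
    df_fore: float
    df_hind: float
    stride_frequency: float
    stance: float  # s, mean over limbs and strides
    swing: float  # s

    @property
    def phase_lf(self) -> float:
        return self.phases[LimbId.LF]

    @property
    def phase_rh(self) -> float:
        return self.phases[LimbId.RH]

    @property
    def phase_rf(self) -> float:
        return self.phases[LimbId.RF]


def segment_strides(
    trial: TrialRecord, with_report: bool = False
) -> list[Stride] | tuple[list[Stride], list[ExcludedCycle]]:
    """Cut a trial into strides at consecutive LH foot-on events.

    Each non-reference limb is attributed its first foot-on at or after the
    stride start and before the next LH foot-on.  Cycles in which any limb
    lacks a foot-on are excluded (non-steady or partly obscured locomotion),
    and reported when ``with_report`` is true.  Fewer than two LH contacts
    yields no strides.
    """
    lh_events = trial.events_for(LimbId.LH)
    other = {
        limb: trial.events_for(limb) for limb in NONREFERENCE_LIMBS
    }
    other_ons = {limb: [e.on_time for e in evs] for limb, evs in other.items()}

    strides: list[Stride] = []
    excluded: list[ExcludedCycle] = []
    for start, nxt in zip(lh_events, lh_events[1:]):
        t0, t1 = start.on_time, nxt.on_time
        contacts: dict[LimbId, FootfallEvent] = {LimbId.LH: start}
        missing: list[LimbId] = []
        for limb in NONREFERENCE_LIMBS:
            i = bisect.bisect_left(other_ons[limb], t0)
            if i < len(other_ons[limb]) and other_ons[limb][i] < t1:
                contacts[limb] = other[limb][i]
            else:
                missing.append(limb)
        if missing:
            excluded.append(ExcludedCycle(t0, t1 - t0, tuple(missing)))
            log.info(
                "trial %s: cycle at t=%.3f s excluded (no foot-on for %s)",
                trial.trial_id,
                t0,
                ",".join(l.value for l in missing),
            )
        else:
            strides.append(Stride(t0=t0, duration=t1 - t0, contacts=contacts))
    if with_report:
        return strides, excluded
    return strides


def stride_params(stride: Stride) -> StrideParams:
    """Compute phases, duty factors, SF and stance/swing for one stride.

    A limb's stance is its attributed contact's full on→off span even when
    the foot-off falls after the stride's end: under steady locomotion this
    equals the within-stride stance contributed by the previous cycle.
    """
    dur = stride.duration
    phases: dict[LimbId, float] = {}
    dfs: dict[LimbId, float] = {}
    stance: dict[LimbId, float] = {}
    swing: dict[LimbId, float] = {}
    for limb, ev in stride.contacts.items():
        phases[limb] = ((ev.on_time - stride.t0) % dur) / dur
        stance[limb] = ev.duration
        dfs[limb] = ev.duration / dur
        swing[limb] = dur - ev.duration
    return StrideParams(
        duration=dur, phases=phases, duty_factors=dfs, stance=stance, swing=swing
    )


def trial_means(strides: list[StrideParams]) -> TrialSummary:
    """Average stride parameters over a trial.

    Phases are averaged on the circle; scalar parameters arithmetically.
    When the circular and arithmetic phase means differ by more than 0.005
    (wrap-around in play, e.g. RF phases straddling 1.0/0.0) the difference
    is logged so the convention choice is visible.
    """
    if not strides:
        raise ValueError("trial_means requires at least one stride")
    phases: dict[LimbId, float] = {}
    phase_sd: dict[LimbId, float] = {}
    for limb in LimbId:
        vals = [s.phases[limb] for s in strides]
        cm = circular_mean(vals)
        phases[limb] = cm
        phase_sd[limb] = circular_std(vals) if len(vals) > 1 else 0.0
        am = fmean(vals)
        if min(abs(cm - am), 1 - abs(cm - am)) > 0.005:
            log.info(
                "limb %s: circular phase mean %.3f differs from arithmetic %.3f",
                limb.value,
                cm,
                am,
            )
    dfs = {limb: fmean(s.duty_factors[limb] for s in strides) for limb in LimbId}
    return TrialSummary(
        n_strides=len(strides),
        phases=phases,
        phase_sd=phase_sd,
        duty_factors=dfs,
        df_mean=fmean(s.df_mean for s in strides),
        df_fore=0.5 * (dfs[LimbId.LF] + dfs[LimbId.RF]),
        df_hind=0.5 * (dfs[LimbId.LH] + dfs[LimbId.RH]),
        stride_frequency=fmean(s.stride_frequency for s in strides),
        stance=fmean(fmean(s.stance.values()) for s in strides),
        swing=fmean(fmean(s.swing.values()) for s in strides),
    )
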