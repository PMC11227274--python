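"""Footfall-pattern classification, support timelines and aerial phases.

Symmetrical quadrupedal gaits are summarised by the *forelimb lag*: the
circular mean of the two hind→ipsilateral-fore foot-on offsets (LH→LF and
RH→RF), as a stride fraction.  Lag 0.5 is a trot (diagonal pairs
synchronous), 0 a pace (ipsilateral pairs), 0.25 a lateral-sequence
singlefoot and 0.75 a diagonal-sequence singlefoot; couplet gaits sit
between.  Eight-way classification bins the lag in 0.125-wide circular
windows around k/8; four-way uses 0.25-wide windows around quarters.
Walking vs running follows the kinematic definition: duty factor >= 0.5 is
walking.

The *support timeline* places each limb's contact interval
[phase_i, phase_i + DF_i) on the unit stride circle and partitions the
stride into intervals of constant support set; zero-support intervals are
aerial (suspended) phases.  A simplified aerial criterion, needing only
mean values, predicts an aerial phase when DF is less than the greatest
phase gap between two consecutive ipsilateral footfalls.
"""

from __future__ import annotations

from dataclasses import dataclass

from .events import LimbId
from .kinematics import StrideParams, TrialSummary, circular_mean

__all__ = [
    "GaitClass",
    "SupportTimeline",
    "AerialReport",
    "CLASS8_LABELS",
    "CLASS4_LABELS",
    "forelimb_lag",
    "classify",
    "support_timeline",
    "detect_aerial",
    "bipedal_support_profile",
]

#: eight-way footfall-pattern labels, indexed by the lag bin k (center k/8)
CLASS8_LABELS = (
    "pace",
    "LS-lateral-couplets",
    "LS-singlefoot",
    "LS-diagonal-couplets",
    "trot",
    "DS-diagonal-couplets",
    "DS-singlefoot",
    "DS-lateral-couplets",
)

#: four-way labels, indexed by the lag bin k (center k/4)
CLASS4_LABELS = ("pace", "lateral-sequence", "trot", "diagonal-sequence")

ParamsLike = StrideParams | TrialSummary


@dataclass(frozen=True)
class GaitClass:
    """Footfall-pattern classification of one stride or trial."""

    class8: str
    class4: str
    locomotion: str  # "walking" | "running"
    symmetry: str  # "symmetrical" | "asymmetrical"
    forelimb_lag: float


@dataclass(frozen=True)
class SupportTimeline:
    """Partition of one stride cycle into intervals of constant support.

    ``intervals`` is a list of (start, end, limbs-in-contact) with phases in
    stride fractions; interval lengths sum to 1, wrap-around resolved.
    """

    intervals: tuple[tuple[float, float, frozenset[LimbId]], ...]

    def support_at(self, phase: float) -> frozenset[LimbId]:
        phase %= 1.0
        for start, end, limbs in self.intervals:
            if start <= phase < end:
                return limbs
        return self.intervals[-1][2]


@dataclass(frozen=True)
class AerialReport:
    """Exact and simplified aerial-phase assessment of a stride."""

    has_aerial: bool
    aerial_windows: tuple[tuple[float, float], ...]
    aerial_fraction: float
    predicted_simplified: bool
    max_ipsilateral_gap: float


def forelimb_lag(params: ParamsLike) -> float:
    """Circular mean of the LH→LF and RH→RF foot-on offsets, in [0, 1)."""
    left = params.phase_lf % 1.0
    right = (params.phase_rf - params.phase_rh) % 1.0
    return circular_mean([left, right])


def _circular_bin(value: float, n_bins: int) -> int:
    """Index of the circular bin of width 1/n_bins centered at k/n_bins.

    Bins are half-open [k/n - 1/(2n), k/n + 1/(2n)); a boundary value
    belongs to the higher bin.
    """
    return int((value % 1.0 + 0.5 / n_bins) * n_bins) % n_bins


def classify(params: ParamsLike) -> GaitClass:
    """Classify a stride's (or trial-mean) footfall pattern.

    The eight- and four-way labels bin the forelimb lag circularly; walking
    vs running splits on mean duty factor at 0.5 (walking at exactly 0.5).
    A stride is flagged asymmetrical when the hind lag (RH phase) falls
    outside 0.5 +- 0.125 circularly; labels are still reported with the flag.
    """
    lag = forelimb_lag(params)
    class8 = CLASS8_LABELS[_circular_bin(lag, 8)]
    class4 = CLASS4_LABELS[_circular_bin(lag, 4)]
    locomotion = "walking" if params.df_mean >= 0.5 else "running"
    hind_lag = params.phase_rh % 1.0
    symmetric = min(abs(hind_lag - 0.5), 1 - abs(hind_lag - 0.5)) <= 0.125
    return GaitClass(
        class8=class8,
        class4=class4,
        locomotion=locomotion,
        symmetry="symmetrical" if symmetric else "asymmetrical",
        forelimb_lag=lag,
    )


def support_timeline(params: ParamsLike) -> SupportTimeline:
    """Exact support-set partition of one stride cycle.

    Limb i is in contact on the circular interval
    [phase_i, phase_i + DF_i) mod 1; a DF of 1 (or more) means continuous
    contact.  Breakpoints are all foot-on and foot-off phases.
    """
    spans: dict[LimbId, tuple[float, float]] = {}
    for limb in LimbId:
        on = params.phases[limb] % 1.0
        df = params.duty_factors[limb]
        spans[limb] = (on, df)

    breaks: set[float] = {0.0}
    for on, df in spans.values():
        if df < 1.0:
            breaks.add(on)
            breaks.add((on + df) % 1.0)
    pts = sorted(breaks)

    def in_contact(limb: LimbId, phase: float) -> bool:
        on, df = spans[limb]
        if df >= 1.0:
            return True
        return (phase - on) % 1.0 < df

    raw: list[tuple[float, float, frozenset[LimbId]]] = []
    for i, start in enumerate(pts):
        end = pts[i + 1] if i + 1 < len(pts) else 1.0
        if end <= start:
            continue
        mid = 0.5 * (start + end)
        limbs = frozenset(l for l in LimbId if in_contact(l, mid))
        raw.append((start, end, limbs))

    # merge adjacent intervals with identical support (incl. the wrap seam)
    merged: list[list] = []
    for start, end, limbs in raw:
        if merged and merged[-1][2] == limbs and merged[-1][1] == start:
            merged[-1][1] = end
        else:
            merged.append([start, end, limbs])
    return SupportTimeline(
        intervals=tuple((s, e, l) for s, e, l in merged)
    )


def max_ipsilateral_gap(params: ParamsLike) -> float:
    """Greatest phase gap between consecutive ipsilateral footfalls.

    Left pair: from LF foot-on to the next LH foot-on, (1 - phase_LF) mod 1.
    Right pair: from RH foot-on to RF foot-on, (phase_RF - phase_RH) mod 1.
    """
    left = (1.0 - params.phase_lf) % 1.0
    right = (params.phase_rf - params.phase_rh) % 1.0
    return max(left, right)


def detect_aerial(timeline: SupportTimeline, params: ParamsLike) -> AerialReport:
    """Exact aerial windows from the support timeline, plus the simplified
    mean-value prediction: an aerial phase is predicted when the mean duty
    factor is below the greatest ipsilateral footfall gap.
    """
    windows = tuple(
        (start, end) for start, end, limbs in timeline.intervals if not limbs
    )
    fraction = sum(end - start for start, end in windows)
    gap = max_ipsilateral_gap(params)
    return AerialReport(
        has_aerial=fraction > 0.0,
        aerial_windows=windows,
        aerial_fraction=fraction,
        predicted_simplified=params.df_mean < gap,
        max_ipsilateral_gap=gap,
    )


_DIAGONAL_PAIRS = (
    frozenset({LimbId.LH, LimbId.RF}),
    frozenset({LimbId.RH, LimbId.LF}),
)
_LATERAL_PAIRS = (
    frozenset({LimbId.LH, LimbId.LF}),
    frozenset({LimbId.RH, LimbId.RF}),
)
_FORE_PAIR = frozenset({LimbId.LF, LimbId.RF})
_HIND_PAIR = frozenset({LimbId.LH, LimbId.RH})


def bipedal_support_profile(timeline: SupportTimeline) -> dict[str, float]:
    """Stride fractions by support configuration.

    Keys: "0", "1", "3", "4" by support count, and two-limb supports split
    into "2-diagonal", "2-lateral" (ipsilateral pair), "2-fore", "2-hind".
    Fractions sum to 1.
    """
    profile = {
        "0": 0.0,
        "1": 0.0,
        "2-diagonal": 0.0,
        "2-lateral": 0.0,
        "2-fore": 0.0,
        "2-hind": 0.0,
        "3": 0.0,
        "4": 0.0,
    }
    for start, end, limbs in timeline.intervals:
        length = end - start
        if len(limbs) == 2:
            if limbs in _DIAGONAL_PAIRS:
                key = "2-diagonal"
            elif limbs in _LATERAL_PAIRS:
                key = "2-lateral"
            elif limbs == _FORE_PAIR:
                key = "2-fore"
            else:
                key = "2-hind"
        else:
            key = str(len(limbs))
        profile[key] += length
    return profile
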