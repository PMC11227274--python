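"""Synthetic footfall-event generation.

Generates trials of timed foot contacts with the statistical structure the
analysis pipeline assumes: an ideal gait template (trot, pace, lateral- or
diagonal-sequence singlefoot), target duty factor and stride frequency,
per-stride Gaussian phase/DF jitter, and optional quantization of all event
times to a video frame grid.  A study-level generator emulates a survey of
hippopotamus locomotion trials: 46 trials from 32 individuals totalling
~169 strides, trial-mean duty factors drawn from two clusters
(~0.36-0.58 "running" and ~0.75-0.94 "walking") with an empty range
between, limb phases dispersed around the observed hippo trot means
(LF 0.46, RH 0.51, RF 0.94), stride frequency tied linearly to duty factor
(SF = -4.14 DF + 3.89 plus residual noise), and forelimb duty factors
slightly exceeding hindlimb ones.

The reference limb (LH) is generated on the exact stride grid; phase
jitter applies to the other three limbs, so recovered phase dispersions
equal the nominal jitter SD and stride durations stay exactly 1/SF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .events import Dataset, FootfallEvent, LimbId, TrialRecord

__all__ = [
    "GAIT_TEMPLATES",
    "SimConfig",
    "StudyConfig",
    "generate_trial",
    "generate_study",
    "quantize_to_fps",
]

#: ideal limb phases per gait (LH = 0 by convention); all symmetrical:
#: hind lag 0.5, fore phases half a stride apart
GAIT_TEMPLATES: dict[str, dict[LimbId, float]] = {
    "trot": {LimbId.LH: 0.0, LimbId.LF: 0.5, LimbId.RH: 0.5, LimbId.RF: 0.0},
    "pace": {LimbId.LH: 0.0, LimbId.LF: 0.0, LimbId.RH: 0.5, LimbId.RF: 0.5},
    "lateral-sequence": {
        LimbId.LH: 0.0, LimbId.LF: 0.25, LimbId.RH: 0.5, LimbId.RF: 0.75,
    },
    "diagonal-sequence": {
        LimbId.LH: 0.0, LimbId.LF: 0.75, LimbId.RH: 0.5, LimbId.RF: 0.25,
    },
}

_FORE = (LimbId.LF, LimbId.RF)

# observed hippo-trot deviations from the ideal trot template, and the
# across-trial SDs of trial-mean phases they disperse with
_HIPPO_PHASE_OFFSET = {LimbId.LF: -0.04, LimbId.RH: 0.01, LimbId.RF: -0.06}
_HIPPO_PHASE_SD = {LimbId.LF: 0.050, LimbId.RH: 0.051, LimbId.RF: 0.040}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic trial.

    ``phase_offsets`` shifts template phases per limb (trial-level gait
    idiosyncrasy); ``phase_jitter_sd``/``df_jitter_sd`` are per-stride
    Gaussian SDs in stride fractions; ``fore_hind_df_offset`` adds half its
    value to forelimb DFs and subtracts half from hindlimb DFs;
    ``frame_rate`` (Hz) quantizes all event times to the video frame grid.
    """

    gait: str = "trot"
    df_mean: float = 0.5
    sf: float = 1.0  # Hz
    phase_jitter_sd: float = 0.0
    df_jitter_sd: float = 0.0
    n_strides: int = 4
    frame_rate: float | None = None
    seed: int = 0
    phase_offsets: dict[LimbId, float] = field(default_factory=dict)
    fore_hind_df_offset: float = 0.0
    trial_id: str = "sim"
    individual_id: str = "sim"
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if self.gait not in GAIT_TEMPLATES:
            raise ValueError(
                f"unknown gait {self.gait!r}; choose from {sorted(GAIT_TEMPLATES)}"
            )
        if not 0.0 < self.df_mean <= 1.0:
            raise ValueError("df_mean must be in (0, 1]")
        if self.sf <= 0:
            raise ValueError("sf must be positive")
        if self.phase_jitter_sd < 0 or self.df_jitter_sd < 0:
            raise ValueError("jitter SDs must be non-negative")
        if self.n_strides < 1:
            raise ValueError("n_strides must be at least 1")


def generate_trial(config: SimConfig) -> TrialRecord:
    """Generate one trial of footfall events; deterministic given the seed.

    Stride duration is 1/SF.  For stride k, each limb's foot-on falls at
    (k + phase + jitter) x duration and its foot-off at foot-on +
    (DF + jitter) x duration; one extra reference-limb cycle is appended so
    segmentation recovers exactly ``n_strides`` complete strides.  Jitter is
    truncated and foot-offs clipped below the next same-limb foot-on so
    per-limb contacts never overlap.  If the frame period exceeds the swing
    duration implied by DF and SF, quantization cannot resolve the swing
    and a warning is issued.
    """
    rng = np.random.default_rng(config.seed)
    dur = 1.0 / config.sf
    template = GAIT_TEMPLATES[config.gait]

    if config.frame_rate is not None:
        swing = (1.0 - config.df_mean) / config.sf
        if 1.0 / config.frame_rate > swing:
            warnings.warn(
                f"frame period {1.0 / config.frame_rate:.3f} s exceeds swing "
                f"duration {swing:.3f} s; quantized events may merge",
                stacklevel=2,
            )

    events: list[FootfallEvent] = []
    for limb in LimbId:
        base = (template[limb] + config.phase_offsets.get(limb, 0.0)) % 1.0
        if limb in _FORE:
            df_base = config.df_mean + 0.5 * config.fore_hind_df_offset
        else:
            df_base = config.df_mean - 0.5 * config.fore_hind_df_offset
        ons, offs = [], []
        for k in range(config.n_strides + 1):
            jit = 0.0
            if limb is not LimbId.LH and config.phase_jitter_sd > 0:
                jit = float(
                    np.clip(rng.normal(0.0, config.phase_jitter_sd), -0.33, 0.33)
                )
            df = df_base
            if config.df_jitter_sd > 0:
                df += float(rng.normal(0.0, config.df_jitter_sd))
            df = float(np.clip(df, 0.05, 0.98))
            # one-stride lead-in keeps all times non-negative under jitter
            on = (k + 1 + base + jit) * dur
            ons.append(on)
            offs.append(on + df * dur)
        order = np.argsort(ons)
        ons = [ons[i] for i in order]
        offs = [offs[i] for i in order]
        for i in range(len(ons) - 1):  # contacts must not overlap
            offs[i] = min(offs[i], ons[i + 1] - 1e-6 * dur)
        events.extend(
            FootfallEvent(limb, on, off) for on, off in zip(ons, offs)
        )

    trial = TrialRecord(
        trial_id=config.trial_id,
        individual_id=config.individual_id,
        source=config.source,
        frame_rate=config.frame_rate,
        events=events,
    )
    if config.frame_rate is not None:
        trial = quantize_to_fps(trial, config.frame_rate)
    return trial


def quantize_to_fps(trial: TrialRecord, frame_rate: float) -> TrialRecord:
    """Round every event time to the nearest video frame (1/frame_rate).

    Idempotent.  When rounding collapses a contact (foot-off frame equal to
    the foot-on frame), the foot-off is pushed one frame later so the event
    survives as the shortest resolvable contact.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    period = 1.0 / frame_rate
    events = []
    for e in trial.events:
        on = round(e.on_time * frame_rate) * period
        off = round(e.off_time * frame_rate) * period
        if off <= on:
            off = on + period
        events.append(FootfallEvent(e.limb, on, off))
    return TrialRecord(
        trial_id=trial.trial_id,
        individual_id=trial.individual_id,
        source=trial.source,
        frame_rate=frame_rate,
        events=events,
    )


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of a synthetic locomotion survey.

    Trial-mean duty factors are drawn from a two-cluster uniform mixture
    (``low_cluster`` sampled with probability ``low_weight``); stride
    frequency follows ``sf_slope x DF + sf_intercept`` plus Gaussian
    residual noise whose SD is derived from ``sf_target_r_squared`` and the
    mixture's DF variance (so the synthetic study reproduces the target R²
    in expectation), floored at ``sf_min``.  Per-trial stride counts are
    drawn from geometrically decaying weights over ``stride_count_range``
    calibrated so the expected total equals ``total_strides``.  Limb-phase
    trial offsets disperse around the observed hippo-trot means.
    """

    n_trials: int = 46
    n_individuals: int = 32
    total_strides: int = 169
    low_cluster: tuple[float, float] = (0.36, 0.58)
    high_cluster: tuple[float, float] = (0.75, 0.94)
    low_weight: float = 0.41
    stride_count_range: tuple[int, int] = (1, 8)
    sf_slope: float = -4.14
    sf_intercept: float = 3.89
    sf_target_r_squared: float = 0.763
    sf_min: float = 0.15
    phase_jitter_sd: float = 0.02
    df_jitter_sd: float = 0.02
    fore_hind_df_offset: float = 0.01
    frame_rate: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_weight <= 1.0:
            raise ValueError("low_weight must be a probability")
        for lo, hi in (self.low_cluster, self.high_cluster):
            if not 0.0 < lo < hi < 1.0:
                raise ValueError("cluster ranges must satisfy 0 < lo < hi < 1")

    def df_variance(self) -> float:
        """Variance of the trial-mean DF mixture distribution."""
        w1, w2 = self.low_weight, 1.0 - self.low_weight
        stats = []
        for lo, hi in (self.low_cluster, self.high_cluster):
            m = 0.5 * (lo + hi)
            v = (hi - lo) ** 2 / 12.0
            stats.append((m, v))
        mean = w1 * stats[0][0] + w2 * stats[1][0]
        second = w1 * (stats[0][1] + stats[0][0] ** 2) + w2 * (
            stats[1][1] + stats[1][0] ** 2
        )
        return second - mean**2

    def sf_residual_sd(self) -> float:
        """Residual SD of the SF~DF relation implied by the target R²."""
        r2 = self.sf_target_r_squared
        signal_var = self.sf_slope**2 * self.df_variance()
        return float(np.sqrt(signal_var * (1.0 - r2) / r2))

    def stride_count_weights(self) -> np.ndarray:
        """Geometric weights over the stride-count range matching the
        expected total stride count."""
        lo, hi = self.stride_count_range
        counts = np.arange(lo, hi + 1, dtype=float)
        target = self.total_strides / self.n_trials

        def mean_at(ratio: float) -> float:
            w = ratio ** (counts - lo)
            return float((counts * w).sum() / w.sum())

        lo_r, hi_r = 1e-6, 1.0
        if not mean_at(lo_r) <= target <= mean_at(hi_r):
            raise ValueError(
                f"target mean stride count {target:.2f} unreachable on "
                f"range {self.stride_count_range}"
            )
        for _ in range(80):  # bisection on the geometric ratio
            mid = 0.5 * (lo_r + hi_r)
            if mean_at(mid) < target:
                lo_r = mid
            else:
                hi_r = mid
        ratio = 0.5 * (lo_r + hi_r)
        w = ratio ** (counts - lo)
        return w / w.sum()


def generate_study(config: StudyConfig = StudyConfig()) -> Dataset:
    """Generate a full synthetic study; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.stride_count_range
    counts = np.arange(lo, hi + 1)
    weights = config.stride_count_weights()
    residual_sd = config.sf_residual_sd()

    # assign individuals: each of the first n_individuals trials introduces
    # a new animal, the rest revisit existing ones
    individual_ids = [f"hippo{i + 1:02d}" for i in range(config.n_individuals)]
    assignment = individual_ids + [
        individual_ids[int(i)]
        for i in rng.integers(
            0, config.n_individuals, size=max(config.n_trials - config.n_individuals, 0)
        )
    ]
    rng.shuffle(assignment)

    trials = []
    for i in range(config.n_trials):
        low = rng.random() < config.low_weight
        cluster = config.low_cluster if low else config.high_cluster
        df_target = float(rng.uniform(*cluster))
        sf = config.sf_slope * df_target + config.sf_intercept
        sf = max(sf + float(rng.normal(0.0, residual_sd)), config.sf_min)
        offsets = {
            limb: _HIPPO_PHASE_OFFSET[limb]
            + float(rng.normal(0.0, _HIPPO_PHASE_SD[limb]))
            for limb in (LimbId.LF, LimbId.RH, LimbId.RF)
        }
        sim = SimConfig(
            gait="trot",
            df_mean=df_target,
            sf=sf,
            phase_jitter_sd=config.phase_jitter_sd,
            df_jitter_sd=config.df_jitter_sd,
            n_strides=int(rng.choice(counts, p=weights)),
            frame_rate=config.frame_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
            phase_offsets=offsets,
            fore_hind_df_offset=config.fore_hind_df_offset,
            trial_id=f"trial{i + 1:03d}",
            individual_id=assignment[i],
            source="internet" if low else "zoo",
        )
        trials.append(generate_trial(sim))
    return Dataset(trials=trials)
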