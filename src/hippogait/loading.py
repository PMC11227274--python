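"""Peak vertical ground-reaction-force estimate from duty factor.

Idealises a limb's vertical force over stance as half of a cosine cycle.
If a limb supports a fraction ``limb_share`` of body weight averaged over a
full stride, its stance-average force is limb_share/DF body weights (the
same impulse delivered in a fraction DF of the stride), and the half-cosine
peak exceeds the stance average by a factor pi/2:

    peak = limb_share * (pi/2) / DF    [body weights]

The default ``limb_share`` of 0.30 corresponds to the forelimb pair
carrying 60% of body weight, the typical anterior weight bias of
quadrupedal mammals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["LoadingParams", "peak_vertical_grf", "half_cosine_force"]

DEFAULT_FORELIMB_SHARE = 0.30


@dataclass(frozen=True)
class LoadingParams:
    """Inputs of the half-cosine loading model.

    duty_factor: stance duration / stride duration, in (0, 1].
    limb_share: fraction of body weight the limb supports averaged over a
        full stride (e.g. 0.30 for one forelimb of a 60/40 fore/hind split).
    """

    duty_factor: float
    limb_share: float = DEFAULT_FORELIMB_SHARE

    def __post_init__(self) -> None:
        if not 0.0 < self.duty_factor <= 1.0:
            raise ValueError(f"duty_factor must be in (0, 1], got {self.duty_factor}")
        if not 0.0 <= self.limb_share <= 1.0:
            raise ValueError(f"limb_share must be in [0, 1], got {self.limb_share}")


def peak_vertical_grf(
    duty_factor: float | LoadingParams,
    limb_share: float = DEFAULT_FORELIMB_SHARE,
) -> float:
    """Peak vertical ground reaction force of one limb, in body weights.

    Accepts either a :class:`LoadingParams` or (duty_factor, limb_share).
    Strictly decreasing in duty factor and increasing in limb share.
    """
    p = (
        duty_factor
        if isinstance(duty_factor, LoadingParams)
        else LoadingParams(duty_factor=float(duty_factor), limb_share=float(limb_share))
    )
    return p.limb_share * (math.pi / 2.0) / p.duty_factor


def half_cosine_force(
    t: np.ndarray, stance_duration: float, peak: float
) -> np.ndarray:
    """Half-cosine vertical force profile over one stance, for t in [0, T].

    F(t) = peak * sin(pi t / T): zero at touchdown and lift-off, maximal at
    midstance.  Useful for impulse checks and plotting.
    """
    t = np.asarray(t, dtype=float)
    return peak * np.sin(np.pi * t / stance_duration)
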