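import pytest

from hippogait import (
    Dataset,
    FootfallEvent,
    LimbId,
    TrialRecord,
)


def make_trial(
    phases,
    duty_factor=0.5,
    n_strides=2,
    duration=1.0,
    trial_id="t1",
    t_start=0.0,
):
    """Hand-build a noiseless periodic trial from limb phases and a DF.

    ``phases`` maps LimbId -> foot-on phase in [0, 1); LH defaults to 0.
    Foot-offs extend DF x duration past each foot-on.  One extra LH cycle
    closes the final stride.
    """
    phases = {LimbId.LH: 0.0, **phases}
    events = []
    for limb, ph in phases.items():
        extra = 1 if limb == LimbId.LH else 1  # one closing cycle for all limbs
        for k in range(n_strides + extra):
            on = t_start + (k + ph) * duration
            events.append(FootfallEvent(limb, on, on + duty_factor * duration))
    return TrialRecord(trial_id=trial_id, individual_id="h1", events=events)


@pytest.fixture
def trot_trial():
    """Ideal trot: diagonal pairs synchronous, DF 0.5."""
    return make_trial(
        {LimbId.LF: 0.5, LimbId.RH: 0.5, LimbId.RF: 0.0}, duty_factor=0.5
    )


@pytest.fixture
def hippo_mean_trial():
    """Noiseless trial at the observed hippo trot mean phases."""
    return make_trial(
        {LimbId.LF: 0.46, LimbId.RH: 0.51, LimbId.RF: 0.94},
        duty_factor=0.76,
        n_strides=3,
    )
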