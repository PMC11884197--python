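import numpy as np
import pytest

from subkin import StimulusPlan, StimulusSegment, Trial

FS = 100.0


def sinusoid_trial(
    frequency=0.25,
    amplitude_p2p=20.0,
    duration=20.0,
    lead_in=0.0,
    phase=0.0,
    center=0.0,
    lag=0.0,
    gain=1.0,
    fs=FS,
    clamp_onset=True,
    **trial_kw,
):
    """A trial holding a (possibly lagged / gain-scaled) pure sinusoid.

    ``clamp_onset=False`` extends the delayed sinusoid backwards in time
    (no stationary onset), which is the clean construction for exact
    event-count checks.
    """
    seg = StimulusSegment(
        frequency=frequency,
        amplitude_p2p=amplitude_p2p,
        center=center,
        t_start=lead_in,
        t_end=lead_in + duration,
        phase=phase,
    )
    plan = StimulusPlan(segments=[seg], lead_in=lead_in)
    n = int(round(plan.duration * fs))
    t = np.arange(n) / fs
    x = np.full(n, center, dtype=float)
    m = t >= lead_in
    tau = t[m] - lag if not clamp_onset else np.maximum(t[m] - lag, lead_in)
    x[m] = center + gain * (seg.position(tau) - center)
    trial_kw.setdefault("participant_id", "p0")
    trial_kw.setdefault("group", "YC")
    trial_kw.setdefault("trial_index", 0)
    return Trial(t=t, x=x, **trial_kw), plan, seg


@pytest.fixture
def quiet_segment():
    """A 20 s 0.25 Hz segment tracked perfectly (no noise)."""
    return sinusoid_trial()
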