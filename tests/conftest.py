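import numpy as np
import pytest

from gripdecode import features as F
from gripdecode import synthetic as S

#: Compact generator settings for tests that need raw-signal sessions:
#: shorter inter-trial spacing and a lower (still valid) sampling rate keep
#: signal synthesis cheap without touching the decode window.
FAST_KW = dict(fs=256.0, trial_spacing=(5.0, 6.0), lead_in=4.0)


@pytest.fixture(scope="session")
def session_noiseless():
    """Noiseless model-2 session, 12 trials, full raw-signal synthesis."""
    cfg = S.SyntheticConfig(n_trials=12, seed=42, true_model_id=2, **FAST_KW)
    return S.generate_session(cfg)


@pytest.fixture(scope="session")
def session_noisy():
    """Model-2 session with 5% force noise, 30 trials."""
    cfg = S.SyntheticConfig(n_trials=30, seed=5, true_model_id=2, noise_sd=0.05,
                            **FAST_KW)
    return S.generate_session(cfg)


@pytest.fixture(scope="session")
def trials_noisy(session_noisy):
    """Feature-extracted, force-normalised trials from the noisy session."""
    trials = F.epoch_trials(session_noisy.recording, pair=1)
    return F.normalize_force(trials)


def trials_from_ground_truth(session):
    """Build Trial objects directly from a session's ground truth."""
    return [
        F.Trial(band_trace=env, force=force, sre=int(sre), cue_time=float(cue))
        for env, force, sre, cue in zip(
            session.true_envelopes,
            session.observed_force,
            session.recording.sre,
            session.recording.cue_times,
        )
    ]
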