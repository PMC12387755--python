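import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from epscorr import EventTrain, Label, PairedSession


@pytest.fixture
def make_train():
    def _make(times, label=Label.LABELED, duration=10.0, cell_id="c", amplitudes=None):
        return EventTrain(
            cell_id=cell_id,
            label=label,
            duration=duration,
            event_times=np.asarray(times, dtype=float),
            amplitudes=None if amplitudes is None else np.asarray(amplitudes, float),
        )

    return _make


@pytest.fixture
def make_session(make_train):
    def _make(times_a, times_b, duration=10.0, session_id="s",
              labels=(Label.LABELED, Label.LABELED)):
        return PairedSession(
            session_id=session_id,
            train_a=make_train(times_a, label=labels[0], duration=duration, cell_id="a"),
            train_b=make_train(times_b, label=labels[1], duration=duration, cell_id="b"),
        )

    return _make
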