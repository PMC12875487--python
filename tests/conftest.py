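import numpy as np
import pytest

from musetrf.midi import Melody, NoteEvent
from musetrf.stimgen import generate_corpus


def make_melody(pitches, iois, mid="m", condition="real", sixteenth=0.06):
    """Build a melody from a pitch list and the IOIs between successive notes."""
    onsets = np.concatenate([[0.0], np.cumsum(iois)])
    durations = list(iois) + [iois[-1]]
    notes = tuple(
        NoteEvent(onset=float(t), pitch=int(p), duration=float(0.8 * d), velocity=100)
        for t, p, d in zip(onsets, pitches, durations)
    )
    return Melody(id=mid, notes=notes, condition=condition, sixteenth_duration=sixteenth)


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(6, n_notes=24, temperature=0.4, seed=11)


@pytest.fixture()
def simple_melody():
    return make_melody([60, 62, 64, 65, 67, 69], [0.3, 0.3, 0.6, 0.3, 0.3], mid="simple")
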