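import numpy as np
import pytest

from gaitsync.experiment import default_library
from gaitsync.library import Library, Song


@pytest.fixture(scope="session")
def walking_library() -> Library:
    """Synthetic playlist covering the walking-tempo range (80-140 BPM)."""
    return default_library()


@pytest.fixture()
def small_library() -> Library:
    lib = Library()
    for sid, bpm in [("a100", 100.0), ("b120", 120.0), ("c140", 140.0)]:
        lib.add(Song(song_id=sid, bpm=bpm, duration_s=60.0))
    return lib


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def fixed_beat_callback(period: float, offset: float = 0.0):
    """A non-adaptive metronome: beats at offset + k*period, k >= 0."""

    def callback(ev):
        t = ev.time
        k = int(np.floor((t - offset) / period))
        ks = np.arange(max(k - 3, 0), k + 5)
        return offset + ks * period

    return callback
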