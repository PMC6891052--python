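import numpy as np
import pandas as pd
import pytest

from rhythmgain import preprocess, stimgen, synthmeeg


@pytest.fixture(scope="session")
def grid():
    return stimgen.build_frequency_grid()


@pytest.fixture(scope="session")
def chord_assignment(grid):
    return stimgen.assign_chord_frequencies(grid, seed=7)


@pytest.fixture(scope="session")
def small_block(chord_assignment):
    spec, _ = chord_assignment
    return stimgen.generate_block(
        "rhythmic", spec, stimgen.BlockParams(n_trials=6), seed=11
    )


@pytest.fixture(scope="session")
def small_jittered_block(chord_assignment):
    spec, _ = chord_assignment
    return stimgen.generate_block(
        "jittered", spec, stimgen.BlockParams(n_trials=8), seed=12
    )


@pytest.fixture(scope="session")
def sensors():
    return synthmeeg.make_sensor_array(6, 6, 8, seed=3)


@pytest.fixture(scope="session")
def small_recording(small_block, sensors):
    """One simulated, filtered, re-referenced recording shared by tests."""
    truth = synthmeeg.GroundTruth(noise_sd=0.5)
    rec = synthmeeg.simulate_recording(small_block, sensors, truth, seed=5)
    return preprocess.rereference_eeg(preprocess.filter_continuous(rec))


def single_tone_block(band: int = 4, duration_ms: int = 33):
    """Minimal hand-built block: one tone, one far-away chord."""
    chord = stimgen.ChordEvent(
        onset_ms=3000, duration_ms=33, identity="A", kind="target",
        preceding_isi_ms=np.nan, following_isi_ms=np.nan,
    )
    tone = stimgen.ToneEvent(onset_ms=500, duration_ms=duration_ms, band=band)
    trial = stimgen.Trial(index=0, chords=[chord], tones=[tone])
    return stimgen.StimulusBlock(
        condition="rhythmic", trials=[trial], params=stimgen.BlockParams(n_trials=1), seed=0
    )
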