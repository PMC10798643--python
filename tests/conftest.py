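"""Shared fixtures: desk-scale synthetic groups used across test modules.

The "group" fixtures emulate the study conditions at test scale
(8 subjects x 32 channels x 10 sequences, 250 Hz epochs): additive-only
feature signals with the documented onset/peak latencies, and a variant
with an added sf x colour conjunction signal.  They are session-scoped
because group-level decoding dominates the suite's runtime.
"""

import numpy as np
import pytest

from featuredyn import (
    FEATURES,
    NoiseSpec,
    SignalComponent,
    SignalSpec,
    build_sequences,
    build_stimulus_set,
    decode_feature_timecourse,
    default_signal_spec,
    generate_epochs,
)

N_SUBJECTS = 8
N_CHANNELS = 32
N_SEQUENCES = 10

#: decoding restricted to -100..300 ms: all injected dynamics end well
#: before 300 ms, and halving the grid halves the suite's runtime
DECODE_TIMES = np.arange(-100, 301, 4.0)

#: window for conjunction analyses (covers baseline-free early response)
CONJUNCTION_TIMES = np.arange(48, 201, 4.0)

#: injected conjunction: later than the single features, per the observed
#: lag of conjunction coding behind feature coding
CONJUNCTION_COMPONENT = SignalComponent(onset_ms=96, peak_ms=128, amplitude=1.5)

INJECTED_PAIR = ("sf", "colour")

#: injected single-feature latencies (ms), from default_signal_spec
INJECTED_ONSETS = {"contrast": 72, "sf": 72, "colour": 72, "orientation": 92}
INJECTED_PEAKS = {"contrast": 96, "sf": 112, "colour": 112, "orientation": 120}


def make_group(signal: SignalSpec, seed_base: int):
    subjects = []
    for i in range(N_SUBJECTS):
        design = build_sequences(N_SEQUENCES, 6.67, seed=seed_base + i)
        subjects.append(
            generate_epochs(
                design,
                N_CHANNELS,
                signal,
                NoiseSpec(),
                subject_seed=seed_base + i,
                subject_id=f"sub-{i:02d}",
            )
        )
    return subjects


@pytest.fixture(scope="session")
def stimset():
    return build_stimulus_set()


@pytest.fixture(scope="session")
def additive_group():
    """Subjects whose signals are purely additive in single features."""
    return make_group(default_signal_spec(), seed_base=3000)


@pytest.fixture(scope="session")
def injected_group():
    """Additive signals plus one sf x colour conjunction component."""
    spec = default_signal_spec()
    signal = SignalSpec(
        features=dict(spec.features),
        conjunctions={INJECTED_PAIR: CONJUNCTION_COMPONENT},
        width_ms=spec.width_ms,
    )
    return make_group(signal, seed_base=4000)


@pytest.fixture(scope="session")
def feature_decoding(additive_group):
    """Per-feature group decoding matrices on the additive group.

    Returns {feature: (times, accuracy matrix subjects x times)}.
    """
    out = {}
    for feature in FEATURES:
        tcs = [
            decode_feature_timecourse(ds, feature, times=DECODE_TIMES)
            for ds in additive_group
        ]
        out[feature] = (tcs[0].times, np.stack([tc.accuracy for tc in tcs]))
    return out


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small, fast dataset for unit tests: 12 channels, 4 sequences."""
    design = build_sequences(4, 20.0, seed=99)
    signal = SignalSpec(
        features={"colour": SignalComponent(40, 100, 2.5, pattern_seed=5)},
        width_ms=60.0,
    )
    return generate_epochs(
        design, 12, signal, NoiseSpec(), subject_seed=99, subject_id="tiny"
    )
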