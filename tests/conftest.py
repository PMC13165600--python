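import numpy as np
import pandas as pd
import pytest

from accelhar import (
    FEATURE_NAMES,
    LabeledWindow,
    SimulationConfig,
    extract_features,
    simulate_dataset,
    window_segments,
)


def make_window(samples, label="walking", participant="P00", placement="hip", index=0):
    return LabeledWindow(
        participant_id=participant,
        placement=placement,
        label=label,
        window_samples=np.asarray(samples, dtype=float),
        window_index=index,
    )


@pytest.fixture
def static_window():
    """A 1-s window of pure gravity along y, no movement."""
    return make_window(np.tile([0.0, 1.0, 0.0], (100, 1)))


@pytest.fixture(scope="session")
def small_cohort_matrix():
    """Feature matrix for a reduced six-participant cohort (fast model tests)."""
    config = SimulationConfig(
        n_participants=6,
        trials={"walking": 2, "running": 2, "jumping": 3},
        segment_seconds={"walking": 3.0, "running": 2.0, "jumping": 2.0},
        seed=11,
    )
    recordings, segments = simulate_dataset(config)
    windows = []
    for recording in recordings:
        windows.extend(
            window_segments(
                recording,
                [s for s in segments if s.recording_id == recording.recording_id],
            )
        )
    return extract_features(windows, fs=config.fs)


@pytest.fixture(scope="session")
def separable_matrix():
    """A trivially separable feature matrix: a distinct constant level per
    class in every one of the 54 columns, plus small seeded noise.

    Eight participants, 12 windows each.
    """
    rng = np.random.default_rng(42)
    rows = []
    levels = {"walking": 0.0, "running": 5.0, "jumping": 10.0}
    index = 0
    for p in range(8):
        for label, level in levels.items():
            for _ in range(4):
                values = dict(
                    zip(FEATURE_NAMES, level + rng.normal(0, 0.05, len(FEATURE_NAMES)))
                )
                values["participant_id"] = f"P{p:02d}"
                values["placement"] = "hip"
                values["label"] = label
                values["window_index"] = index
                index += 1
                rows.append(values)
    return pd.DataFrame(rows)
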