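import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from specklesense import (
    OpticsParams,
    RunConfig,
    render_speckle_video,
    run_study,
)


@pytest.fixture(scope="session")
def integer_shift_video():
    """Noise-free video whose pattern moves by exactly (+1, 0) px per frame."""
    pos = np.zeros((12, 2))
    pos[:, 0] = np.arange(12)
    optics = OpticsParams(frame_px=64, master_margin_px=16, sensor_noise_sd=0.0, seed=5)
    return render_speckle_video(pos, optics)


@pytest.fixture(scope="session")
def static_video():
    """Noise-free video with no motion at all."""
    pos = np.zeros((6, 2))
    optics = OpticsParams(frame_px=64, master_margin_px=8, sensor_noise_sd=0.0, seed=9)
    return render_speckle_video(pos, optics)


def make_feature_table(n_per_label=30, n_features=6, separation=3.0, seed=0):
    """Synthetic feature table: one informative feature per label, rest noise.

    Subjects S1..S5 are assigned round-robin so subject-wise splits work.
    """
    from specklesense import FIVE_LABELS

    rng = np.random.default_rng(seed)
    rows = []
    for li, label in enumerate(FIVE_LABELS):
        for i in range(n_per_label):
            feats = rng.normal(size=n_features)
            # first feature carries the labels with gaps far beyond its noise
            feats[0] = separation * li + 0.05 * feats[0]
            rows.append(
                {
                    "subject_id": f"S{(i % 5) + 1}",
                    "recording_id": i,
                    "chunk_index": i,
                    "time_label": label,
                    **{f"x__f{j}": feats[j] for j in range(n_features)},
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def separable_table():
    return make_feature_table()


@pytest.fixture(scope="session")
def study_result():
    """The scaled synthetic study run end-to-end through rendered video.

    5 subjects x 5 states x 2 recordings/state, 20 search trials per scheme;
    shared across tests because it is by far the most expensive fixture.
    """
    cfg = RunConfig(render=True, recordings_per_state=2, trials=20, seed=1)
    return run_study(cfg)
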