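import numpy as np
import pytest
from scipy.signal import periodogram

from specklesense import (
    CardiacParams,
    FIVE_LABELS,
    OpticsParams,
    StateProfile,
    default_state_profiles,
    default_study_design,
    render_speckle_video,
    simulate_displacement,
    simulate_study,
)
from specklesense.simulate import synthesize_master_field


def quiet_cardiac(**overrides):
    base = dict(
        heart_rate_hz=1.2, hrv_sd_s=0.0, pulse_amplitude_px=2.0,
        drift_amplitude_px=0.0, noise_sd_px=0.0,
    )
    base.update(overrides)
    return CardiacParams(**base)


class TestCardiacParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"heart_rate_hz": 0.3},
            {"heart_rate_hz": 3.5},
            {"hrv_sd_s": -0.1},
            {"drift_freq_hz": 0.6},
            {"pulse_amplitude_px": -1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CardiacParams(**kwargs)

    def test_unknown_state_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            StateProfile("45 min", CardiacParams())


class TestSimulateDisplacement:
    def test_zero_amplitudes_give_all_zero_trace(self):
        state = StateProfile(
            "before drinking", quiet_cardiac(pulse_amplitude_px=0.0)
        )
        trace = simulate_displacement(state, 2.0, 500.0, seed=0)
        assert np.all(trace == 0.0)

    def test_recording_length_matches_duration_times_fps(self):
        state = StateProfile("before drinking", CardiacParams())
        trace = simulate_displacement(state, 6.0, 500.0, seed=0)
        assert trace.shape == (3000, 2)

    def test_beat_count_matches_rate(self):
        # 1.2 Hz for 60 s with no variability: exactly 72 distinct beat lobes
        state = StateProfile("before drinking", quiet_cardiac())
        x = simulate_displacement(state, 60.0, 500.0, seed=0)[:, 0]
        interior = x[1:-1]
        peaks = (
            (interior > x[:-2]) & (interior >= x[2:]) & (interior > 0.5 * x.max())
        )
        assert int(peaks.sum()) == 72

    def test_deterministic_given_seed(self):
        state = StateProfile("0 min", default_state_profiles()["0 min"].cardiac)
        a = simulate_displacement(state, 3.0, 500.0, seed=11)
        b = simulate_displacement(state, 3.0, 500.0, seed=11)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("duration_s,fps", [(0.0, 500.0), (6.0, -1.0)])
    def test_invalid_arguments(self, duration_s, fps):
        state = StateProfile("before drinking", CardiacParams())
        with pytest.raises(ValueError):
            simulate_displacement(state, duration_s, fps, seed=0)

    def test_power_concentrates_in_cardiac_band(self):
        # drift and noise off: >90% of non-DC power must sit in 0.5-3 Hz
        state = StateProfile("before drinking", quiet_cardiac(hrv_sd_s=0.05))
        x = simulate_displacement(state, 60.0, 500.0, seed=3)[:, 0]
        freqs, power = periodogram(x, fs=500.0)
        band = (freqs >= 0.5) & (freqs <= 3.0)
        assert power[band].sum() / power[freqs > 0].sum() > 0.9


class TestRenderSpeckleVideo:
    def test_no_motion_means_identical_frames(self, static_video):
        for frame in static_video.frames:
            np.testing.assert_array_equal(frame, static_video.frames[0])

    def test_integer_translation_is_exact_crop(self, integer_shift_video):
        # pattern moves +1 px/frame rightward: frame i is frame 0 shifted by i
        frames = integer_shift_video.frames
        for i in range(1, 5):
            np.testing.assert_array_equal(frames[i][:, i:], frames[0][:, :-i])

    def test_determinism(self):
        pos = np.cumsum(np.full((10, 2), 0.3), axis=0)
        optics = OpticsParams(seed=21)
        a = render_speckle_video(pos, optics)
        b = render_speckle_video(pos, optics)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_out_of_margin_shift_names_frame(self):
        pos = np.zeros((30, 2))
        pos[:, 1] = np.arange(30)  # runs past the 16 px margin at frame 16
        with pytest.raises(ValueError, match="frame 16"):
            render_speckle_video(pos, OpticsParams(master_margin_px=16))

    def test_master_field_is_developed_speckle(self):
        field = synthesize_master_field(128, 4.0, np.random.default_rng(0))
        cv = field.std() / field.mean()
        assert cv > 0.3  # fully developed speckle has unit contrast


class TestSimulateStudy:
    def test_default_study_has_125_recordings(self):
        # 5 subjects x 5 states x 5 recordings; fast mode keeps this cheap
        recordings, manifest = simulate_study(
            recordings_per_state=5, duration_s=0.6, fps=100.0, render=False
        )
        assert len(recordings) == 125
        assert len(manifest) == 125
        assert set(manifest["time_label"]) == set(FIVE_LABELS)

    def test_single_subject_counts(self):
        design = default_study_design(1)
        recordings, manifest = simulate_study(
            design, recordings_per_state=1, duration_s=0.6, fps=100.0, render=False
        )
        assert len(recordings) == 5 and len(manifest) == 5

    def test_same_seed_reproduces_study(self):
        design = default_study_design(2)
        kwargs = dict(recordings_per_state=1, duration_s=0.5, fps=100.0, seed=4, render=False)
        rec_a, man_a = simulate_study(design, **kwargs)
        rec_b, man_b = simulate_study(design, **kwargs)
        assert man_a.equals(man_b)
        for (_, ta), (_, tb) in zip(rec_a, rec_b):
            np.testing.assert_array_equal(ta, tb)

    def test_duplicate_subject_ids_rejected(self):
        design = default_study_design(2)
        design[1] = (design[0][0], design[1][1])
        with pytest.raises(ValueError, match="duplicate"):
            simulate_study(design, recordings_per_state=1, duration_s=0.5, fps=100.0, render=False)

    def test_missing_state_label_rejected(self):
        profiles = {k: v for k, v in default_state_profiles().items() if k != "90 min"}
        with pytest.raises(ValueError, match="90 min"):
            simulate_study([("S1", profiles), ("S2", default_state_profiles())],
                           recordings_per_state=1, duration_s=0.5, fps=100.0, render=False)
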