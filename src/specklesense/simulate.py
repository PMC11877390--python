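"""Synthetic defocused-speckle recordings with known ground truth.

The physical picture: a coherent laser spot on skin above the radial artery
produces a fully developed speckle pattern.  With the camera defocused to the
far field, a tilt of the illuminated surface translates the whole pattern
laterally instead of decorrelating it, so the beat-to-beat motion of the
artery wall shows up as a 2D trajectory of the speckle field.  This module
builds that forward model: a cardiac pulse train drives a lateral shift
series, and frames are rendered as shifted crops of one master speckle field.

The "alcohol state" labels parameterize the cardiac waveform (rate, amplitude,
inter-beat variability) so that classifiers downstream have a real, known
signal to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: The five measurement time points, in chronological order.
FIVE_LABELS = ("before drinking", "0 min", "30 min", "60 min", "90 min")

# Physiological band of the heartbeat signal; motion artifacts live below it.
CARDIAC_BAND_HZ = (0.5, 3.0)


@dataclass(frozen=True)
class CardiacParams:
    """Parameters of the beat-driven displacement waveform.

    Attributes
    ----------
    heart_rate_hz:
        Mean beat frequency. Must lie in the physiological 0.5-3 Hz band.
    hrv_sd_s:
        Standard deviation of inter-beat intervals (heart-rate variability),
        in seconds.
    pulse_amplitude_px:
        Peak tilt-induced lateral shift per beat, in pixels.
    pulse_width_s:
        Duration of one beat's displacement lobe. The default of 0.5 s keeps
        almost all pulse-train power below 3 Hz while still resolving
        individual beats at rates up to ~1.5 Hz.
    drift_amplitude_px, drift_freq_hz:
        Sub-0.5 Hz sinusoidal motion-artifact component.
    noise_sd_px:
        Additive white displacement noise per axis, in pixels.
    """

    heart_rate_hz: float = 1.1
    hrv_sd_s: float = 0.05
    pulse_amplitude_px: float = 2.0
    pulse_width_s: float = 0.5
    drift_amplitude_px: float = 0.3
    drift_freq_hz: float = 0.2
    noise_sd_px: float = 0.02

    def __post_init__(self) -> None:
        lo, hi = CARDIAC_BAND_HZ
        if not (lo <= self.heart_rate_hz <= hi):
            raise ValueError(
                f"heart_rate_hz={self.heart_rate_hz} outside physiological "
                f"band [{lo}, {hi}] Hz"
            )
        if self.hrv_sd_s < 0:
            raise ValueError("hrv_sd_s must be >= 0")
        if self.drift_freq_hz >= 0.5:
            raise ValueError("drift_freq_hz must be < 0.5 (motion-artifact band)")
        if self.pulse_width_s <= 0:
            raise ValueError("pulse_width_s must be > 0")
        for name in ("pulse_amplitude_px", "drift_amplitude_px", "noise_sd_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class StateProfile:
    """One measurement time point and the cardiac waveform it produces."""

    label: str
    cardiac: CardiacParams

    def __post_init__(self) -> None:
        if self.label not in FIVE_LABELS:
            raise ValueError(
                f"unknown time-point label {self.label!r}; "
                f"expected one of {FIVE_LABELS}"
            )


@dataclass(frozen=True)
class OpticsParams:
    """Rendering parameters of the synthetic speckle camera.

    ``master_margin_px`` is the extra border of the master speckle field on
    each side of the cropped frame, so the crop window never leaves the field
    for any cumulative shift smaller than the margin.
    """

    frame_px: int = 64
    grain_px: float = 4.0
    master_margin_px: int = 16
    bit_depth: int = 8
    sensor_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_px <= 0:
            raise ValueError("frame_px must be > 0")
        if self.grain_px < 2:
            raise ValueError("grain_px must be >= 2 (Nyquist for the peak)")
        if self.master_margin_px < 1:
            raise ValueError("master_margin_px must be >= 1")
        if not (1 <= self.bit_depth <= 16):
            raise ValueError("bit_depth must be in [1, 16]")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be >= 0")


@dataclass
class SpeckleVideo:
    """Ordered stack of grayscale frames plus acquisition metadata.

    ``ground_truth``, when present, is the true cumulative lateral position
    (x, y) of the speckle pattern for every frame, in pixels, relative to
    frame 0.
    """

    frames: np.ndarray  # (n_frames, H, W)
    fps: float
    ground_truth: np.ndarray | None = None  # (n_frames, 2)

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) stack")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.ground_truth is not None and len(self.ground_truth) != len(
            self.frames
        ):
            raise ValueError("ground_truth must have one (x, y) entry per frame")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def default_state_profiles() -> dict[str, StateProfile]:
    """The default study design: five states with a monotone return to baseline.

    Post-consumption states have elevated pulse amplitude and heart rate that
    decay toward the pre-drinking baseline, mimicking a blood alcohol level
    that falls linearly over the 90-minute session.
    """
    base = CardiacParams()
    amp_scale = {"0 min": 1.5, "30 min": 1.4, "60 min": 1.25, "90 min": 1.15}
    rate_scale = {"0 min": 1.25, "30 min": 1.2, "60 min": 1.12, "90 min": 1.06}
    profiles = {FIVE_LABELS[0]: StateProfile(FIVE_LABELS[0], base)}
    for label in FIVE_LABELS[1:]:
        profiles[label] = StateProfile(
            label,
            replace(
                base,
                pulse_amplitude_px=base.pulse_amplitude_px * amp_scale[label],
                heart_rate_hz=base.heart_rate_hz * rate_scale[label],
            ),
        )
    return profiles


def _beat_times(
    cardiac: CardiacParams, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Jittered beat centres: intervals ~ Normal(1/rate, hrv), truncated > 0."""
    mean_ibi = 1.0 / cardiac.heart_rate_hz
    times = []
    t = 0.5 * mean_ibi  # first beat at half an interval, away from the edges
    while t < duration_s:
        times.append(t)
        ibi = rng.normal(mean_ibi, cardiac.hrv_sd_s) if cardiac.hrv_sd_s > 0 else mean_ibi
        # truncate to positive: redraw pathological draws (rare for sane hrv)
        attempts = 0
        while ibi <= 0 and attempts < 100:
            ibi = rng.normal(mean_ibi, cardiac.hrv_sd_s)
            attempts += 1
        if ibi <= 0:
            ibi = mean_ibi
        t += ibi
    return np.asarray(times)


def simulate_displacement(
    state: StateProfile, duration_s: float, fps: float, seed: int
) -> np.ndarray:
    """Ground-truth 2D lateral position series for one recording.

    The cardiac component is a train of raised-cosine (Hann) lobes, one per
    beat, with beat times jittered by the configured heart-rate variability.
    That scalar waveform, plus a slow sinusoidal drift, drives a fixed unit
    direction vector (1, 0.4)/|.| so both axes carry correlated signal; white
    displacement noise is added independently per axis.

    Returns
    -------
    (n, 2) array of cumulative (x, y) positions in pixels, n = round(duration_s * fps).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if fps <= 0:
        raise ValueError("fps must be > 0")
    c = state.cardiac
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps

    signal = np.zeros(n)
    if c.pulse_amplitude_px > 0:
        half = c.pulse_width_s / 2.0
        for tb in _beat_times(c, duration_s, rng):
            lo = np.searchsorted(t, tb - half)
            hi = np.searchsorted(t, tb + half, side="right")
            tt = t[lo:hi] - tb
            signal[lo:hi] += (
                c.pulse_amplitude_px * 0.5 * (1.0 + np.cos(np.pi * tt / half))
            )
    else:
        # keep the rng stream aligned whether or not beats are drawn
        _beat_times(c, duration_s, rng)

    if c.drift_amplitude_px > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal = signal + c.drift_amplitude_px * np.sin(
            2 * np.pi * c.drift_freq_hz * t + phase
        )

    direction = np.array([1.0, 0.4])
    direction /= np.linalg.norm(direction)
    xy = np.outer(signal, direction)
    if c.noise_sd_px > 0:
        xy = xy + rng.normal(0.0, c.noise_sd_px, size=xy.shape)
    return xy


def synthesize_master_field(
    size_px: int, grain_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Fully developed speckle intensity field via a random phase screen.

    Uniform random phase on a centred circular frequency-domain support of
    diameter ``size_px / grain_px`` (the aperture), inverse-transformed; the
    intensity is exponentially distributed (unit contrast), as for polarized,
    fully developed speckle.  Returned normalized to unit mean.
    """
    fy = np.fft.fftfreq(size_px)[:, None]
    fx = np.fft.fftfreq(size_px)[None, :]
    radius = 0.5 / grain_px  # aperture radius in cycles/px
    support = (fx**2 + fy**2) <= radius**2
    phase = rng.uniform(0, 2 * np.pi, size=(size_px, size_px))
    spectrum = np.where(support, np.exp(1j * phase), 0.0)
    field = np.fft.ifft2(spectrum)
    intensity = np.abs(field) ** 2
    return intensity / intensity.mean()


def render_speckle_video(
    true_shift: np.ndarray,
    optics: OpticsParams,
    fps: float = 500.0,
) -> SpeckleVideo:
    """Render frames as shifted crops of one master speckle field.

    Frame *i* shows the master pattern translated by ``true_shift[i]``
    (+x rightward, +y downward).  The integer part of each shift is applied
    by pure array indexing — so integer-shift ground truth survives rendering
    exactly — and the fractional part by bilinear interpolation.  Sensor
    noise is added per frame and the result quantized to ``bit_depth`` bits.
    """
    shift = np.atleast_2d(np.asarray(true_shift, dtype=float))
    if shift.ndim != 2 or shift.shape[1] != 2:
        raise ValueError("true_shift must be an (n, 2) array of (x, y) positions")
    margin = optics.master_margin_px
    # one extra pixel is consumed by the bilinear neighbourhood
    limit = margin - 1
    over = np.nonzero(np.abs(shift).max(axis=1) > limit)[0]
    if over.size:
        raise ValueError(
            f"cumulative shift at frame {over[0]} exceeds the master margin "
            f"({np.abs(shift[over[0]]).max():.2f} px > {limit} px); "
            "increase master_margin_px"
        )

    rng = np.random.default_rng(optics.seed)
    size = optics.frame_px + 2 * margin
    master = synthesize_master_field(size, optics.grain_px, rng)
    max_level = 2**optics.bit_depth - 1
    # mean grey ~ 1/4 of full scale: exponential tail clipping stays ~ 2%
    master_grey = master * (0.25 * max_level)

    h = w = optics.frame_px
    dtype = np.uint8 if optics.bit_depth <= 8 else np.uint16
    frames = np.empty((len(shift), h, w), dtype=dtype)
    for i, (x, y) in enumerate(shift):
        # pattern moves by (+x, +y)  =>  crop window moves by (-x, -y)
        oy, ox = margin - y, margin - x
        iy, ix = int(np.floor(oy)), int(np.floor(ox))
        fy, fx = oy - iy, ox - ix
        block = master_grey[iy : iy + h + 1, ix : ix + w + 1]
        if fy == 0.0 and fx == 0.0:
            img = block[:h, :w].copy()
        else:
            img = (
                (1 - fy) * (1 - fx) * block[:h, :w]
                + (1 - fy) * fx * block[:h, 1:]
                + fy * (1 - fx) * block[1:, :w]
                + fy * fx * block[1:, 1:]
            )
        if optics.sensor_noise_sd > 0:
            img = img + rng.normal(0.0, optics.sensor_noise_sd, size=img.shape)
        frames[i] = np.round(np.clip(img, 0, max_level)).astype(dtype)
    return SpeckleVideo(frames=frames, fps=fps, ground_truth=shift.copy())


def recording_seed(master_seed: int, subject_idx: int, state_idx: int, rec_idx: int) -> int:
    """Deterministic per-recording seed fan-out from one master seed."""
    ss = np.random.SeedSequence([int(master_seed), subject_idx, state_idx, rec_idx])
    return int(ss.generate_state(1)[0] % 2**31)


StudyDesign = Sequence[tuple[str, dict[str, StateProfile]]]


def default_study_design(n_subjects: int = 5) -> list[tuple[str, dict[str, StateProfile]]]:
    """Five subjects sharing the state schedule, with individual resting rates.

    Real subjects differ physiologically; a small deterministic per-subject
    heart-rate multiplier keeps held-out-subject validation honest (the
    validation subject is similar to, but not a clone of, the training ones).
    """
    rate_mult = [0.95, 1.0, 1.02, 1.05, 0.98, 0.97, 1.03, 1.01, 0.99, 1.04]
    if n_subjects > len(rate_mult):
        raise ValueError(f"at most {len(rate_mult)} default subjects supported")
    design = []
    for s in range(n_subjects):
        profiles = {}
        for label, prof in default_state_profiles().items():
            c = prof.cardiac
            profiles[label] = StateProfile(
                label, replace(c, heart_rate_hz=c.heart_rate_hz * rate_mult[s])
            )
        design.append((f"S{s + 1}", profiles))
    return design


def _validate_design(design: StudyDesign) -> None:
    ids = [sid for sid, _ in design]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject ids in design: {dupes}")
    for sid, profiles in design:
        missing = [lab for lab in FIVE_LABELS if lab not in profiles]
        if missing:
            raise ValueError(f"subject {sid!r} is missing state labels {missing}")


def iter_study_recordings(
    design: StudyDesign,
    recordings_per_state: int = 5,
    duration_s: float = 6.0,
    fps: float = 500.0,
    seed: int = 0,
    optics: OpticsParams | None = None,
    render: bool = True,
) -> Iterator[tuple[dict, SpeckleVideo | np.ndarray]]:
    """Yield (metadata, recording) pairs for a whole study, lazily.

    With ``render=False`` (the fast mode) the recording is the ground-truth
    displacement series itself, skipping speckle rendering; with
    ``render=True`` it is a :class:`SpeckleVideo`.  Laziness matters: a full
    study is hundreds of megabytes of frames.
    """
    _validate_design(design)
    if recordings_per_state < 1:
        raise ValueError("recordings_per_state must be >= 1")
    if optics is None:
        optics = OpticsParams()
    for si, (sid, profiles) in enumerate(design):
        for li, label in enumerate(FIVE_LABELS):
            for ri in range(recordings_per_state):
                rec_seed = recording_seed(seed, si, li, ri)
                meta = {
                    "subject_id": sid,
                    "time_label": label,
                    "recording_id": ri,
                    "seed": rec_seed,
                }
                trace = simulate_displacement(profiles[label], duration_s, fps, rec_seed)
                if render:
                    video = render_speckle_video(
                        trace, replace(optics, seed=rec_seed), fps=fps
                    )
                    yield meta, video
                else:
                    yield meta, trace


def simulate_study(
    design: StudyDesign | None = None,
    recordings_per_state: int = 5,
    duration_s: float = 6.0,
    fps: float = 500.0,
    seed: int = 0,
    optics: OpticsParams | None = None,
    render: bool = True,
) -> tuple[list[tuple[dict, SpeckleVideo | np.ndarray]], pd.DataFrame]:
    """Materialize a full study in memory and return it with its manifest.

    The default design mirrors a five-subject protocol with five time points
    and five recordings per time point (125 recordings).  For large studies
    prefer :func:`iter_study_recordings` and stream recordings to disk.
    """
    if design is None:
        design = default_study_design()
    recordings = list(
        iter_study_recordings(
            design, recordings_per_state, duration_s, fps, seed, optics, render
        )
    )
    manifest = pd.DataFrame([meta for meta, _ in recordings])
    return recordings, manifest
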