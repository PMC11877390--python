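"""Windowing of displacement traces into labelled learning elements.

A recording's trajectory is sliced into overlapping fixed-length chunks
(default 256 frames with a 32-frame stride).  Each chunk carries four
channels: the X and Y cumulative displacement, re-zeroed to the chunk's
first sample, and their first differences (the per-pair shifts).  Chunks
keep their subject/recording/time-point metadata so that splitting can be
done subject-wise, which is the only split that avoids leaking overlapping
windows of one person's recordings across the train/validation boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import FIVE_LABELS
from .vibrometry import DisplacementTrace

CHANNEL_NAMES = ("x", "y", "dx", "dy")


@dataclass
class ElementChunk:
    """One 4-channel window of a displacement trace, the unit of classification."""

    channels: np.ndarray  # (4, L): x, y, dx, dy
    subject_id: str
    recording_id: int
    chunk_index: int
    time_label: str
    start_frame: int

    def __post_init__(self) -> None:
        if self.channels.shape[0] != 4:
            raise ValueError("channels must be a (4, L) array")
        if self.time_label not in FIVE_LABELS:
            raise ValueError(f"unknown time label {self.time_label!r}")

    @property
    def length(self) -> int:
        return self.channels.shape[1]


def chunk_starts(n_samples: int, length: int, stride: int) -> list[int]:
    """Valid window start offsets; trailing partial windows are dropped."""
    return list(range(0, n_samples - length + 1, stride))


def chunk_trace(
    trace: DisplacementTrace,
    subject_id: str,
    recording_id: int,
    time_label: str,
    length: int = 256,
    stride: int = 32,
) -> list[ElementChunk]:
    """Slice a trace into overlapping chunks with derived difference channels.

    Channels 1-2 are the cumulative (x, y) position re-zeroed to each chunk's
    first sample; channels 3-4 are their first differences, padded back to
    length L by repeating the first difference value.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = trace.n_frames
    if n < length:
        raise ValueError(
            f"trace has {n} samples but at least {length} are required for one chunk"
        )
    chunks = []
    for k, s in enumerate(chunk_starts(n, length, stride)):
        pos = trace.cum_position[s : s + length] - trace.cum_position[s]
        diff = np.diff(pos, axis=0)
        padded = np.vstack([diff[:1], diff])  # repeat first difference
        channels = np.vstack([pos.T, padded.T])
        chunks.append(
            ElementChunk(
                channels=channels,
                subject_id=subject_id,
                recording_id=recording_id,
                chunk_index=k,
                time_label=time_label,
                start_frame=s,
            )
        )
    return chunks


def split_by_subject(
    chunks: list[ElementChunk], validation_subjects: set[str] | frozenset[str]
) -> tuple[list[ElementChunk], list[ElementChunk]]:
    """Partition chunks into training and validation sets by subject identity.

    This is the canonical held-out-subject split: no chunk of a validation
    subject ever reaches training, so identity leakage across overlapping
    windows is impossible by construction.
    """
    validation_subjects = set(validation_subjects)
    observed = {c.subject_id for c in chunks}
    if not validation_subjects:
        raise ValueError("validation_subjects must be non-empty")
    unknown = validation_subjects - observed
    if unknown:
        raise ValueError(f"validation subjects not present in data: {sorted(unknown)}")
    if validation_subjects == observed:
        raise ValueError("validation_subjects must be a proper subset of all subjects")
    train = [c for c in chunks if c.subject_id not in validation_subjects]
    val = [c for c in chunks if c.subject_id in validation_subjects]
    return train, val


def split_random(
    chunks: list[ElementChunk], validation_fraction: float = 0.2, seed: int = 0
) -> tuple[list[ElementChunk], list[ElementChunk]]:
    """Chunk-wise random split. Discouraged: overlapping chunks leak.

    Adjacent chunks share up to (length - stride) frames, so a random split
    places near-duplicates on both sides of the boundary and inflates
    validation scores.  Provided for comparison studies only.
    """
    warnings.warn(
        "split_random leaks overlapping windows across the train/validation "
        "boundary; prefer split_by_subject",
        UserWarning,
        stacklevel=2,
    )
    if not 0 < validation_fraction < 1:
        raise ValueError("validation_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(chunks))
    n_val = max(1, int(round(validation_fraction * len(chunks))))
    val_set = set(idx[:n_val].tolist())
    train = [c for i, c in enumerate(chunks) if i not in val_set]
    val = [c for i, c in enumerate(chunks) if i in val_set]
    return train, val


def augment_chunks(
    chunks: list[ElementChunk],
    n_copies: int = 1,
    noise_sd: float = 0.05,
    max_shift: int = 8,
    seed: int = 0,
) -> list[ElementChunk]:
    """Optional augmentation hook: jittered copies of existing chunks.

    Each copy adds small white noise to the position channels and applies a
    small circular time shift; difference channels are recomputed.  Disabled
    by default in the pipeline.
    """
    rng = np.random.default_rng(seed)
    out = list(chunks)
    for c in chunks:
        for j in range(n_copies):
            pos = c.channels[:2].T.copy()
            roll = int(rng.integers(-max_shift, max_shift + 1))
            pos = np.roll(pos, roll, axis=0)
            pos = pos - pos[0] + rng.normal(0, noise_sd, size=pos.shape)
            pos[0] = 0.0
            diff = np.diff(pos, axis=0)
            padded = np.vstack([diff[:1], diff])
            out.append(
                ElementChunk(
                    channels=np.vstack([pos.T, padded.T]),
                    subject_id=c.subject_id,
                    recording_id=c.recording_id,
                    chunk_index=len(out),
                    time_label=c.time_label,
                    start_frame=c.start_frame,
                )
            )
    return out
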