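"""Displacement extraction from speckle videos by correlation-peak tracking.

Each consecutive frame pair is cross-correlated in the frequency domain; the
location of the correlation maximum gives the lateral shift of the speckle
pattern between the two frames, optionally refined to sub-pixel precision by
a three-point parabolic fit.  Summing the per-pair shifts reconstructs the
cumulative trajectory of the pattern, which carries the cardiac signal.

Coordinate convention (used everywhere in this package): x = column index
increasing rightward, y = row index increasing downward, origin at top-left.
``correlate_pair(a, b)`` returns the (dx, dy) by which the pattern in ``b``
is displaced relative to ``a``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SpeckleVideo


@dataclass
class DisplacementTrace:
    """Per-pair 2D shifts and the cumulative peak-position trajectory.

    Invariants: ``cum_position[0] == (0, 0)`` and
    ``cum_position[k] == pair_shift[:k].sum(axis=0)``.
    """

    fps: float
    pair_shift: np.ndarray  # (n_frames - 1, 2) of (dx, dy)
    cum_position: np.ndarray  # (n_frames, 2) of (x, y)
    peak_height: np.ndarray  # (n_frames - 1,) normalized correlation maxima

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        n = len(self.cum_position)
        if len(self.pair_shift) != n - 1 or len(self.peak_height) != n - 1:
            raise ValueError("pair_shift/peak_height must have length n_frames - 1")

    @property
    def n_frames(self) -> int:
        return len(self.cum_position)


def _signed_shift(index: int, size: int) -> int:
    """Map a circular argmax index to a signed shift in (-size/2, size/2]."""
    return index if index <= size // 2 else index - size


def _parabolic_offset(c_minus: float, c_zero: float, c_plus: float) -> float:
    """Vertex offset of the parabola through three equispaced samples, clamped."""
    denom = c_minus - 2.0 * c_zero + c_plus
    if denom >= 0:  # flat or not a local maximum: no refinement
        return 0.0
    delta = 0.5 * (c_minus - c_plus) / denom
    return float(np.clip(delta, -0.5, 0.5))


def correlate_pair(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    subpixel: bool = True,
    window: bool = False,
) -> tuple[float, float, float]:
    """Locate the cross-correlation peak between two speckle frames.

    Computes the zero-mean normalized circular cross-correlation in the
    frequency domain and returns the signed shift (dx, dy) of the argmax,
    each axis mapped into (-N/2, N/2], plus the normalized correlation value
    at the integer argmax.  With ``subpixel`` the shift is refined per axis
    by a parabolic fit over the three samples around the peak (clamped to
    +/-0.5 px).  ``window`` applies a Hann window before correlating, for
    scenes dominated by frame edges.

    Ties between equal maxima resolve to the smallest row-major index.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2 or min(a.shape) < 32:
        raise ValueError("frames must be 2D and at least 32x32")
    a = a - a.mean()
    b = b - b.mean()
    norm_a = np.linalg.norm(a)
    norm_b = np.linalg.norm(b)
    if norm_a == 0 or norm_b == 0:
        which = "first" if norm_a == 0 else "second"
        raise ValueError(
            f"{which} frame is constant (zero variance); no correlation peak exists"
        )
    if window:
        wy = np.hanning(a.shape[0])[:, None]
        wx = np.hanning(a.shape[1])[None, :]
        taper = wy * wx
        a = a * taper
        b = b * taper
        norm_a = np.linalg.norm(a)
        norm_b = np.linalg.norm(b)

    corr = np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))).real
    corr /= norm_a * norm_b

    py, px = np.unravel_index(int(np.argmax(corr)), corr.shape)
    peak = float(corr[py, px])
    ny, nx = corr.shape
    dx = float(_signed_shift(px, nx))
    dy = float(_signed_shift(py, ny))
    if subpixel:
        dx += _parabolic_offset(
            corr[py, (px - 1) % nx], corr[py, px], corr[py, (px + 1) % nx]
        )
        dy += _parabolic_offset(
            corr[(py - 1) % ny, px], corr[py, px], corr[(py + 1) % ny, px]
        )
    return dx, dy, peak


def extract_displacement(
    video: SpeckleVideo, subpixel: bool = True, window: bool = False
) -> DisplacementTrace:
    """Track the correlation peak across all consecutive frame pairs.

    The cumulative position is the running sum of per-pair shifts, anchored
    at (0, 0) for frame 0.
    """
    n = video.n_frames
    if n < 2:
        raise ValueError("video must have at least 2 frames")
    pair_shift = np.empty((n - 1, 2))
    peak_height = np.empty(n - 1)
    for i in range(n - 1):
        try:
            dx, dy, peak = correlate_pair(
                video.frames[i], video.frames[i + 1], subpixel=subpixel, window=window
            )
        except ValueError as exc:
            raise ValueError(f"frame pair ({i}, {i + 1}): {exc}") from exc
        pair_shift[i] = (dx, dy)
        peak_height[i] = peak
    cum_position = np.vstack([np.zeros((1, 2)), np.cumsum(pair_shift, axis=0)])
    return DisplacementTrace(
        fps=video.fps,
        pair_shift=pair_shift,
        cum_position=cum_position,
        peak_height=peak_height,
    )
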