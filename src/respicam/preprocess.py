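"""Raw-recording preprocessing.

Turns timestamped, possibly non-uniformly sampled, single-channel video into
uniformly resampled, merged and windowed frame stacks:

* :func:`resample_uniform` -- per-pixel linear interpolation to a uniform rate,
* :func:`to_grayscale` -- RGB to luma conversion,
* :func:`downscale` -- spatial block-mean downsampling,
* :func:`merge_views` -- stacking synchronized views into one image plane,
* :func:`split_segments` -- cutting a recording at acquisition gaps,
* :func:`sliding_windows` -- the 8 s / 1 s sliding-window decomposition.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import interp1d

from .config import GRAYSCALE_WEIGHTS

__all__ = [
    "FrameStack",
    "WindowView",
    "resample_uniform",
    "to_grayscale",
    "downscale",
    "merge_views",
    "split_segments",
    "sliding_windows",
    "expected_window_count",
]


@dataclass
class FrameStack:
    """A timestamped sequence of single-channel frames from one view.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)``.
    timestamps
        Strictly increasing acquisition times in seconds, one per frame.
    view_id
        Integer identifying the camera view (-1 for a merged stack).
    """

    frames: np.ndarray
    timestamps: np.ndarray
    view_id: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (n, rows, cols), got {self.frames.shape}")
        if self.timestamps.ndim != 1 or len(self.timestamps) != len(self.frames):
            raise ValueError("timestamps must be 1-D with one entry per frame")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if not np.all(np.isfinite(self.timestamps)):
            raise ValueError("timestamps must be finite")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def rate_hz(self, rtol: float = 1e-6) -> float:
        """Sampling rate of a uniformly sampled stack.

        Raises ``ValueError`` when the timestamps are not an arithmetic grid.
        """
        dts = np.diff(self.timestamps)
        if len(dts) == 0:
            raise ValueError("need at least 2 frames to define a rate")
        if not np.allclose(dts, dts[0], rtol=rtol, atol=1e-9):
            raise ValueError("timestamps are not uniformly spaced")
        return 1.0 / float(dts[0])


#: Alias: a merged multi-view stack is structurally a FrameStack (view_id=-1).
MergedStack = FrameStack


@dataclass
class WindowView:
    """One sliding-window slice of a uniformly sampled stack.

    ``index`` is 1-based; ``samples`` has shape ``(n, rows, cols)`` where
    ``n = window_s * rate`` (72 for 8 s at 9 Hz).
    """

    index: int
    samples: np.ndarray
    start_index: int
    start_s: float
    rate_hz: float

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def frame_indices(self) -> np.ndarray:
        return np.arange(self.start_index, self.start_index + self.n)


def resample_uniform(stack: FrameStack, target_rate: float) -> FrameStack:
    """Linearly interpolate every pixel's time series onto a uniform grid.

    The grid starts at the first input timestamp and is clipped to the
    recorded span (no extrapolation).
    """
    if stack.n_frames < 2:
        raise ValueError("resampling requires at least 2 frames")
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    t = stack.timestamps
    n_out = int(np.floor((t[-1] - t[0]) * target_rate + 1e-9)) + 1
    grid = t[0] + np.arange(n_out) / target_rate
    f = interp1d(t, stack.frames, axis=0, kind="linear", assume_sorted=True)
    return FrameStack(frames=f(grid), timestamps=grid, view_id=stack.view_id)


def to_grayscale(
    frames: np.ndarray,
    timestamps: np.ndarray | None = None,
    view_id: int = 0,
    weights: Sequence[float] = GRAYSCALE_WEIGHTS,
) -> FrameStack:
    """Convert RGB frames ``(n, rows, cols, 3)`` to a single-channel stack.

    Uses the ITU-R BT.601 luma weights by default (they sum to 1, so a pure
    white 255 frame maps to 255).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise ValueError(f"expected (n, rows, cols, 3) RGB frames, got {frames.shape}")
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,):
        raise ValueError("weights must have length 3")
    gray = frames @ w
    if timestamps is None:
        timestamps = np.arange(len(gray), dtype=float)
    return FrameStack(frames=gray, timestamps=timestamps, view_id=view_id)


def downscale(stack: FrameStack, factor: int) -> FrameStack:
    """Spatially downscale by block-mean over ``factor x factor`` blocks.

    Rows/cols not divisible by ``factor`` are cropped at the bottom/right
    edge before averaging.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return stack
    n, rows, cols = stack.frames.shape
    r, c = (rows // factor) * factor, (cols // factor) * factor
    cropped = stack.frames[:, :r, :c]
    blocks = cropped.reshape(n, r // factor, factor, c // factor, factor)
    return FrameStack(
        frames=blocks.mean(axis=(2, 4)), timestamps=stack.timestamps, view_id=stack.view_id
    )


def merge_views(stacks: Sequence[FrameStack]) -> MergedStack:
    """Concatenate synchronized equal-shape views along the row axis.

    Three 60x80 views become one 180x80 stack; a single view passes through
    unchanged. The inverse split (row blocks of the input height) recovers
    each view exactly.
    """
    if len(stacks) == 0:
        raise ValueError("need at least one stack")
    if len(stacks) == 1:
        return stacks[0]
    shape0 = stacks[0].frame_shape
    t0 = stacks[0].timestamps
    for s in stacks[1:]:
        if s.frame_shape != shape0:
            raise ValueError("all views must share the frame shape")
        if len(s.timestamps) != len(t0) or not np.allclose(s.timestamps, t0, atol=1e-9):
            raise ValueError("views must be temporally aligned")
    merged = np.concatenate([s.frames for s in stacks], axis=1)
    return FrameStack(frames=merged, timestamps=t0.copy(), view_id=-1)


def split_segments(stack: FrameStack, max_gap_s: float) -> list[FrameStack]:
    """Split a recording wherever consecutive timestamps differ by more than
    ``max_gap_s`` (windows must never bridge an acquisition gap)."""
    if stack.n_frames < 2:
        return [stack]
    gaps = np.flatnonzero(np.diff(stack.timestamps) > max_gap_s)
    if len(gaps) == 0:
        return [stack]
    out = []
    start = 0
    for g in gaps:
        out.append(
            FrameStack(
                frames=stack.frames[start : g + 1],
                timestamps=stack.timestamps[start : g + 1],
                view_id=stack.view_id,
            )
        )
        start = g + 1
    out.append(
        FrameStack(
            frames=stack.frames[start:], timestamps=stack.timestamps[start:], view_id=stack.view_id
        )
    )
    return out


def sliding_windows(
    stack: FrameStack, window_s: float = 8.0, slide_s: float = 1.0
) -> list[WindowView]:
    """Cut a uniformly sampled stack into overlapping windows.

    Window ``j`` (1-based) starts at sample ``(j-1) * slide_s * rate``. A
    recording shorter than one window yields an empty list.
    """
    rate = stack.rate_hz()
    n = int(round(window_s * rate))
    step = int(round(slide_s * rate))
    if n < 2 or step < 1:
        raise ValueError("window/slide too short for the sampling rate")
    windows = []
    j = 1
    for start in range(0, stack.n_frames - n + 1, step):
        windows.append(
            WindowView(
                index=j,
                samples=stack.frames[start : start + n],
                start_index=start,
                start_s=float(stack.timestamps[start]),
                rate_hz=rate,
            )
        )
        j += 1
    return windows


def expected_window_count(duration_s: float, window_s: float = 8.0, slide_s: float = 1.0) -> int:
    """Closed-form window count for gap-free uniform input."""
    if duration_s < window_s:
        return 0
    return int(np.floor((duration_s - window_s) / slide_s + 1e-9)) + 1
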