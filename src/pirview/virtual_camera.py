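"""The sensor grid as a virtual top-view camera.

Averaging each sensor's binary responses over a one-second window turns
the 20 binary channels into 20 grey "pixel values" in [0, 1]:

    p_ij(t) = (1 / (H + 1)) * sum_{u = t - H/2}^{t + H/2} s_ij(u)

for sampling rate H (Hz).  The weighted average of the cell indices with
the pixel values as weights estimates the person's position, and the sum
of all 20 pixel values measures the momentary strength of activity.

Two window modes are provided: ``centered`` is the formula above and is
acausal by H/2 samples; ``trailing`` averages the last H+1 samples ending
at t and is what the online fall detector consumes.  For odd H the
centered window is the nearest symmetric H+1 window with the extra sample
on the trailing (past) side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import SensorGrid
from .sensor_sim import SensorStream

__all__ = [
    "PixelFrame",
    "PixelSeries",
    "PositionEstimate",
    "pixelize",
    "pixelize_stream",
    "localize",
    "activity_strength",
    "position_to_cm",
]


@dataclass(frozen=True)
class PixelFrame:
    """The 20 pixel values of the virtual camera at one sample index."""

    t: int
    values: np.ndarray  # (n_rows, n_cols), entries in [0, 1]
    H: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("pixel values must lie in [0, 1]")


@dataclass(frozen=True)
class PositionEstimate:
    """Continuous person location in grid-index units, (x, y) in
    [1, n_rows] x [1, n_cols]; ``valid`` is False when no estimate exists
    (no active pixel and no previous position)."""

    x: float
    y: float
    valid: bool = True


@dataclass(frozen=True)
class PixelSeries:
    """Pixel frames for a range of sample indices.

    ``t`` maps each row of ``values`` (shape ``(n, n_sensors)``, row-major
    cells) back to the sample index of the underlying binary stream.
    """

    t: np.ndarray
    values: np.ndarray
    H: float
    mode: str
    grid_shape: tuple[int, int]

    def frame(self, k: int) -> PixelFrame:
        return PixelFrame(int(self.t[k]), self.values[k].reshape(self.grid_shape), self.H)

    def __len__(self) -> int:
        return len(self.t)


def _window_bounds(t: int, H: int, mode: str) -> tuple[int, int]:
    """Inclusive (lo, hi) sample bounds of the H+1 averaging window."""
    if mode == "centered":
        lo = t - (H + 1) // 2 if H % 2 else t - H // 2
        hi = t + H // 2
    elif mode == "trailing":
        lo, hi = t - H, t
    else:
        raise ValueError(f"window_mode must be 'centered' or 'trailing', got {mode!r}")
    return lo, hi


def pixelize(stream: SensorStream, t: int, window_mode: str = "centered") -> PixelFrame:
    """Pixel values at sample index ``t`` (0-based) of a binary stream."""
    H = int(round(stream.rate_H))
    lo, hi = _window_bounds(t, H, window_mode)
    if lo < 0 or hi >= stream.n_samples:
        raise ValueError(
            f"sample {t} out of range for {window_mode} window of {H + 1} samples: "
            f"needs samples {lo}..{hi}, stream has 0..{stream.n_samples - 1}"
        )
    vals = stream.frames[lo:hi + 1].astype(float).mean(axis=0) * (hi - lo + 1) / (H + 1)
    return PixelFrame(t=t, values=vals, H=stream.rate_H)


def pixelize_stream(stream: SensorStream, window_mode: str = "trailing") -> PixelSeries:
    """Pixel values at every admissible sample index, vectorized.

    Returns the series of frames for all ``t`` with a full H+1 window
    inside the stream.
    """
    H = int(round(stream.rate_H))
    flat = stream.flat.astype(float)
    T = flat.shape[0]
    lo0, hi0 = _window_bounds(0, H, window_mode)  # window offsets
    t_lo, t_hi = -lo0, T - 1 - hi0
    if t_hi < t_lo:
        raise ValueError(
            f"stream of {T} samples too short for a {H + 1}-sample window"
        )
    csum = np.vstack([np.zeros((1, flat.shape[1])), np.cumsum(flat, axis=0)])
    t = np.arange(t_lo, t_hi + 1)
    vals = (csum[t + hi0 + 1] - csum[t + lo0]) / (H + 1)
    return PixelSeries(t=t, values=vals, H=stream.rate_H, mode=window_mode,
                       grid_shape=(stream.grid.n_rows, stream.grid.n_cols))


def _frame_values(frame) -> np.ndarray:
    return frame.values if isinstance(frame, PixelFrame) else np.asarray(frame, dtype=float)


def localize(frame, previous: PositionEstimate | None = None) -> PositionEstimate:
    """Weighted-centroid position estimate from one pixel frame.

    The estimate is the average of the 1-based cell indices (i, j) weighted
    by the pixel values.  When every pixel is zero (no recent motion) the
    person is assumed to have stayed put: the previous estimate is returned
    unchanged, or an invalid estimate when there is none.
    """
    v = _frame_values(frame)
    total = v.sum()
    if total <= 0.0:
        if previous is not None and previous.valid:
            return previous
        return PositionEstimate(float("nan"), float("nan"), valid=False)
    i = np.arange(1, v.shape[0] + 1, dtype=float)
    j = np.arange(1, v.shape[1] + 1, dtype=float)
    x = float((v.sum(axis=1) * i).sum() / total)
    y = float((v.sum(axis=0) * j).sum() / total)
    return PositionEstimate(x, y, valid=True)


def activity_strength(frame) -> float:
    """Sum of the 20 pixel values: the momentary strength of activity,
    in [0, n_sensors]."""
    return float(_frame_values(frame).sum())


def position_to_cm(pos: PositionEstimate, grid: SensorGrid) -> tuple[float, float]:
    """Convert a grid-index position estimate to floor cm."""
    x, y = grid.index_to_cm(np.array([pos.x, pos.y]))
    return float(x), float(y)
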