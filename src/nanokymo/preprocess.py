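"""Raw-stack preprocessing: transverse collapse, relative-contrast
normalization and separable moving-average background suppression.

The normalization step converts intensities to relative contrast,

    Ibar(x, t) = (I(x, t) - <I(x, t)>_t) / <I(x, t)>_t,

where the time average is taken per position over the full stack, and the
high-pass step subtracts a low-pass version of Ibar built from two
normalized sliding windows (default 200 frames along time, then 200 pixels
along position).  Edge windows are truncated and renormalized so the
filter keeps its unit sum everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import ChannelGeometry, Kymograph

__all__ = [
    "RawFrameStack",
    "collapse_transverse",
    "normalize_stack",
    "lowpass_subtract",
    "preprocess_stack",
]


@dataclass
class RawFrameStack:
    """Raw intensity stack: time x position, or time x position x transverse."""

    values: np.ndarray
    dt: float = 0.005
    pixel_size_nm: float = 27.4

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim not in (2, 3):
            raise ValueError("stack must be 2-D or 3-D")


def collapse_transverse(stack: RawFrameStack) -> RawFrameStack:
    """Average over the transverse (third) axis; 2-D stacks pass through."""
    if stack.values.ndim == 2:
        return stack
    return RawFrameStack(values=stack.values.mean(axis=2),
                         dt=stack.dt, pixel_size_nm=stack.pixel_size_nm)


def normalize_stack(stack: RawFrameStack) -> np.ndarray:
    """Relative-contrast normalization against the per-position time mean."""
    v = stack.values
    if v.ndim != 2:
        raise ValueError("normalize_stack expects a 2-D stack")
    mean = v.mean(axis=0, keepdims=True)
    if np.any(mean <= 0):
        raise ValueError("per-position time mean must be positive")
    return (v - mean) / mean


def _moving_average(a: np.ndarray, window: int, axis: int) -> np.ndarray:
    """Centered moving average with truncated, renormalized edge windows."""
    if window < 1:
        raise ValueError("window must be >= 1")
    a = np.moveaxis(a, axis, 0)
    n = a.shape[0]
    w = min(window, n)
    left = w // 2
    right = w - 1 - left
    # cumulative-sum trick: sums over [i-left, i+right] clipped to range
    c = np.concatenate([np.zeros((1,) + a.shape[1:]), np.cumsum(a, axis=0)])
    hi = np.minimum(np.arange(n) + right + 1, n)
    lo = np.maximum(np.arange(n) - left, 0)
    sums = c[hi] - c[lo]
    counts = (hi - lo).astype(np.float64).reshape((-1,) + (1,) * (a.ndim - 1))
    return np.moveaxis(sums / counts, 0, axis)


def lowpass_subtract(kymo: np.ndarray, window_time: int = 200,
                     window_space: int = 200) -> np.ndarray:
    """Subtract the separable moving-average low-pass (time axis first)."""
    kymo = np.asarray(kymo, dtype=np.float64)
    if kymo.ndim != 2:
        raise ValueError("expected a 2-D normalized kymograph")
    if kymo.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    low = _moving_average(kymo, window_time, axis=0)
    low = _moving_average(low, window_space, axis=1)
    return kymo - low


def preprocess_stack(stack: RawFrameStack, geometry: ChannelGeometry,
                     window_time: int = 200, window_space: int = 200) -> Kymograph:
    """Full pipeline: collapse -> normalize -> high-pass -> Kymograph."""
    flat = collapse_transverse(stack)
    norm = normalize_stack(flat)
    values = lowpass_subtract(norm, window_time, window_space)
    return Kymograph(values=values, geometry=geometry, dt=stack.dt,
                     provenance="measured")
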