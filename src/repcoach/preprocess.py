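"""Sensor denoising: the causal moving-average filter.

Smoothing is causal (trailing window with warm-up over the samples seen so
far) because feedback must be produced in real time — a centered window
would require future samples.  A window of ``T`` samples at rate ``f`` Hz
spans ``T * 1000 / f`` ms of signal (e.g. 10 samples at 50 Hz = 200 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FilterConfig", "moving_average", "window_span_ms"]


@dataclass
class FilterConfig:
    """Denoise window in samples (``T_denoise``); 1 disables smoothing."""

    window: int = 1

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("denoise window must be >= 1")


def moving_average(signal, window: int) -> np.ndarray:
    """Causal moving average over the last ``min(window, t+1)`` samples.

    Accepts a 1-D sequence or an (N, k) array of k-vectors; each axis is
    filtered independently.  Output has the same shape as the input.
    """
    if window < 1:
        raise ValueError("denoise window must be >= 1")
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("signal must be non-empty")
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    c = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    t = np.arange(n)
    lo = np.maximum(t - window + 1, 0)
    out = (c[t + 1] - c[lo]) / (t + 1 - lo)[:, None]
    return out[:, 0] if squeeze else out


def window_span_ms(window: int, rate_hz: float) -> float:
    """Temporal span of a ``window``-sample filter at ``rate_hz``."""
    if window < 1:
        raise ValueError("denoise window must be >= 1")
    return window * 1000.0 / rate_hz
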