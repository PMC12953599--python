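"""Conversion of wavelength-shift traces into input-layer currents.

Each of the 21 sensor channels is split into its positive (compression,
SA1-like) and negative (stretch, SA2-like) rectified components, which are
compressed logarithmically and injected as external currents into two
dedicated input-layer neurons per sensor (42 input neurons total).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EncoderParams", "rectify_split", "log_transform", "encode"]


@dataclass(frozen=True)
class EncoderParams:
    """Logarithmic compression parameters.

    ``LF`` (nm) sets the degree of non-linearity, ``gain`` (pA) the current
    scale: ``f(x) = gain * ln(1 + x/LF)``.  Defaults are calibrated so a
    mid-range indentation (~2 N peak force) drives its nearest input
    neurons in the 30-80 Hz range.  ``positive_only`` silences the
    negative-component neurons (used to probe the functional role of the
    SA2-like channels).
    """

    LF: float = 0.5
    gain: float = 50.0
    positive_only: bool = False

    def __post_init__(self):
        if self.LF <= 0 or self.gain <= 0:
            raise ValueError("LF and gain must be > 0")


def rectify_split(delta_lambda: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a wavelength-shift trace into ReLU(+x) and ReLU(-x) parts."""
    x = np.asarray(delta_lambda, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite wavelength-shift trace")
    return np.maximum(x, 0.0), np.maximum(-x, 0.0)


def log_transform(x, params: EncoderParams | None = None) -> np.ndarray:
    """Map a rectified shift (nm) to an input current (pA).

    Strictly increasing and concave with f(0)=0: ``gain*ln(1 + x/LF)``.
    """
    p = params or EncoderParams()
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("log_transform requires x >= 0")
    return p.gain * np.log1p(x / p.LF)


def channel_map(n_sensors: int = 21) -> np.ndarray:
    """Sensor -> (positive neuron id, negative neuron id).

    Positive-component neurons occupy ids [0, n_sensors), negative ones
    [n_sensors, 2*n_sensors).
    """
    return np.stack([np.arange(n_sensors), np.arange(n_sensors) + n_sensors], axis=1)


def encode(
    t_ms: np.ndarray,
    delta_lambda: np.ndarray,
    params: EncoderParams | None = None,
    dt: float = 1.0,
    duration: float | None = None,
) -> np.ndarray:
    """Encode a (T, 21) wavelength-shift record into (n_steps, 42) currents.

    Sensor traces sampled on ``t_ms`` (arbitrary rate) are resampled to the
    simulation grid by zero-order hold.  Output column order follows
    :func:`channel_map`.
    """
    p = params or EncoderParams()
    t_ms = np.asarray(t_ms, dtype=float)
    x = np.asarray(delta_lambda, dtype=float)
    if x.ndim != 2:
        raise ValueError("delta_lambda must be 2-D (time x channels)")
    n_sensors = x.shape[1]
    duration = float(t_ms[-1] + (t_ms[1] - t_ms[0] if len(t_ms) > 1 else dt)) if duration is None else duration
    n_steps = int(round(duration / dt))
    grid = np.arange(n_steps) * dt
    # zero-order hold: value of the last sample at or before each grid point
    idx = np.clip(np.searchsorted(t_ms, grid, side="right") - 1, 0, len(t_ms) - 1)
    held = x[idx]
    pos, neg = rectify_split(held)
    if p.positive_only:
        neg = np.zeros_like(neg)
    out = np.empty((n_steps, 2 * n_sensors))
    out[:, :n_sensors] = log_transform(pos, p)
    out[:, n_sensors:] = log_transform(neg, p)
    return out
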