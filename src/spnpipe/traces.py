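"""Fluorescence-trace processing: neuropil subtraction, ΔF/F, smoothing.

Each imaged cell is paired with a neighbouring background source whose trace
is subtracted from the cell trace to remove shared neuropil contamination.
ΔF/F is then (F − F0)/F0 with F0 a low percentile of the corrected trace,
and traces are smoothed with a 150 ms moving average before peak detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import oaconvolve


@dataclass
class TraceMatrix:
    """Per-neuron fluorescence time series sharing one frame clock.

    ``raw`` and ``background`` are (n_neurons, n_frames) arrays in arbitrary
    fluorescence units; ``dff`` is filled by :func:`process_traces` and holds
    the smoothed, neuropil-corrected ΔF/F traces.  Raw traces are never
    mutated.
    """

    raw: np.ndarray
    background: np.ndarray
    frame_rate: float
    neuron_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    dff: np.ndarray | None = None
    f0: np.ndarray | None = None

    def __post_init__(self):
        self.raw = np.atleast_2d(np.asarray(self.raw, dtype=float))
        self.background = np.atleast_2d(np.asarray(self.background, dtype=float))
        if self.raw.shape != self.background.shape:
            raise ValueError("raw and background shapes differ")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.raw.shape[0])

    @property
    def n_neurons(self) -> int:
        return self.raw.shape[0]

    @property
    def n_frames(self) -> int:
        return self.raw.shape[1]


def subtract_neuropil(cell: np.ndarray, background: np.ndarray,
                      weight: float = 1.0) -> np.ndarray:
    """Remove shared neuropil signal: ``cell − weight × background``."""
    cell = np.asarray(cell, dtype=float)
    background = np.asarray(background, dtype=float)
    if cell.shape != background.shape:
        raise ValueError("cell and background traces must have equal shapes")
    if not 0.0 <= weight <= 1.0:
        raise ValueError("neuropil weight must lie in [0, 1]")
    return cell - weight * background


def compute_dff(
    trace: np.ndarray,
    baseline_method: str = "percentile",
    percentile: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """ΔF/F = (F − F0)/F0, per neuron.

    ``baseline_method`` is ``"percentile"`` (F0 = the given percentile of
    each trace, default 10th — robust to sparse transients) or ``"mean"``.
    Returns ``(dff, f0)``.  Raises if any F0 is non-positive, naming the
    offending neuron row.
    """
    trace = np.atleast_2d(np.asarray(trace, dtype=float))
    if baseline_method == "percentile":
        f0 = np.percentile(trace, percentile, axis=1)
    elif baseline_method == "mean":
        f0 = trace.mean(axis=1)
    else:
        raise ValueError(f"unknown baseline_method {baseline_method!r}")
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        raise ValueError(f"non-positive baseline F0 for neuron row(s) {bad.tolist()}")
    return (trace - f0[:, None]) / f0[:, None], f0


def smoothing_window_frames(window_s: float, frame_rate: float) -> int:
    """Window length in frames, rounding half up (150 ms at 30 Hz -> 5)."""
    return int(np.floor(window_s * frame_rate + 0.5))


def smooth(trace: np.ndarray, window_s: float = 0.150,
           frame_rate: float = 30.0) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges.

    Output length equals input length; the mean of the trace is preserved up
    to edge effects.
    """
    if window_s < 1.0 / frame_rate:
        raise ValueError("smoothing window shorter than one frame")
    x = np.asarray(trace, dtype=float)
    squeeze = x.ndim == 1
    x2 = np.atleast_2d(x)
    w = smoothing_window_frames(window_s, frame_rate)
    if w <= 1:
        return x.copy()
    kernel = np.ones(w)
    num = oaconvolve(x2, kernel[None, :], mode="same", axes=1)
    counts = np.convolve(np.ones(x2.shape[1]), kernel, mode="same")
    out = num / counts[None, :]
    return out[0] if squeeze else out


def process_traces(
    traces: TraceMatrix,
    neuropil_weight: float = 1.0,
    smooth_window_s: float = 0.150,
    baseline_percentile: float = 10.0,
) -> TraceMatrix:
    """Full processing chain: subtract neuropil, ΔF/F, smooth.

    Fills ``traces.dff`` (smoothed ΔF/F) and ``traces.f0`` in place and
    returns the same object.
    """
    corrected = subtract_neuropil(traces.raw, traces.background, neuropil_weight)
    dff, f0 = compute_dff(corrected, percentile=baseline_percentile)
    traces.dff = smooth(dff, smooth_window_s, traces.frame_rate)
    traces.f0 = f0
    return traces
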