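"""Ca²⁺ transient detection on smoothed ΔF/F traces.

A local maximum is a transient when, relative to that trace's robust baseline
statistics (μ = median, σ = 1.4826 × MAD):

* its height above baseline is at least ``k_sd`` σ (default 5),
* its topographic prominence is at least ``k_sd`` σ,
* its width at half prominence (linear interpolation) is at least
  ``min_width_s`` (default 140 ms).

The criteria are intentionally stringent: they exclude events not clearly
resolved from baseline fluorescence at the cost of underestimating transient
frequency.  Peaks closer than one smoothing window are merged to the larger
(ties broken toward the earlier peak).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences, peak_widths

from .behavior import BehaviorSegments
from .params import DetectionCriteria
from .traces import TraceMatrix, smoothing_window_frames

EVENT_COLUMNS = ["neuron_id", "peak_time", "amplitude", "prominence",
                 "width_half_prom"]


def estimate_baseline_stats(dff: np.ndarray) -> tuple[float, float]:
    """Robust baseline mean and SD of a ΔF/F trace.

    μ is the median; σ is 1.4826 × the median absolute deviation, which is
    insensitive to the sparse transients riding on the baseline.
    """
    dff = np.asarray(dff, dtype=float)
    if dff.size < 100:
        raise ValueError("trace too short for baseline statistics (<100 frames)")
    mu = float(np.median(dff))
    sigma = float(1.4826 * np.median(np.abs(dff - mu)))
    if sigma == 0.0:
        raise ValueError("degenerate trace: zero baseline variability")
    return mu, sigma


def _merge_close_peaks(peaks: np.ndarray, values: np.ndarray,
                       min_sep: int) -> np.ndarray:
    """Keep the larger of any two peaks closer than ``min_sep`` frames.

    Greedy by height; ties broken toward the earlier peak.  Returns a boolean
    keep-mask aligned with ``peaks``.
    """
    order = np.lexsort((peaks, -values))  # height desc, then earlier first
    keep = np.zeros(peaks.size, dtype=bool)
    taken: list[int] = []
    for j in order:
        p = peaks[j]
        if all(abs(p - q) >= min_sep for q in taken):
            keep[j] = True
            taken.append(p)
    return keep


def detect_transients(
    dff: np.ndarray,
    frame_rate: float,
    criteria: DetectionCriteria | None = None,
    neuron_id: int = 0,
) -> pd.DataFrame:
    """Detect transients on one smoothed ΔF/F trace.

    Returns an event table with peak time (s), amplitude (peak ΔF/F minus
    baseline μ), prominence, and width at half prominence (s), sorted by
    peak time.  Deterministic: identical traces give identical tables.
    """
    crit = criteria or DetectionCriteria()
    crit.validate()
    dff = np.asarray(dff, dtype=float)
    mu, sigma = estimate_baseline_stats(dff)

    peaks, props = find_peaks(dff, height=mu + crit.k_sd * sigma,
                              prominence=crit.k_sd * sigma)
    if peaks.size == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    prom_data = (props["prominences"], props["left_bases"], props["right_bases"])
    widths = peak_widths(dff, peaks, rel_height=0.5, prominence_data=prom_data)[0]
    widths_s = widths / frame_rate
    ok = widths_s >= crit.min_width_s
    peaks, widths_s = peaks[ok], widths_s[ok]
    proms = props["prominences"][ok]
    if peaks.size:
        min_sep = smoothing_window_frames(crit.smooth_window_s, frame_rate)
        keep = _merge_close_peaks(peaks, dff[peaks], min_sep)
        peaks, widths_s, proms = peaks[keep], widths_s[keep], proms[keep]

    out = pd.DataFrame({
        "neuron_id": neuron_id,
        "peak_time": peaks / frame_rate,
        "amplitude": dff[peaks] - mu,
        "prominence": proms,
        "width_half_prom": widths_s,
    })
    return out.sort_values("peak_time", ignore_index=True)


def detect_all(traces: TraceMatrix,
               criteria: DetectionCriteria | None = None) -> pd.DataFrame:
    """Detect transients for every neuron in a processed TraceMatrix.

    Neurons with degenerate (constant) traces contribute no events.
    """
    if traces.dff is None:
        raise ValueError("traces not processed: run process_traces first")
    tables = []
    for i in range(traces.n_neurons):
        try:
            tables.append(detect_transients(traces.dff[i], traces.frame_rate,
                                            criteria,
                                            neuron_id=int(traces.neuron_ids[i])))
        except ValueError:
            continue
    tables = [t for t in tables if len(t)]
    if not tables:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(tables, ignore_index=True)


def flag_active(
    events: pd.DataFrame,
    neuron_ids: np.ndarray,
    segments: BehaviorSegments | None = None,
    scope: str = "locomotion",
) -> pd.Series:
    """Per-neuron activity flag.

    ``scope="session"``: active means at least one detected transient
    anywhere.  ``scope="locomotion"`` (default for ensemble metrics): active
    means at least one transient whose peak falls inside a movement bout
    (refined onset/offset).
    """
    neuron_ids = np.asarray(neuron_ids)
    flags = pd.Series(False, index=neuron_ids, name=f"active_{scope}")
    if len(events) == 0:
        return flags
    if scope == "session":
        flags.loc[np.intersect1d(events.neuron_id.unique(), neuron_ids)] = True
        return flags
    if scope != "locomotion":
        raise ValueError(f"unknown scope {scope!r}")
    if segments is None or len(segments.bouts) == 0:
        warnings.warn("locomotion scope with no bouts: all neurons inactive",
                      stacklevel=2)
        return flags
    in_bout = events_in_bouts(events, segments)
    active = events.loc[in_bout, "neuron_id"].unique()
    flags.loc[np.intersect1d(active, neuron_ids)] = True
    return flags


def events_in_bouts(events: pd.DataFrame, segments: BehaviorSegments) -> np.ndarray:
    """Boolean mask over event rows whose peak lies inside any bout."""
    mask = np.zeros(len(events), dtype=bool)
    t = events.peak_time.to_numpy()
    for b in segments.bouts.itertuples():
        mask |= (t >= b.onset_s) & (t < b.offset_s)
    return mask


def events_in_intervals(events: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask over event rows whose peak lies inside [start_s, end_s)."""
    mask = np.zeros(len(events), dtype=bool)
    t = events.peak_time.to_numpy()
    for r in intervals.itertuples():
        mask |= (t >= r.start_s) & (t < r.end_s)
    return mask
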