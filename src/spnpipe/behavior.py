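"""Treadmill-behavior segmentation.

Derives a velocity trace on the imaging frame clock from rotary-encoder
positions, then segments the session into immobility intervals and movement
bouts:

* immobility — absolute velocity below 0.2 cm/s, trimmed by 0.5 s guard bands
  after the downward and before the upward threshold crossing, kept when the
  trimmed interval lasts at least 4 s;
* movement bout — absolute velocity above 0.4 cm/s for at least 4 s, flanked
  by immobility intervals, with onset/offset refined to the first/last sample
  at least two standard deviations away from the mean immobile velocity.

All intervals are half-open ``[start, end)`` in seconds on the frame grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import SegmentationParams

BOUT_COLUMNS = [
    "onset_s",
    "offset_s",
    "candidate_start_s",
    "candidate_end_s",
    "duration_s",
    "peak_velocity",
    "distance_cm",
]


@dataclass
class VelocityTrace:
    """Signed treadmill velocity sampled uniformly at the imaging frame rate."""

    velocity: np.ndarray  # cm/s, signed
    frame_rate: float  # Hz
    #: intervals [(on_s, off_s), ...] the generator drove above the bout
    #: threshold; empty for real (encoder-derived) data
    true_bout_windows: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.velocity.size

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class BehaviorSegments:
    """Immobility intervals and movement bouts for one session."""

    immobility: pd.DataFrame  # columns: start_s, end_s
    bouts: pd.DataFrame  # columns: BOUT_COLUMNS
    immobile_mean: float = np.nan  # cm/s (signed mean over immobile samples)
    immobile_sd: float = np.nan

    @property
    def total_bout_time(self) -> float:
        if len(self.bouts) == 0:
            return 0.0
        return float((self.bouts.offset_s - self.bouts.onset_s).sum())

    @property
    def total_immobility_time(self) -> float:
        if len(self.immobility) == 0:
            return 0.0
        return float((self.immobility.end_s - self.immobility.start_s).sum())


def velocity_from_encoder(
    ticks: np.ndarray,
    timestamps: np.ndarray,
    wheel_circumference: float,
    ticks_per_rev: int,
    frame_rate: float,
) -> VelocityTrace:
    """Convert raw encoder counts to a velocity trace on the frame clock.

    Unwraps counter rollover (counts live in ``[0, ticks_per_rev)``), converts
    to linear distance, differentiates, and resamples onto a uniform grid at
    ``frame_rate``.
    """
    ticks = np.asarray(ticks, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    if ticks.shape != timestamps.shape or ticks.ndim != 1:
        raise ValueError("ticks and timestamps must be matching 1-D arrays")
    if np.any(np.diff(timestamps) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    d = np.diff(ticks)
    d = np.where(d > ticks_per_rev / 2, d - ticks_per_rev, d)
    d = np.where(d < -ticks_per_rev / 2, d + ticks_per_rev, d)
    position_cm = np.concatenate([[0.0], np.cumsum(d)]) * (
        wheel_circumference / ticks_per_rev
    )
    v_raw = np.gradient(position_cm, timestamps)
    t_frames = np.arange(0.0, timestamps[-1] - timestamps[0] + 0.5 / frame_rate,
                         1.0 / frame_rate) + timestamps[0]
    t_frames = t_frames[t_frames <= timestamps[-1] + 1e-9]
    v = np.interp(t_frames, timestamps, v_raw)
    return VelocityTrace(velocity=v, frame_rate=frame_rate)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def find_immobility(
    v: VelocityTrace, params: SegmentationParams | None = None
) -> pd.DataFrame:
    """Immobility intervals: |v| below threshold, guard-trimmed, >= 4 s.

    The guard band is only trimmed at ends produced by an actual threshold
    crossing; a run that starts at the first frame or ends at the last frame
    of the session keeps that edge.
    """
    p = params or SegmentationParams()
    n = v.n_frames
    guard = int(round(p.guard_s * v.frame_rate))
    min_len = p.min_immobility_s * v.frame_rate
    rows = []
    for i0, i1 in _runs(np.abs(v.velocity) < p.immobile_speed):
        j0 = i0 + guard if i0 > 0 else i0
        j1 = i1 - guard if i1 < n else i1
        if j1 - j0 >= min_len:
            rows.append((j0 / v.frame_rate, j1 / v.frame_rate))
    return pd.DataFrame(rows, columns=["start_s", "end_s"])


def immobile_stats(v: VelocityTrace, immobility: pd.DataFrame) -> tuple[float, float]:
    """Mean and SD of the signed velocity over all immobility samples."""
    fr = v.frame_rate
    samples = [
        v.velocity[int(round(r.start_s * fr)) : int(round(r.end_s * fr))]
        for r in immobility.itertuples()
    ]
    if not samples:
        return np.nan, np.nan
    cat = np.concatenate(samples)
    return float(cat.mean()), float(cat.std())


def find_bouts(
    v: VelocityTrace,
    immobility: pd.DataFrame,
    params: SegmentationParams | None = None,
) -> BehaviorSegments:
    """Movement bouts with refined onsets and offsets.

    Candidates are maximal runs with |v| above the bout threshold lasting at
    least ``min_bout_s``.  A candidate becomes a bout when an immobility
    interval of at least ``flank_s`` ends within ``gap_tol_s`` before its
    start and another begins within ``gap_tol_s`` after its end.  The onset is
    then pushed back from the candidate start through the contiguous run of
    samples more than ``onset_k_sd`` immobile-velocity SDs away from the mean
    immobile velocity (bounded by the preceding immobility interval), and the
    offset forward symmetrically.
    """
    p = params or SegmentationParams()
    fr = v.frame_rate
    n = v.n_frames
    mean_imm, sd_imm = immobile_stats(v, immobility)
    empty = pd.DataFrame({c: pd.Series(dtype=float) for c in BOUT_COLUMNS})
    if len(immobility) == 0 or not np.isfinite(sd_imm):
        warnings.warn("no immobility in session; zero bouts", stacklevel=2)
        return BehaviorSegments(immobility=immobility, bouts=empty,
                                immobile_mean=mean_imm, immobile_sd=sd_imm)

    imm_start = immobility.start_s.to_numpy()
    imm_end = immobility.end_s.to_numpy()
    imm_dur = imm_end - imm_start
    exceed = np.abs(v.velocity - mean_imm) > p.onset_k_sd * sd_imm

    rows = []
    for i0, i1 in _runs(np.abs(v.velocity) > p.bout_speed):
        if i1 - i0 < p.min_bout_s * fr:
            continue
        t0, t1 = i0 / fr, i1 / fr
        # preceding immobility interval
        prev = np.flatnonzero(imm_end <= t0 + 1e-9)
        nxt = np.flatnonzero(imm_start >= t1 - 1e-9)
        if prev.size == 0 or nxt.size == 0:
            continue
        ip, iq = prev[-1], nxt[0]
        if t0 - imm_end[ip] > p.gap_tol_s or imm_start[iq] - t1 > p.gap_tol_s:
            continue
        if imm_dur[ip] < p.flank_s or imm_dur[iq] < p.flank_s:
            continue
        # onset refinement, bounded by the preceding immobility end
        lo = int(round(imm_end[ip] * fr))
        j = i0
        if exceed[j]:
            while j - 1 >= lo and exceed[j - 1]:
                j -= 1
        # offset refinement, bounded by the following immobility start
        hi = int(round(imm_start[iq] * fr))
        k = i1 - 1
        if exceed[k]:
            while k + 1 < min(hi, n) and exceed[k + 1]:
                k += 1
        onset, offset = j / fr, (k + 1) / fr
        seg = np.abs(v.velocity[j : k + 1])
        rows.append((
            onset,
            offset,
            t0,
            t1,
            offset - onset,
            float(seg.max()),
            float(np.trapezoid(seg, dx=1.0 / fr)),
        ))
    bouts = pd.DataFrame(rows, columns=BOUT_COLUMNS) if rows else empty
    return BehaviorSegments(immobility=immobility, bouts=bouts,
                            immobile_mean=mean_imm, immobile_sd=sd_imm)


def segment_session(
    v: VelocityTrace, params: SegmentationParams | None = None
) -> BehaviorSegments:
    """Run immobility and bout segmentation in one call."""
    p = params or SegmentationParams()
    return find_bouts(v, find_immobility(v, p), p)


def session_distance(
    v: VelocityTrace,
    scope: str = "all",
    bouts: pd.DataFrame | None = None,
) -> float:
    """Distance travelled (cm): trapezoidal integral of |v| over the scope."""
    speed = np.abs(v.velocity)
    dt = 1.0 / v.frame_rate
    if scope == "all":
        return float(np.trapezoid(speed, dx=dt))
    if scope == "bouts":
        if bouts is None or len(bouts) == 0:
            return 0.0
        fr = v.frame_rate
        total = 0.0
        for r in bouts.itertuples():
            i0 = int(round(r.onset_s * fr))
            i1 = int(round(r.offset_s * fr))
            total += float(np.trapezoid(speed[i0:i1], dx=dt))
        return total
    raise ValueError(f"unknown scope {scope!r}")


def cumulative_distance(v: VelocityTrace) -> np.ndarray:
    """Cumulative trapezoidal |v| integral at each frame time (cm)."""
    speed = np.abs(v.velocity)
    out = np.zeros(v.n_frames)
    if v.n_frames > 1:
        steps = 0.5 * (speed[1:] + speed[:-1]) / v.frame_rate
        out[1:] = np.cumsum(steps)
    return out
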