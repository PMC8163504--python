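"""Per-FOV ensemble metrics.

Quantities reported per field of view and session: ensemble sizes (% of
imaged dSPNs / iSPNs with transients during locomotion), pathway bias
indices, state-dependent transient frequencies and amplitudes,
velocity-resolved activity, peri-bout rate curves, cumulative ensemble
recruitment with distance travelled, and the inclusion QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BehaviorSegments, VelocityTrace, cumulative_distance
from .detect import events_in_bouts, events_in_intervals

SPN_CLASSES = ("dSPN", "iSPN")


@dataclass
class FovMetrics:
    """Summary of one FOV × session × condition."""

    condition: str = "baseline"
    scope: str = "locomotion"
    n_imaged: dict = field(default_factory=dict)
    n_active: dict = field(default_factory=dict)
    ensemble_size: dict = field(default_factory=dict)  # % per class
    freq_moving: dict = field(default_factory=dict)  # events/s per active neuron
    freq_immobile: dict = field(default_factory=dict)
    amp_mean: dict = field(default_factory=dict)  # ΔF/F per class
    bias_size: float = np.nan
    bias_freq: float = np.nan
    bias_amp: float = np.nan
    distance_cm: float = np.nan
    qc_pass: bool = False

    def to_row(self) -> dict:
        row = {"condition": self.condition, "scope": self.scope,
               "bias_size": self.bias_size, "bias_freq": self.bias_freq,
               "bias_amp": self.bias_amp, "distance_cm": self.distance_cm,
               "qc_pass": self.qc_pass}
        for c in SPN_CLASSES:
            row[f"n_imaged_{c}"] = self.n_imaged.get(c, 0)
            row[f"n_active_{c}"] = self.n_active.get(c, 0)
            row[f"ensemble_size_{c}"] = self.ensemble_size.get(c, np.nan)
            row[f"freq_moving_{c}"] = self.freq_moving.get(c, np.nan)
            row[f"freq_immobile_{c}"] = self.freq_immobile.get(c, np.nan)
            row[f"amp_mean_{c}"] = self.amp_mean.get(c, np.nan)
        return row


def ensemble_size(classes: np.ndarray, active: np.ndarray) -> dict:
    """Percent of imaged neurons of each SPN class that are active.

    A class with zero imaged neurons gets NaN (undefined, not zero).
    """
    classes = np.asarray(classes)
    active = np.asarray(active, dtype=bool)
    out = {}
    for c in SPN_CLASSES:
        m = classes == c
        out[c] = 100.0 * active[m].mean() if m.any() else np.nan
    return out


def bias_index(x_d: float, x_i: float) -> float:
    """Pathway bias: (dSPN − iSPN) / (dSPN + iSPN), in [−1, 1].

    Positive values indicate direct-pathway dominance.  NaN when both inputs
    are zero or either is missing.
    """
    if x_d < 0 or x_i < 0:
        raise ValueError("bias_index inputs must be non-negative")
    s = x_d + x_i
    if not np.isfinite(s) or s == 0:
        return np.nan
    return (x_d - x_i) / s


def state_frequencies(
    events: pd.DataFrame,
    segments: BehaviorSegments,
    neuron_ids: np.ndarray,
) -> pd.DataFrame:
    """Per-neuron transient frequency while moving and while immobile.

    Moving frequency = events with peaks inside bouts / total bout time;
    immobile frequency uses immobility intervals.  A state with zero total
    time yields NaN for every neuron.
    """
    neuron_ids = np.asarray(neuron_ids)
    t_move = segments.total_bout_time
    t_imm = segments.total_immobility_time
    out = pd.DataFrame(index=neuron_ids,
                       data={"freq_moving": np.nan, "freq_immobile": np.nan})
    if len(events):
        move_counts = events.loc[events_in_bouts(events, segments)] \
            .groupby("neuron_id").size()
        imm_counts = events.loc[events_in_intervals(events, segments.immobility)] \
            .groupby("neuron_id").size()
    else:
        move_counts = imm_counts = pd.Series(dtype=float)
    if t_move > 0:
        out["freq_moving"] = 0.0
        common = move_counts.index.intersection(out.index)
        out.loc[common, "freq_moving"] = move_counts.loc[common] / t_move
    if t_imm > 0:
        out["freq_immobile"] = 0.0
        common = imm_counts.index.intersection(out.index)
        out.loc[common, "freq_immobile"] = imm_counts.loc[common] / t_imm
    return out


def _velocity_at(events: pd.DataFrame, v: VelocityTrace) -> np.ndarray:
    idx = np.clip(np.round(events.peak_time.to_numpy() * v.frame_rate).astype(int),
                  0, v.n_frames - 1)
    return np.abs(v.velocity[idx])


def frequency_vs_velocity(
    events: pd.DataFrame,
    v: VelocityTrace,
    n_neurons: int,
    vel_bin: float = 0.4,
) -> pd.DataFrame:
    """Occupancy-normalised event rate per velocity bin.

    Bins are [k·vel_bin, (k+1)·vel_bin) on |v|.  Rate = events whose
    instantaneous velocity falls in the bin / (n_neurons × time spent in the
    bin).  Bins with zero occupancy get NaN (undefined, not zero); the
    identity Σ_b rate_b × time_b × n = total events holds over occupied bins.
    """
    if n_neurons <= 0:
        raise ValueError("n_neurons must be positive")
    speed = np.abs(v.velocity)
    nbins = int(np.floor(speed.max() / vel_bin)) + 1
    dt = 1.0 / v.frame_rate
    time_per_bin = np.bincount(
        np.minimum((speed / vel_bin).astype(int), nbins - 1), minlength=nbins
    ) * dt
    counts = np.zeros(nbins)
    if len(events):
        ev_bins = np.minimum((_velocity_at(events, v) / vel_bin).astype(int),
                             nbins - 1)
        counts = np.bincount(ev_bins, minlength=nbins).astype(float)
    rate = np.full(nbins, np.nan)
    occ = time_per_bin > 0
    rate[occ] = counts[occ] / (n_neurons * time_per_bin[occ])
    return pd.DataFrame({
        "vel_lo": np.arange(nbins) * vel_bin,
        "vel_hi": (np.arange(nbins) + 1) * vel_bin,
        "time_s": time_per_bin,
        "n_events": counts,
        "rate": rate,
    })


def fraction_active_vs_velocity(
    events: pd.DataFrame,
    classes: np.ndarray,
    neuron_ids: np.ndarray,
    v: VelocityTrace,
    time_bin: float = 0.2,
    vel_bin: float = 0.4,
) -> pd.DataFrame:
    """Mean % of imaged neurons of each class active per velocity bin.

    Tiles the session into ``time_bin`` windows, computes the fraction of
    each imaged class with at least one event peak per window, groups the
    windows by their mean |velocity| into ``vel_bin`` bins, and averages.
    """
    classes = np.asarray(classes)
    neuron_ids = np.asarray(neuron_ids)
    frames_per = int(round(time_bin * v.frame_rate))
    n_windows = v.n_frames // frames_per
    if n_windows == 0:
        return pd.DataFrame(columns=["vel_lo", "vel_hi", *SPN_CLASSES])
    speed = np.abs(v.velocity[: n_windows * frames_per])
    win_speed = speed.reshape(n_windows, frames_per).mean(axis=1)
    class_of = pd.Series(classes, index=neuron_ids)
    n_imaged = {c: int((classes == c).sum()) for c in SPN_CLASSES}

    frac = {c: np.zeros(n_windows) for c in SPN_CLASSES}
    if len(events):
        ev = events.copy()
        ev["window"] = (ev.peak_time // time_bin).astype(int)
        ev = ev[ev.window < n_windows]
        ev["cls"] = class_of.reindex(ev.neuron_id).to_numpy()
        for c in SPN_CLASSES:
            if n_imaged[c] == 0:
                continue
            sub = ev[ev.cls == c]
            per_win = sub.groupby("window").neuron_id.nunique()
            frac[c][per_win.index.to_numpy()] = per_win.to_numpy() / n_imaged[c]

    vel_idx = (win_speed / vel_bin).astype(int)
    nbins = vel_idx.max() + 1
    rows = []
    for b in range(nbins):
        m = vel_idx == b
        if not m.any():
            continue
        row = {"vel_lo": b * vel_bin, "vel_hi": (b + 1) * vel_bin}
        for c in SPN_CLASSES:
            row[c] = 100.0 * frac[c][m].mean() if n_imaged[c] else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def peri_bout_rate(
    events: pd.DataFrame,
    segments: BehaviorSegments,
    n_active: int,
    align: str = "onset",
    bin_s: float = 0.2,
    window_s: float = 4.0,
) -> pd.DataFrame:
    """Mean event rate around bout onsets or offsets.

    Histograms event peaks into ``bin_s`` bins within ±``window_s`` of each
    bout's onset (or offset), averages over bouts, and normalises by the
    number of active neurons and the bin width → events/s per active neuron.
    """
    if n_active <= 0:
        raise ValueError("peri-bout rate undefined with zero active neurons")
    if align not in ("onset", "offset"):
        raise ValueError(f"unknown align {align!r}")
    if len(segments.bouts) == 0:
        raise ValueError("no bouts")
    edges = np.arange(-window_s, window_s + bin_s / 2, bin_s)
    centers = (edges[:-1] + edges[1:]) / 2
    hist = np.zeros(centers.size)
    anchors = (segments.bouts.onset_s if align == "onset"
               else segments.bouts.offset_s).to_numpy()
    t = events.peak_time.to_numpy() if len(events) else np.empty(0)
    for a in anchors:
        hist += np.histogram(t - a, bins=edges)[0]
    rate = hist / (len(anchors) * n_active * bin_s)
    return pd.DataFrame({"time_s": centers, "rate": rate})


def cumulative_recruitment(
    events: pd.DataFrame,
    active_flags: pd.Series,
    v: VelocityTrace,
    segments: BehaviorSegments,
) -> pd.DataFrame:
    """Empirical CDF of ensemble members recruited vs distance travelled.

    For each locomotion-active neuron, takes the cumulative |v| distance at
    its first in-bout event; the CDF is non-decreasing and reaches 1.0 by
    the session's total distance.
    """
    members = active_flags.index[active_flags.to_numpy(dtype=bool)]
    if members.size == 0:
        return pd.DataFrame(columns=["distance_cm", "fraction"])
    cdist = cumulative_distance(v)
    ev = events[events.neuron_id.isin(members)]
    ev = ev.loc[events_in_bouts(ev, segments)]
    first_t = ev.groupby("neuron_id").peak_time.min()
    idx = np.clip(np.round(first_t.to_numpy() * v.frame_rate).astype(int),
                  0, v.n_frames - 1)
    d = np.sort(cdist[idx])
    frac = np.arange(1, d.size + 1) / members.size
    return pd.DataFrame({"distance_cm": d, "fraction": frac})


def qc_include_fov(n_active_d: int, n_active_i: int, distance_cm: float,
                   min_active: int = 5, min_distance_cm: float = 500.0) -> bool:
    """FOV inclusion rule: ≥5 active dSPNs, ≥5 active iSPNs, ≥5 m travelled."""
    return (n_active_d >= min_active and n_active_i >= min_active
            and distance_cm >= min_distance_cm)


def compute_fov_metrics(
    events: pd.DataFrame,
    classes: np.ndarray,
    neuron_ids: np.ndarray,
    active_flags: pd.Series,
    segments: BehaviorSegments,
    v: VelocityTrace,
    condition: str = "baseline",
    scope: str = "locomotion",
) -> FovMetrics:
    """Assemble the per-FOV summary from a session's analysis products.

    Frequencies and amplitudes are averaged over *active* neurons of each
    class; ensemble size over *all imaged* neurons of the class.
    """
    from .behavior import session_distance

    classes = np.asarray(classes)
    neuron_ids = np.asarray(neuron_ids)
    active = active_flags.reindex(neuron_ids).fillna(False).to_numpy(dtype=bool)
    m = FovMetrics(condition=condition, scope=scope)
    m.n_imaged = {c: int((classes == c).sum()) for c in SPN_CLASSES}
    m.n_active = {c: int(active[classes == c].sum()) for c in SPN_CLASSES}
    m.ensemble_size = ensemble_size(classes, active)

    freqs = state_frequencies(events, segments, neuron_ids)
    amp_by_neuron = events.groupby("neuron_id").amplitude.mean() if len(events) \
        else pd.Series(dtype=float)
    for c in SPN_CLASSES:
        sel = neuron_ids[(classes == c) & active]
        if sel.size:
            m.freq_moving[c] = float(freqs.loc[sel, "freq_moving"].mean())
            m.freq_immobile[c] = float(freqs.loc[sel, "freq_immobile"].mean())
            amps = amp_by_neuron.reindex(sel).dropna()
            m.amp_mean[c] = float(amps.mean()) if len(amps) else np.nan
        else:
            m.freq_moving[c] = m.freq_immobile[c] = m.amp_mean[c] = np.nan

    m.bias_size = bias_index(m.ensemble_size.get("dSPN", np.nan),
                             m.ensemble_size.get("iSPN", np.nan)) \
        if all(np.isfinite(list(m.ensemble_size.values()))) else np.nan
    fm_d, fm_i = m.freq_moving.get("dSPN", np.nan), m.freq_moving.get("iSPN", np.nan)
    m.bias_freq = bias_index(fm_d, fm_i) if np.isfinite(fm_d) and np.isfinite(fm_i) else np.nan
    a_d, a_i = m.amp_mean.get("dSPN", np.nan), m.amp_mean.get("iSPN", np.nan)
    m.bias_amp = bias_index(a_d, a_i) if np.isfinite(a_d) and np.isfinite(a_i) else np.nan
    m.distance_cm = session_distance(v, "all")
    m.qc_pass = qc_include_fov(m.n_active.get("dSPN", 0),
                               m.n_active.get("iSPN", 0), m.distance_cm)
    return m
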