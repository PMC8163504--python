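"""Synthetic imaging-session generator.

Emulates, at the extracted-trace level, a population calcium-imaging session
of dorsolateral striatum in a head-fixed mouse on a circular treadmill:

* a velocity trace that alternates immobility with locomotor bouts (free
  mode) or follows a motorized 10 s-on / 10 s-off schedule at 10 cm/s;
* a neuron population split into dSPNs, iSPNs and tonically active
  interneurons, with a minority "movement ensemble" per SPN class whose size
  is scaled by a named dopamine-manipulation condition;
* ground-truth event trains — ensemble members fire as a Poisson process
  during locomotion calibrated so a 2 s locomotion window recruits each
  member with probability ``p_recruit_2s``; all SPNs fire at a low immobile
  rate; interneurons fire tonically regardless of state;
* GCaMP6f-shaped fluorescence: events convolved with a double-exponential
  kernel on a noisy per-neuron baseline plus a shared neuropil signal, with
  paired background traces carrying the neuropil signal alone.

Same seed and parameters give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import oaconvolve

from .behavior import VelocityTrace
from .params import CLASSES, SimParams
from .traces import TraceMatrix

_MIN_GAP_S = 6.0  # shortest inter-bout immobility that still segments cleanly


@dataclass
class GroundTruth:
    """Generator-side truth for one session."""

    classes: np.ndarray  # str per neuron
    ensemble: np.ndarray  # bool per neuron (always False for interneurons)
    red_intensity: np.ndarray
    baseline: np.ndarray  # raw-fluorescence baseline per neuron, a.u.
    event_times: list = field(default_factory=list)  # per-neuron array, s
    event_amps: list = field(default_factory=list)  # per-neuron array, ΔF/F
    condition_multipliers: tuple = (1.0, 1.0)

    @property
    def n_neurons(self) -> int:
        return self.classes.size

    def events_frame(self) -> pd.DataFrame:
        rows = [
            (i, t, a)
            for i, (ts, amps) in enumerate(zip(self.event_times, self.event_amps))
            for t, a in zip(ts, amps)
        ]
        return pd.DataFrame(rows, columns=["neuron_id", "time_s", "amplitude"])


@dataclass
class SessionBundle:
    """Everything one synthetic session produces."""

    params: SimParams
    velocity: VelocityTrace
    neurons: pd.DataFrame
    truth: GroundTruth
    traces: TraceMatrix


def _bout_profile(n: int, speed: float, frame_rate: float,
                  ramp_s: float = 0.5) -> np.ndarray:
    """Trapezoidal bout: linear ramps of ``ramp_s`` around a flat plateau."""
    ramp = max(1, int(round(ramp_s * frame_rate)))
    ramp = min(ramp, n // 2)
    prof = np.full(n, speed)
    r = (np.arange(ramp) + 1) / ramp
    prof[:ramp] = speed * r
    prof[n - ramp:] = speed * r[::-1]
    return prof


def simulate_velocity(params: SimParams,
                      rng: np.random.Generator | None = None) -> VelocityTrace:
    """Generate the treadmill velocity trace for one session.

    Free mode draws bout durations and plateau speeds from truncated normal
    distributions and spaces bouts so that every one satisfies the bout
    definition (>=4 s above 0.4 cm/s flanked by >=4 s immobility).  Motorized
    mode imposes 10 s bouts at 10 cm/s every 20 s after a 10 s lead-in.
    """
    params.validate()
    rng = rng or np.random.default_rng(params.seed)
    fr = params.frame_rate
    n = params.n_frames
    v = rng.normal(0.0, params.vel_noise_sd, n)
    windows: list[tuple[float, float]] = []

    if params.treadmill_mode == "motorized":
        if params.session_length < 25.0:
            raise ValueError(
                "session too short for one complete motorized bout "
                "(needs >= 25 s)"
            )
        t_on = 10.0
        while t_on + 10.0 <= params.session_length + 1e-9:
            i0, i1 = int(round(t_on * fr)), int(round((t_on + 10.0) * fr))
            v[i0:i1] += _bout_profile(i1 - i0, 10.0, fr, ramp_s=0.25)
            windows.append((t_on, t_on + 10.0))
            t_on += 20.0
    elif params.bout_rate > 0:
        if params.session_length < 2 * _MIN_GAP_S + 5.0:
            raise ValueError(
                "session too short to contain one bout "
                f"(needs >= {2 * _MIN_GAP_S + 5.0:g} s)"
            )
        mean_gap = max(60.0 / params.bout_rate - params.bout_duration_mean,
                       _MIN_GAP_S)
        cursor = _MIN_GAP_S + rng.exponential(max(mean_gap - _MIN_GAP_S, 1e-9))
        while True:
            dur = max(5.0, rng.normal(params.bout_duration_mean,
                                      0.15 * params.bout_duration_mean))
            if cursor + dur + _MIN_GAP_S > params.session_length:
                break
            speed = max(2.0, rng.normal(params.bout_speed_mean,
                                        0.2 * params.bout_speed_mean))
            i0, i1 = int(round(cursor * fr)), int(round((cursor + dur) * fr))
            v[i0:i1] += _bout_profile(i1 - i0, speed, fr)
            windows.append((cursor, cursor + dur))
            cursor += dur + _MIN_GAP_S + rng.exponential(
                max(mean_gap - _MIN_GAP_S, 1e-9)
            )
    return VelocityTrace(velocity=v, frame_rate=fr, true_bout_windows=windows)


def _exact_counts(n: int, fractions) -> np.ndarray:
    """Largest-remainder apportionment of ``n`` across classes."""
    raw = np.asarray(fractions) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def simulate_population(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw neuron classes, ensemble membership, red intensity, baselines.

    Classes follow ``class_fractions`` (per-neuron multinomial draw, or exact
    largest-remainder counts when ``params.exact_counts``).  Ensemble flags
    are Bernoulli per SPN class with the condition-scaled ensemble fractions;
    interneurons are never ensemble members.  The tdTomato-labelled class
    (dSPNs for Drd1a_tdTomato, iSPNs for Adora2a_tdTomato) gets high red
    intensity; interneurons get an elevated fluorescence baseline.
    """
    params.validate()
    rng = rng or np.random.default_rng(params.seed)
    n = params.n_neurons
    if params.exact_counts:
        counts = _exact_counts(n, params.class_fractions)
        classes = np.repeat(np.array(CLASSES), counts)
        classes = rng.permutation(classes)
    else:
        classes = rng.choice(np.array(CLASSES), size=n, p=params.class_fractions)

    fd, fi = params.effective_ensemble_fractions()
    u = rng.random(n)
    ensemble = np.where(classes == "dSPN", u < fd,
                        np.where(classes == "iSPN", u < fi, False))

    labeled = "dSPN" if params.reporter_line == "Drd1a_tdTomato" else "iSPN"
    red = np.where(classes == labeled,
                   rng.normal(100.0, 15.0, n),
                   rng.normal(10.0, 3.0, n))
    red = np.clip(red, 0.0, None)

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, n)
    baseline = np.clip(baseline, 0.2, None)
    baseline = baseline + np.where(classes == "interneuron",
                                   params.interneuron_baseline_offset, 0.0)

    neurons = pd.DataFrame({
        "neuron_id": np.arange(n),
        "red_intensity": red,
        "true_class": classes,
        "ensemble_flag": ensemble,
    })
    truth = GroundTruth(
        classes=classes, ensemble=ensemble, red_intensity=red,
        baseline=baseline,
        condition_multipliers=params.condition_multipliers,
    )
    return neurons, truth


def simulate_events(
    velocity: VelocityTrace,
    truth: GroundTruth,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Draw ground-truth event trains onto the session clock.

    Per-frame Bernoulli thinning of a piecewise-constant Poisson rate:
    ensemble members fire at ``-ln(1 - p_recruit_2s)/2`` events/s during
    locomotion and at ``rate_immobile`` otherwise; non-ensemble SPNs fire
    only the immobile rate (no locomotion-locked events); interneurons fire
    at ``interneuron_rate`` regardless of state.

    The locomotion state is the generated bout window when the velocity
    carries ground-truth windows (so the per-2 s-window recruitment
    calibration holds over whole bouts, ramps included); otherwise frames
    with |v| above the bout speed threshold.
    """
    params.validate()
    rng = rng or np.random.default_rng(params.seed)
    fr = velocity.frame_rate
    n_frames = velocity.n_frames
    if velocity.true_bout_windows:
        moving = np.zeros(n_frames, dtype=bool)
        for on, off in velocity.true_bout_windows:
            moving[int(round(on * fr)):int(round(off * fr))] = True
    else:
        moving = np.abs(velocity.velocity) > 0.4

    r_loc = params.locomotion_rate()
    rate = np.zeros((truth.n_neurons, n_frames))
    is_int = truth.classes == "interneuron"
    is_spn = ~is_int
    member = truth.ensemble & is_spn
    rate[is_int, :] = params.interneuron_rate
    rate[np.ix_(is_spn, ~moving)] = params.rate_immobile
    rate[np.ix_(member, moving)] = r_loc

    p = 1.0 - np.exp(-rate / fr)
    hits = rng.random(rate.shape) < p

    # amplitudes: log-normal with the requested mean and sd in ΔF/F units
    m, s = params.amp_mean, params.amp_sd
    sigma2 = math.log(1.0 + (s / m) ** 2)
    mu = math.log(m) - sigma2 / 2.0
    truth.event_times = []
    truth.event_amps = []
    for i in range(truth.n_neurons):
        idx = np.flatnonzero(hits[i])
        truth.event_times.append(idx / fr)
        truth.event_amps.append(
            rng.lognormal(mu, math.sqrt(sigma2), idx.size)
        )
    return truth


def gcamp_kernel(frame_rate: float, rise: float = 0.050, decay: float = 0.250,
                 length_tau: float = 8.0) -> np.ndarray:
    """Peak-normalized double-exponential GCaMP6f kernel on the frame grid."""
    t = np.arange(0.0, length_tau * decay, 1.0 / frame_rate)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    return k / k.max()


def render_traces(
    truth: GroundTruth,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> TraceMatrix:
    """Render raw fluorescence from ground-truth events.

    cell trace  = baseline + Σ amplitudes ⊗ kernel + noise + w × neuropil
    background  = neuropil signal alone
    """
    params.validate()
    rng = rng or np.random.default_rng(params.seed)
    fr = params.frame_rate
    n_frames = params.n_frames
    n = truth.n_neurons

    # shared neuropil: slow positive fluctuation around a fixed pedestal
    white = rng.normal(0.0, 1.0, n_frames)
    slow = gaussian_filter1d(white, sigma=15.0)
    sd = slow.std()
    if sd > 0:
        slow *= 0.05 / sd
    neuropil = np.clip(0.2 + slow, 0.0, None)

    kernel = gcamp_kernel(fr, params.kernel_rise, params.kernel_decay)
    impulses = np.zeros((n, n_frames))
    for i, (times, amps) in enumerate(zip(truth.event_times, truth.event_amps)):
        idx = np.round(np.asarray(times) * fr).astype(int)
        np.add.at(impulses[i], idx[idx < n_frames], amps[idx < n_frames])
    signal = oaconvolve(impulses, kernel[None, :], axes=1)[:, :n_frames]

    noise = rng.normal(0.0, params.noise_sd, (n, n_frames))
    raw = (truth.baseline[:, None] + signal + noise
           + params.neuropil_weight * neuropil[None, :])
    background = np.tile(neuropil, (n, 1))
    return TraceMatrix(raw=raw, background=background, frame_rate=fr)


def simulate_session(params: SimParams) -> SessionBundle:
    """Generate a complete session from one root seed.

    Randomness is split into named substreams (velocity, population, events,
    rendering) so each stage is individually reproducible.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    rng_v, rng_p, rng_e, rng_r = (np.random.default_rng(s) for s in ss.spawn(4))
    velocity = simulate_velocity(params, rng_v)
    neurons, truth = simulate_population(params, rng_p)
    truth = simulate_events(velocity, truth, params, rng_e)
    traces = render_traces(truth, params, rng_r)
    return SessionBundle(params=params, velocity=velocity, neurons=neurons,
                         truth=truth, traces=traces)
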