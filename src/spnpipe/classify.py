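"""Neuron classification from red-channel intensity and trace features.

tdTomato-positive neurons take the reporter line's labelled class (dSPNs for
Drd1a_tdTomato, iSPNs for Adora2a_tdTomato).  Red-negative neurons with an
elevated fluorescence baseline or tonic activity while immobile are labelled
interneurons; the remainder take the complementary SPN class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import ClassificationThresholds

_LABELED = {"Drd1a_tdTomato": "dSPN", "Adora2a_tdTomato": "iSPN"}
_COMPLEMENT = {"dSPN": "iSPN", "iSPN": "dSPN"}


def two_means_threshold(values: np.ndarray) -> float:
    """Exact 1-D two-means split: midpoint of the two cluster centroids.

    Scans every split of the sorted values and picks the one minimising
    within-cluster sum of squares; deterministic and exact in one dimension.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        raise ValueError("red-intensity distribution has no split")
    csum = np.cumsum(x)
    csq = np.cumsum(x ** 2)
    k = np.arange(1, n)  # split: x[:k] | x[k:]
    left_ss = csq[k - 1] - csum[k - 1] ** 2 / k
    rsum = csum[-1] - csum[k - 1]
    rsq = csq[-1] - csq[k - 1]
    right_ss = rsq - rsum ** 2 / (n - k)
    kbest = int(k[np.argmin(left_ss + right_ss)])
    return float((csum[kbest - 1] / kbest + (csum[-1] - csum[kbest - 1]) / (n - kbest)) / 2.0)


def classify_neurons(
    neurons: pd.DataFrame,
    baseline_f: np.ndarray,
    immobile_rate: np.ndarray | None = None,
    reporter_line: str = "Drd1a_tdTomato",
    thresholds: ClassificationThresholds | None = None,
) -> pd.DataFrame:
    """Assign every neuron exactly one class.

    ``baseline_f`` is the per-neuron baseline fluorescence (e.g. the F0 from
    ΔF/F computation); ``immobile_rate`` the per-neuron event rate during
    immobility (events/s), used to catch tonically active interneurons whose
    baseline alone is ambiguous.

    The interneuron baseline threshold is mean + k·SD of the red-negative
    population's baselines: SPNs dominate that population, and the
    interneuron minority inflates the SD, which places the cut between the
    two modes.
    """
    if reporter_line not in _LABELED:
        raise ValueError(f"unknown reporter_line {reporter_line!r}")
    thr = thresholds or ClassificationThresholds()
    out = neurons.copy()
    red = out["red_intensity"].to_numpy(dtype=float)
    baseline_f = np.asarray(baseline_f, dtype=float)
    if baseline_f.size != len(out):
        raise ValueError("baseline_f length mismatch")

    red_thr = thr.red_threshold
    if red_thr is None:
        red_thr = two_means_threshold(red)
    red_pos = red > red_thr

    labeled = _LABELED[reporter_line]
    other = _COMPLEMENT[labeled]

    neg = ~red_pos
    if neg.sum() >= 2:
        mu, sd = baseline_f[neg].mean(), baseline_f[neg].std()
    else:
        mu, sd = baseline_f.mean(), baseline_f.std()
    base_thr = mu + thr.interneuron_baseline_k_sd * sd
    tonic = np.zeros(len(out), dtype=bool)
    if immobile_rate is not None:
        tonic = np.asarray(immobile_rate, dtype=float) > thr.interneuron_tonic_rate

    cls = np.where(red_pos, labeled,
                   np.where((baseline_f > base_thr) | tonic, "interneuron", other))
    out["class"] = cls
    out.attrs["red_threshold"] = float(red_thr)
    out.attrs["interneuron_baseline_threshold"] = float(base_thr)
    return out


def immobile_event_rate(
    events: pd.DataFrame,
    neuron_ids: np.ndarray,
    immobility: pd.DataFrame,
) -> np.ndarray:
    """Per-neuron event rate (events/s) during immobility intervals."""
    neuron_ids = np.asarray(neuron_ids)
    total = float((immobility.end_s - immobility.start_s).sum()) if len(immobility) else 0.0
    rates = np.zeros(neuron_ids.size)
    if total == 0.0 or len(events) == 0:
        return rates
    t = events.peak_time.to_numpy()
    mask = np.zeros(len(events), dtype=bool)
    for r in immobility.itertuples():
        mask |= (t >= r.start_s) & (t < r.end_s)
    counts = events.loc[mask].groupby("neuron_id").size()
    idx = pd.Series(np.arange(neuron_ids.size), index=neuron_ids)
    common = counts.index.intersection(idx.index)
    rates[idx.loc[common].to_numpy()] = counts.loc[common].to_numpy() / total
    return rates
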