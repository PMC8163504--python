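"""Parameter containers and experimental-condition presets.

The simulator and every analysis stage read their defaults from here so that
the whole pipeline can be driven by a single serializable configuration.
Defaults reflect the study conditions the pipeline is designed for: dorsal
striatum imaged at 30 Hz, ~327 neurons per field of view, ~95% of neurons
being spiny projection neurons (SPNs) split evenly between the direct (dSPN)
and indirect (iSPN) pathway, with movement ensembles covering 16.9% of dSPNs
and 18.6% of iSPNs and ~10% of the active ensemble recruited per 2 s of
locomotion.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Tuple

#: Multipliers applied to (ensemble_fraction_d, ensemble_fraction_i) for each
#: named dopamine-manipulation condition, relative to the intact baseline.
#: D1/2R antagonists halve the dSPN ensemble and expand the iSPN ensemble
#: >3-fold; acute 6-OHDA lesion resembles the antagonist state; by one month
#: post-lesion the iSPN ensemble has renormalized while the dSPN ensemble
#: remains halved; L-DOPA on a chronic lesion expands the lesioned dSPN
#: ensemble 10-fold (i.e. 5x the intact baseline) and pushes iSPNs below
#: their pre-lesion size.  Effective fractions are capped at 1.
CONDITION_PRESETS: dict[str, Tuple[float, float]] = {
    "baseline": (1.0, 1.0),
    "antagonist": (0.5, 3.3),
    "agonist_low": (1.3, 1.0),
    "agonist_high": (0.6, 0.3),
    "ohda_day1": (0.5, 2.2),
    "ohda_day30": (0.5, 1.0),
    "ldopa_on_lesion": (5.0, 0.5),
}

CLASSES = ("dSPN", "iSPN", "interneuron")


@dataclass
class SimParams:
    """Generator parameters for one synthetic imaging session.

    Rates are in events/s, amplitudes and noise in ΔF/F units, durations in
    seconds, speeds in cm/s.
    """

    n_neurons: int = 327
    class_fractions: Tuple[float, float, float] = (0.475, 0.475, 0.05)
    frame_rate: float = 30.0
    session_length: float = 300.0
    treadmill_mode: str = "free"  # "free" | "motorized"
    bout_rate: float = 2.0  # bouts/min, free mode
    bout_duration_mean: float = 8.0
    bout_speed_mean: float = 8.0
    ensemble_fraction_d: float = 0.169
    ensemble_fraction_i: float = 0.186
    p_recruit_2s: float = 0.10
    rate_immobile: float = 0.005
    amp_mean: float = 0.8
    amp_sd: float = 0.4
    noise_sd: float = 0.05
    neuropil_weight: float = 1.0
    kernel_rise: float = 0.050
    kernel_decay: float = 0.250
    interneuron_baseline_offset: float = 0.5
    interneuron_rate: float = 0.2
    condition: str = "baseline"
    seed: int = 0
    # plumbing defaults (not per-condition)
    vel_noise_sd: float = 0.03  # immobile velocity noise, cm/s
    baseline_mean: float = 1.0  # raw fluorescence baseline, a.u.
    baseline_sd: float = 0.05
    reporter_line: str = "Drd1a_tdTomato"
    exact_counts: bool = False  # largest-remainder class assignment

    def validate(self) -> None:
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if any(f < 0 or f > 1 for f in self.class_fractions):
            raise ValueError("class_fractions must lie in [0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.session_length <= 0:
            raise ValueError("session_length must be positive")
        for name in ("bout_rate", "rate_immobile", "interneuron_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("ensemble_fraction_d", "ensemble_fraction_i", "p_recruit_2s"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_recruit_2s >= 1.0:
            raise ValueError("p_recruit_2s must be < 1")
        if self.treadmill_mode not in ("free", "motorized"):
            raise ValueError(f"unknown treadmill_mode {self.treadmill_mode!r}")
        if self.condition not in CONDITION_PRESETS:
            raise ValueError(
                f"unknown condition {self.condition!r}; "
                f"known: {sorted(CONDITION_PRESETS)}"
            )
        if self.n_neurons <= 0:
            raise ValueError("n_neurons must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.session_length * self.frame_rate))

    @property
    def condition_multipliers(self) -> Tuple[float, float]:
        return CONDITION_PRESETS[self.condition]

    def effective_ensemble_fractions(self) -> Tuple[float, float]:
        """Ensemble fractions after applying the condition multipliers, capped at 1."""
        md, mi = self.condition_multipliers
        return (
            min(1.0, self.ensemble_fraction_d * md),
            min(1.0, self.ensemble_fraction_i * mi),
        )

    def locomotion_rate(self) -> float:
        """Per-member event rate (events/s) during locomotion.

        Calibrated so that P(>=1 event in a 2 s locomotion window) equals
        ``p_recruit_2s`` under a Poisson process: rate = -ln(1 - p) / 2.
        """
        return -math.log(1.0 - self.p_recruit_2s) / 2.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_fractions"] = list(self.class_fractions)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        if "class_fractions" in d:
            d["class_fractions"] = tuple(d["class_fractions"])
        p = cls(**d)
        p.validate()
        return p

    @classmethod
    def from_json(cls, path) -> "SimParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class DetectionCriteria:
    """Transient-detection thresholds.

    A local maximum of the smoothed ΔF/F trace is a transient when its height
    above baseline and its topographic prominence both exceed ``k_sd`` robust
    standard deviations of the trace, and its width at half prominence is at
    least ``min_width_s``.
    """

    k_sd: float = 5.0
    min_width_s: float = 0.140
    smooth_window_s: float = 0.150

    def validate(self) -> None:
        for name in ("k_sd", "min_width_s", "smooth_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class SegmentationParams:
    """Thresholds defining immobility and movement bouts."""

    immobile_speed: float = 0.2  # cm/s
    bout_speed: float = 0.4  # cm/s
    guard_s: float = 0.5  # trimmed from each end of an immobility run
    min_immobility_s: float = 4.0
    min_bout_s: float = 4.0
    flank_s: float = 4.0  # required immobility flanking a bout
    gap_tol_s: float = 1.0  # max gap between candidate edge and immobility
    onset_k_sd: float = 2.0  # onset/offset refinement threshold

    def validate(self) -> None:
        for name in dataclasses.asdict(self):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ClassificationThresholds:
    """Thresholds for assigning dSPN / iSPN / interneuron labels."""

    red_threshold: float | None = None  # None -> two-means split of red intensity
    interneuron_baseline_k_sd: float = 2.0
    interneuron_tonic_rate: float = 0.1  # events/s while immobile
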