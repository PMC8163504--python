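import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spnpipe import (
    VelocityTrace,
    bias_index,
    cumulative_recruitment,
    ensemble_size,
    fraction_active_vs_velocity,
    frequency_vs_velocity,
    peri_bout_rate,
    qc_include_fov,
    segment_session,
    state_frequencies,
)

FR = 30.0


def one_bout_velocity(bout_speed=10.0, bout_s=10.0, flank_s=6.0):
    v = np.r_[np.zeros(int(flank_s * FR)),
              np.full(int(bout_s * FR), bout_speed),
              np.zeros(int(flank_s * FR))]
    return VelocityTrace(velocity=v, frame_rate=FR)


class TestEnsembleSize:
    def test_20_of_100(self):
        classes = np.array(["dSPN"] * 100 + ["iSPN"] * 50)
        active = np.r_[np.ones(20), np.zeros(130)].astype(bool)
        out = ensemble_size(classes, active)
        assert out["dSPN"] == 20.0
        assert out["iSPN"] == 0.0

    def test_zero_imaged_is_nan(self):
        out = ensemble_size(np.array(["dSPN", "dSPN"]), np.array([True, False]))
        assert math.isnan(out["iSPN"])
        assert out["dSPN"] == 50.0


class TestBiasIndex:
    def test_equality_gives_zero(self):
        assert bias_index(3.0, 3.0) == 0.0

    def test_printed_ensemble_sizes(self):
        # direct evaluation of (d - i)/(d + i) on 16.9 and 18.6
        assert bias_index(16.9, 18.6) == pytest.approx(-1.7 / 35.5, rel=1e-12)

    def test_both_zero_undefined(self):
        assert math.isnan(bias_index(0.0, 0.0))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            bias_index(-1.0, 2.0)

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    @settings(deadline=None, max_examples=100)
    def test_antisymmetry_and_bounds(self, a, b):
        x = bias_index(a, b)
        if math.isnan(x):
            assert a + b == 0
        else:
            assert -1.0 <= x <= 1.0
            assert bias_index(b, a) == pytest.approx(-x, abs=1e-12)


class TestStateFrequencies:
    def test_5_events_in_10s_bout(self):
        v = one_bout_velocity()
        seg = segment_session(v)
        ev = pd.DataFrame({"neuron_id": [0] * 5,
                           "peak_time": [7.0, 8.0, 9.0, 10.0, 11.0]})
        out = state_frequencies(ev, seg, np.arange(2))
        assert out.loc[0, "freq_moving"] == pytest.approx(5 / seg.total_bout_time)
        assert out.loc[0, "freq_moving"] == pytest.approx(0.5, rel=0.05)
        assert out.loc[0, "freq_immobile"] == 0.0
        assert out.loc[1, "freq_moving"] == 0.0


class TestFrequencyVsVelocity:
    def test_count_conservation_identity(self):
        rng = np.random.default_rng(0)
        v = VelocityTrace(velocity=rng.uniform(0, 5, 6000), frame_rate=FR)
        ev = pd.DataFrame({"neuron_id": rng.integers(0, 10, 200),
                           "peak_time": rng.uniform(0, 200, 200)})
        out = frequency_vs_velocity(ev, v, n_neurons=10)
        occ = out.dropna(subset=["rate"])
        total = (occ.rate * occ.time_s * 10).sum()
        assert total == pytest.approx(len(ev), rel=1e-9)

    def test_all_events_at_one_velocity(self):
        v = VelocityTrace(velocity=np.full(3000, 3.0), frame_rate=FR)
        ev = pd.DataFrame({"neuron_id": [0, 1], "peak_time": [10.0, 20.0]})
        out = frequency_vs_velocity(ev, v, n_neurons=2)
        occupied = out[out.time_s > 0]
        assert len(occupied) == 1
        assert occupied.n_events.iloc[0] == 2

    def test_doubling_occupancy_halves_rate(self):
        v1 = VelocityTrace(velocity=np.full(3000, 3.0), frame_rate=FR)
        v2 = VelocityTrace(velocity=np.full(6000, 3.0), frame_rate=FR)
        ev = pd.DataFrame({"neuron_id": [0] * 4, "peak_time": [1.0, 2.0, 3.0, 4.0]})
        r1 = frequency_vs_velocity(ev, v1, 1).dropna(subset=["rate"]).rate.iloc[-1]
        r2 = frequency_vs_velocity(ev, v2, 1).dropna(subset=["rate"]).rate.iloc[-1]
        assert r2 == pytest.approx(r1 / 2, rel=1e-9)


class TestFractionActiveVsVelocity:
    def test_no_events_zero_everywhere(self):
        v = one_bout_velocity()
        ev = pd.DataFrame(columns=["neuron_id", "peak_time"])
        out = fraction_active_vs_velocity(
            ev, np.array(["dSPN"] * 4), np.arange(4), v)
        assert (out["dSPN"] == 0).all()

    def test_all_neurons_fire_in_one_window(self):
        v = one_bout_velocity()
        ids = np.arange(4)
        ev = pd.DataFrame({"neuron_id": ids,
                           "peak_time": np.full(4, 10.05)})
        out = fraction_active_vs_velocity(ev, np.array(["dSPN"] * 4), ids, v)
        top = out[out.vel_lo == 10.0]
        assert top["dSPN"].iloc[0] > 0


class TestPeriBoutRate:
    def test_no_events_zero_curve(self):
        seg = segment_session(one_bout_velocity())
        ev = pd.DataFrame(columns=["neuron_id", "peak_time"])
        out = peri_bout_rate(ev, seg, n_active=5)
        assert (out.rate == 0).all()

    def test_events_only_after_onset(self):
        seg = segment_session(one_bout_velocity())
        onset = seg.bouts.onset_s.iloc[0]
        ev = pd.DataFrame({"neuron_id": [0, 0, 1],
                           "peak_time": onset + np.array([0.5, 1.0, 2.0])})
        out = peri_bout_rate(ev, seg, n_active=2)
        assert (out.loc[out.time_s < 0, "rate"] == 0).all()
        assert out.loc[out.time_s > 0, "rate"].sum() > 0

    def test_zero_active_undefined(self):
        seg = segment_session(one_bout_velocity())
        with pytest.raises(ValueError):
            peri_bout_rate(pd.DataFrame(columns=["neuron_id", "peak_time"]),
                           seg, n_active=0)


class TestCumulativeRecruitment:
    def test_member_firing_at_bout_start_steps_early(self):
        v = one_bout_velocity()
        seg = segment_session(v)
        onset = seg.bouts.onset_s.iloc[0]
        ev = pd.DataFrame({"neuron_id": [0], "peak_time": [onset + 0.1]})
        flags = pd.Series([True], index=[0])
        out = cumulative_recruitment(ev, flags, v, seg)
        assert out.fraction.iloc[-1] == 1.0
        assert out.distance_cm.iloc[0] < 5.0

    def test_cdf_non_decreasing_reaches_one(self):
        rng = np.random.default_rng(1)
        v = one_bout_velocity(bout_s=60.0)
        seg = segment_session(v)
        n = 40
        ev = pd.DataFrame({
            "neuron_id": np.arange(n),
            "peak_time": rng.uniform(seg.bouts.onset_s.iloc[0] + 0.1,
                                     seg.bouts.offset_s.iloc[0] - 0.1, n),
        })
        flags = pd.Series(True, index=np.arange(n))
        out = cumulative_recruitment(ev, flags, v, seg)
        assert (np.diff(out.fraction) >= 0).all()
        assert out.fraction.iloc[-1] == pytest.approx(1.0)

    def test_constant_rate_matches_exponential_law(self):
        # members firing at rate lam during a long constant-speed bout:
        # P(first event distance <= d) = 1 - exp(-lam * d / speed)
        rng = np.random.default_rng(2)
        speed, lam, n = 5.0, 0.05, 300
        v = one_bout_velocity(bout_speed=speed, bout_s=600.0)
        seg = segment_session(v)
        onset = seg.bouts.onset_s.iloc[0]
        first = onset + rng.exponential(1 / lam, n)
        ev = pd.DataFrame({"neuron_id": np.arange(n), "peak_time": first})
        ev = ev[ev.peak_time < seg.bouts.offset_s.iloc[0]]
        flags = pd.Series(True, index=np.arange(n))
        flags[~flags.index.isin(ev.neuron_id)] = False
        out = cumulative_recruitment(ev, flags, v, seg)
        d0 = onset * 0 + 0.0
        theo = 1 - np.exp(-lam * (out.distance_cm - out.distance_cm.min()) / speed)
        theo /= theo.iloc[-1]  # condition on firing within the session
        ks = np.abs(out.fraction - theo).max()
        assert ks < 0.1


class TestQc:
    @pytest.mark.parametrize("nd,ni,dist,expected", [
        (5, 5, 510.0, True),
        (4, 5, 510.0, False),
        (6, 6, 499.0, False),
        (5, 5, 500.0, True),
    ])
    def test_inclusion_rule_edges(self, nd, ni, dist, expected):
        assert qc_include_fov(nd, ni, dist) is expected
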