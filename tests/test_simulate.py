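import dataclasses
import math

import numpy as np
import pytest

from spnpipe import (
    CONDITION_PRESETS,
    SimParams,
    VelocityTrace,
    segment_session,
    session_distance,
    simulate_events,
    simulate_population,
    simulate_session,
    simulate_velocity,
)
from spnpipe.simulate import GroundTruth, gcamp_kernel, render_traces
from spnpipe.traces import smooth


class TestVelocity:
    def test_motorized_60s_has_two_complete_bouts(self):
        p = SimParams(treadmill_mode="motorized", session_length=60.0, seed=0)
        v = simulate_velocity(p)
        seg = segment_session(v)
        assert len(seg.bouts) == 2
        for b in seg.bouts.itertuples():
            i0 = int((b.onset_s + 2) * p.frame_rate)
            i1 = int((b.offset_s - 2) * p.frame_rate)
            assert np.median(v.velocity[i0:i1]) == pytest.approx(10.0, abs=0.1)

    def test_zero_bout_rate_stays_below_immobility_threshold(self):
        p = SimParams(bout_rate=0.0, session_length=120.0, seed=2)
        v = simulate_velocity(p)
        assert np.abs(v.velocity).max() < 0.2

    def test_session_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            simulate_velocity(SimParams(session_length=10.0))
        with pytest.raises(ValueError, match="too short"):
            simulate_velocity(SimParams(treadmill_mode="motorized",
                                        session_length=20.0))

    def test_deterministic_and_distance_matches_trapezoid(self):
        p = SimParams(seed=7, session_length=300.0)
        v1 = simulate_velocity(p)
        v2 = simulate_velocity(p)
        assert np.array_equal(v1.velocity, v2.velocity)
        assert len(v1.true_bout_windows) == len(v2.true_bout_windows)
        d = session_distance(v1)
        assert d == pytest.approx(np.trapezoid(np.abs(v1.velocity),
                                               dx=1 / p.frame_rate), abs=1e-9)

    def test_every_generated_bout_is_detected(self):
        for seed in (1, 2, 3):
            p = SimParams(seed=seed)
            v = simulate_velocity(p)
            seg = segment_session(v)
            assert len(seg.bouts) == len(v.true_bout_windows)


class TestPopulation:
    def test_exact_rounding_forced_split(self):
        p = SimParams(n_neurons=100, class_fractions=(0.5, 0.5, 0.0),
                      exact_counts=True, seed=0)
        neurons, truth = simulate_population(p)
        assert (truth.classes == "dSPN").sum() == 50
        assert (truth.classes == "iSPN").sum() == 50

    def test_zero_ensemble_fraction_means_no_members(self):
        p = SimParams(n_neurons=500, ensemble_fraction_d=0.0, seed=1)
        _, truth = simulate_population(p)
        assert not truth.ensemble[truth.classes == "dSPN"].any()

    def test_interneurons_never_ensemble_members(self):
        _, truth = simulate_population(SimParams(n_neurons=1000, seed=2))
        assert not truth.ensemble[truth.classes == "interneuron"].any()

    def test_multinomial_counts_within_3se(self):
        p = SimParams(n_neurons=1000)
        counts = np.zeros(3)
        n_draws = 50
        for s in range(n_draws):
            _, truth = simulate_population(dataclasses.replace(p, seed=s))
            for k, c in enumerate(("dSPN", "iSPN", "interneuron")):
                counts[k] += (truth.classes == c).sum()
        mean_counts = counts / n_draws
        for k, f in enumerate(p.class_fractions):
            se = math.sqrt(1000 * f * (1 - f) / n_draws)
            assert abs(mean_counts[k] - 1000 * f) <= 3 * se

    def test_labeled_class_has_high_red(self):
        _, truth = simulate_population(SimParams(n_neurons=500, seed=3))
        d = truth.red_intensity[truth.classes == "dSPN"]
        o = truth.red_intensity[truth.classes != "dSPN"]
        assert d.min() > o.max()


class TestEvents:
    @staticmethod
    def moving_session(n_members=500, seconds=200.0, p_recruit=0.1, seed=3):
        fr = 30.0
        v = VelocityTrace(velocity=np.full(int(seconds * fr), 5.0), frame_rate=fr)
        classes = np.array(["dSPN"] * n_members)
        truth = GroundTruth(classes=classes,
                            ensemble=np.ones(n_members, dtype=bool),
                            red_intensity=np.full(n_members, 100.0),
                            baseline=np.ones(n_members))
        p = SimParams(n_neurons=n_members, p_recruit_2s=p_recruit,
                      rate_immobile=0.0, seed=seed)
        return simulate_events(v, truth, p, np.random.default_rng(seed)), p

    def test_zero_rates_give_zero_events(self):
        truth, _ = self.moving_session(n_members=50, p_recruit=0.0)
        assert all(t.size == 0 for t in truth.event_times)

    def test_locomotion_rate_closed_form(self):
        p = SimParams(p_recruit_2s=0.1)
        assert p.locomotion_rate() == pytest.approx(-math.log(0.9) / 2, rel=1e-12)
        assert p.locomotion_rate() == pytest.approx(0.0527, abs=5e-4)

    def test_recruitment_per_2s_window_within_2se(self):
        truth, p = self.moving_session()
        fr, win = 30.0, 2.0
        n_windows = int(200.0 / win)
        hits = 0
        for times in truth.event_times:
            w = np.unique((np.asarray(times) // win).astype(int))
            hits += (w < n_windows).sum()
        total = truth.n_neurons * n_windows
        p_hat = hits / total
        se = math.sqrt(0.1 * 0.9 / total)
        assert abs(p_hat - 0.1) <= 2 * se

    def test_non_members_emit_nothing_while_moving(self):
        fr = 30.0
        v = VelocityTrace(velocity=np.full(3000, 5.0), frame_rate=fr)
        truth = GroundTruth(classes=np.array(["iSPN"] * 50),
                            ensemble=np.zeros(50, dtype=bool),
                            red_intensity=np.zeros(50), baseline=np.ones(50))
        p = SimParams(n_neurons=50, rate_immobile=0.01, seed=0)
        truth = simulate_events(v, truth, p, np.random.default_rng(0))
        assert all(t.size == 0 for t in truth.event_times)


class TestRender:
    @staticmethod
    def single_event_truth(amp=0.8):
        return GroundTruth(classes=np.array(["dSPN"]),
                           ensemble=np.array([True]),
                           red_intensity=np.array([100.0]),
                           baseline=np.array([1.0]),
                           event_times=[np.array([5.0])],
                           event_amps=[np.array([amp])])

    def test_no_events_no_noise_is_flat_baseline(self):
        truth = GroundTruth(classes=np.array(["dSPN"]),
                            ensemble=np.array([True]),
                            red_intensity=np.array([100.0]),
                            baseline=np.array([1.0]),
                            event_times=[np.empty(0)],
                            event_amps=[np.empty(0)])
        p = SimParams(n_neurons=1, noise_sd=0.0, neuropil_weight=0.0,
                      session_length=30.0)
        tm = render_traces(truth, p, np.random.default_rng(0))
        assert np.allclose(tm.raw, 1.0)

    def test_zero_neuropil_weight_leaves_cell_trace(self):
        p = SimParams(n_neurons=1, noise_sd=0.0, neuropil_weight=0.0,
                      session_length=30.0)
        tm = render_traces(self.single_event_truth(), p, np.random.default_rng(0))
        assert np.abs(tm.background).max() > 0  # neuropil still recorded
        p1 = dataclasses.replace(p, neuropil_weight=1.0)
        tm1 = render_traces(self.single_event_truth(), p1, np.random.default_rng(0))
        # with weight 1 the background subtraction recovers the weight-0 trace
        assert np.allclose(tm1.raw - tm1.background, tm.raw, atol=1e-12)

    def test_rendered_event_width_exceeds_detector_minimum(self):
        p = SimParams(n_neurons=1, noise_sd=0.0, neuropil_weight=0.0,
                      session_length=30.0)
        tm = render_traces(self.single_event_truth(), p, np.random.default_rng(0))
        x = smooth(tm.raw[0] - 1.0, 0.150, p.frame_rate)
        half = x.max() / 2
        above = np.flatnonzero(x > half)
        width_s = (above[-1] - above[0]) / p.frame_rate
        assert width_s >= 0.140

    def test_kernel_halfwidth_on_fine_grid(self):
        k = gcamp_kernel(frame_rate=1000.0)
        above = np.flatnonzero(k > 0.5)
        assert (above[-1] - above[0]) / 1000.0 >= 0.140


class TestSessionDeterminism:
    def test_same_seed_bit_identical(self, small_params):
        a = simulate_session(small_params)
        b = simulate_session(small_params)
        assert np.array_equal(a.velocity.velocity, b.velocity.velocity)
        assert np.array_equal(a.traces.raw, b.traces.raw)
        assert all(np.array_equal(x, y) for x, y in
                   zip(a.truth.event_times, b.truth.event_times))

    def test_condition_presets_scale_fractions(self):
        assert CONDITION_PRESETS["baseline"] == (1.0, 1.0)
        p = SimParams(condition="antagonist")
        fd, fi = p.effective_ensemble_fractions()
        assert fd == pytest.approx(0.169 * 0.5)
        assert fi == pytest.approx(0.186 * 3.3)
        capped = SimParams(condition="ldopa_on_lesion", ensemble_fraction_d=0.5)
        assert capped.effective_ensemble_fractions()[0] == 1.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(class_fractions=(0.5, 0.4, 0.2)).validate()
        with pytest.raises(ValueError):
            SimParams(condition="nope").validate()
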