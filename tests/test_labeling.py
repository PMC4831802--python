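import numpy as np
import pytest

import germcycle as gc
from germcycle.labeling import ActivitySchedule


class TestActivitySchedule:
    def test_rejects_overlapping_or_inverted_intervals(self):
        with pytest.raises(ValueError):
            ActivitySchedule(((0.0, 2.0), (1.0, 3.0)))
        with pytest.raises(ValueError):
            ActivitySchedule(((2.0, 1.0),))

    def test_active_time_is_nondecreasing(self):
        sched = ActivitySchedule(((0.5, 1.5), (2.0, 4.0)))
        ts = np.linspace(0, 5, 40)
        vals = [sched.active_time(t) for t in ts]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert sched.active_time(5.0) == pytest.approx(3.0)

    def test_clip_shifts_to_window_origin(self):
        sched = ActivitySchedule(((0.5, 1.5), (2.0, 4.0)))
        clipped = sched.clip(1.0, 3.0)
        assert clipped.intervals == ((0.0, 0.5), (1.0, 2.0))


class TestPulseLabel:
    def test_plateau_cells_stay_unlabeled(self, wt_params):
        # all in G2/M, pulse too short for any to wrap into G1 then S
        pop = gc.ZonePopulation(np.array([0.75, 0.8, 0.85]))
        out = gc.pulse_label(pop, 0.1, wt_params)
        assert not out.labeled.any()

    def test_zero_duration_pulse_labels_cells_in_s(self, wt_params):
        ages = np.array([0.1, 0.45, 0.75])  # G1, S, G2
        out = gc.pulse_label(gc.ZonePopulation(ages), 0.0, wt_params)
        np.testing.assert_array_equal(out.labeled, [False, True, False])
        np.testing.assert_array_equal(out.ages, ages)

    def test_pulse_longer_than_cycle_rejected(self, wt_params):
        pop = gc.sample_steady_state(5, wt_params, 0)
        with pytest.raises(ValueError):
            gc.pulse_label(pop, wt_params.t_c, wt_params)

    def test_steady_state_labeled_fraction(self, wt_params):
        n, pulse = 20_000, 1.1
        pop = gc.sample_steady_state(n, wt_params, 11)
        out = gc.pulse_label(pop, pulse, wt_params)
        expected = wt_params.f_s + pulse / wt_params.t_c
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(out.labeled.mean() - expected) < 3 * se


class TestChase:
    def test_fully_dormant_schedule_freezes_population(self, wt_params):
        pop = gc.sample_steady_state(50, wt_params, 3)
        out = gc.chase(pop, ActivitySchedule.none(), 4.0, wt_params)
        np.testing.assert_array_equal(out.ages, pop.ages)

    def test_fully_active_schedule_equals_advance(self, wt_params):
        pop = gc.sample_steady_state(50, wt_params, 4)
        out = gc.chase(pop, ActivitySchedule.full(4.0), 4.0, wt_params)
        np.testing.assert_allclose(out.ages, gc.advance(pop, 4.0, wt_params).ages)

    def test_half_active_schedule_advances_half(self, wt_params):
        pop = gc.sample_steady_state(50, wt_params, 5)
        sched = ActivitySchedule(((1.0, 3.0),))
        out = gc.chase(pop, sched, 4.0, wt_params)
        np.testing.assert_allclose(out.ages, gc.advance(pop, 2.0, wt_params).ages)

    def test_schedule_outside_window_rejected(self, wt_params):
        pop = gc.sample_steady_state(5, wt_params, 6)
        with pytest.raises(ValueError):
            gc.chase(pop, ActivitySchedule.full(5.0), 4.0, wt_params)


class TestContinuousLabel:
    def test_dormant_window_labels_nothing(self, wt_params):
        pop = gc.sample_steady_state(200, wt_params, 7)
        out = gc.continuous_label(pop, ActivitySchedule.none(), 6.0, wt_params)
        assert not out.labeled.any()

    def test_full_cycle_of_activity_labels_everyone(self, wt_params):
        pop = gc.sample_steady_state(500, wt_params, 8)
        t = wt_params.t_c
        out = gc.continuous_label(pop, ActivitySchedule.full(t), t, wt_params)
        assert out.labeled.all()

    def test_short_window_labeled_fraction(self, wt_params):
        n, t = 20_000, 1.5
        pop = gc.sample_steady_state(n, wt_params, 9)
        out = gc.continuous_label(pop, ActivitySchedule.full(t), t, wt_params)
        expected = wt_params.f_s + t / wt_params.t_c
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(out.labeled.mean() - expected) < 3 * se

    def test_label_set_never_shrinks(self, wt_params):
        pop = gc.sample_steady_state(300, wt_params, 10)
        pop = gc.pulse_label(pop, 0.5, wt_params)
        before = pop.labeled.copy()
        out = gc.continuous_label(pop, ActivitySchedule(((0.0, 1.0),)), 2.0, wt_params)
        assert np.all(out.labeled[before])

    def test_active_zone_of_260_labels_immediately(self, wt_params):
        # the zone-level approximation: an active 260-cell zone essentially
        # always contains an S-phase cell, so first-label time is ~0
        hits = 0
        for seed in range(200):
            pop = gc.sample_steady_state(260, wt_params, seed)
            out = gc.continuous_label(pop, ActivitySchedule.full(0.01), 0.01, wt_params)
            hits += out.labeled.any()
        assert hits == 200


class TestHistogramPair:
    def test_noiseless_g1_population_fills_first_bin(self, wt_params):
        pop = gc.ZonePopulation(np.full(40, 0.1))
        hp = gc.make_histogram_pair(pop, gc.default_bin_edges(), wt_params)
        assert hp.counts_neg[0] == 40
        assert hp.counts_pos.sum() == 0

    def test_counts_conserve_cells(self, wt_params):
        pop = gc.sample_steady_state(777, wt_params, 12)
        hp = gc.make_histogram_pair(pop, gc.default_bin_edges(), wt_params, 0.06, seed=1)
        assert hp.total == 777

    def test_empty_population_flagged_not_raised(self, wt_params):
        hp = gc.make_histogram_pair(
            gc.ZonePopulation(np.array([])), gc.default_bin_edges(), wt_params
        )
        assert hp.empty and np.isnan(hp.frac_pos)

    def test_noisy_g1_content_unbiased(self, wt_params):
        n = 10_000
        pop = gc.ZonePopulation(np.full(n, 0.1))
        rng = np.random.default_rng(13)
        content = gc.dna_content(pop.ages, wt_params) * (1 + rng.normal(0, 0.05, n))
        se = 0.05 / np.sqrt(n)
        assert abs(content.mean() - 1.0) < 3 * se


class TestTemplateLibrary:
    def test_twenty_evenly_spaced_phases(self, noiseless_library):
        lib = noiseless_library
        assert lib.k == 20
        np.testing.assert_allclose(lib.phases, np.arange(20) / 20)

    def test_phase_zero_equals_fresh_pulse(self, wt_params, noiseless_library):
        lib = noiseless_library
        pop = gc.sample_steady_state(lib.n_sim, wt_params, 99)
        pop = gc.pulse_label(pop, lib.pulse_duration, wt_params)
        hp = gc.make_histogram_pair(pop, lib.bin_edges, wt_params)
        np.testing.assert_array_equal(hp.counts_pos, lib.templates[0].counts_pos)
        np.testing.assert_array_equal(hp.counts_neg, lib.templates[0].counts_neg)

    def test_periodicity_full_cycle_reproduces_phase_zero(self, wt_params):
        lib = gc.build_template_library(wt_params, k=4, n_sim=5000, seed=42)
        pop = gc.sample_steady_state(lib.n_sim, wt_params, 42)
        pop = gc.pulse_label(pop, lib.pulse_duration, wt_params)
        wrapped = gc.advance(pop, wt_params.t_c, wt_params)
        hp = gc.make_histogram_pair(wrapped, lib.bin_edges, wt_params)
        np.testing.assert_array_equal(hp.counts_pos, lib.templates[0].counts_pos)
        np.testing.assert_array_equal(hp.counts_neg, lib.templates[0].counts_neg)

    def test_k_below_two_rejected(self, wt_params):
        with pytest.raises(ValueError):
            gc.build_template_library(wt_params, k=1, n_sim=100)
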