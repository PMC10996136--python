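"""Forward simulator: task profiles, templates, firing, mixing, drift, force."""

import numpy as np
import pytest

from mudrive.core import GridGeometry
from mudrive.synthetic import (DriftSchedule, MotorUnitPool,
                               generate_muap_templates, ground_truth_force,
                               make_trapezoid_profile, simulate_firing,
                               simulate_session, SimulationConfig,
                               synthesize_emg)
from mudrive.twitch import contraction_time


class TestTrapezoidProfile:
    def test_paper_task_dimensions(self):
        prof = make_trapezoid_profile(0.20, 2, 3, 2000)
        assert prof.shape == (10000,)
        assert prof[0] == 0.0
        np.testing.assert_allclose(prof[4000:], 0.20)

    def test_thirty_percent_level(self):
        assert make_trapezoid_profile(0.30, 2, 3, 2000).max() == pytest.approx(0.30)

    def test_short_profile_endpoints(self):
        prof = make_trapezoid_profile(0.5, 1, 0.1, 10)
        assert prof[0] == 0.0
        assert prof[-1] == pytest.approx(0.5)

    def test_rejects_nonpositive_durations(self):
        with pytest.raises(ValueError):
            make_trapezoid_profile(0.2, 0, 3, 2000)


class TestTemplates:
    def test_seeded_generation_is_reproducible(self, grid):
        pool = MotorUnitPool()
        a = generate_muap_templates(pool, grid, seed=7)
        b = generate_muap_templates(pool, grid, seed=7)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.waveforms, tb.waveforms)

    def test_channels_are_zero_mean(self, grid):
        tpl = generate_muap_templates(MotorUnitPool(), grid, seed=1)[0]
        peak = np.abs(tpl.waveforms).max()
        assert np.abs(tpl.waveforms.mean(axis=1)).max() < 1e-9 * peak

    def test_grid_peak_to_peak_tracks_twitch_amplitude(self, grid):
        pool = MotorUnitPool(n_units=2,
                             recruitment_thresholds=np.array([0.1, 0.2]),
                             twitch_amplitudes=np.array([2.0, 1.0]))
        t2, t1 = generate_muap_templates(pool, grid, seed=0)
        ratio = t2.peak_to_peak.max() / t1.peak_to_peak.max()
        assert ratio == pytest.approx(2.0, abs=1e-6)

    def test_short_support_rejected(self, grid):
        with pytest.raises(ValueError):
            generate_muap_templates(MotorUnitPool(), grid, duration_ms=10)


class TestFiring:
    def test_silent_below_threshold(self):
        pool = MotorUnitPool()
        trains = simulate_firing(pool, np.zeros(4000), 2000.0)
        assert all(t.n_spikes == 0 for t in trains)

    def test_near_regular_isis_at_tiny_cv(self):
        pool = MotorUnitPool(n_units=1,
                             recruitment_thresholds=np.array([0.02]),
                             twitch_amplitudes=np.array([1.0]),
                             isi_cv=1e-4, peak_rate=35.0)
        (train,) = simulate_firing(pool, np.ones(20000), 2000.0)
        isis = np.diff(train.spikes)
        expected = 2000.0 / 35.0
        assert np.all(np.abs(isis - expected) <= 1.0)

    def test_seeded_runs_identical(self):
        pool = MotorUnitPool()
        exc = make_trapezoid_profile(0.3, 2, 3, 2000)
        a = simulate_firing(pool, exc, 2000.0, seed=5)
        b = simulate_firing(pool, exc, 2000.0, seed=5)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.spikes, tb.spikes)

    def test_rejects_excitation_outside_unit_interval(self):
        with pytest.raises(ValueError):
            simulate_firing(MotorUnitPool(), np.array([0.5, 1.5]), 2000.0)


class TestSynthesize:
    def test_single_spike_places_template(self, grid):
        pool = MotorUnitPool(n_units=1,
                             recruitment_thresholds=np.array([0.1]),
                             twitch_amplitudes=np.array([1.0]))
        (tpl,) = generate_muap_templates(pool, grid, seed=0)
        from tests.conftest import make_train
        rec = synthesize_emg([tpl], [make_train([500])], noise_snr_db=None,
                             drift=None, fs=2000.0, n_samples=2000)
        np.testing.assert_allclose(rec.samples[500:500 + tpl.length],
                                   tpl.waveforms.T, atol=1e-12)
        assert not rec.samples[:500].any()

    def test_noise_matches_requested_snr(self, grid):
        cfg = SimulationConfig(noise_snr_db=20.0, n_trials=1)
        rec = simulate_session(cfg)
        clean = rec.meta["clean"]
        noise = rec.samples - clean
        snr = 10 * np.log10(np.mean(clean**2) / np.mean(noise**2))
        assert snr == pytest.approx(20.0, abs=0.5)

    def test_linear_in_spike_trains_without_noise_or_drift(self, grid):
        pool = MotorUnitPool(n_units=2,
                             recruitment_thresholds=np.array([0.1, 0.2]))
        tpls = generate_muap_templates(pool, grid, seed=2)
        from tests.conftest import make_train
        t_a, t_b = make_train([100], mu_id=0), make_train([700], mu_id=1)
        both = synthesize_emg(tpls, [t_a, t_b], None, None, 2000.0,
                              n_samples=2000)
        only_a = synthesize_emg([tpls[0]], [t_a], None, None, 2000.0,
                                n_samples=2000, grid=grid)
        only_b = synthesize_emg([tpls[1]], [t_b], None, None, 2000.0,
                                n_samples=2000, grid=grid)
        np.testing.assert_allclose(both.samples,
                                   only_a.samples + only_b.samples, atol=1e-12)

    def test_drift_scales_late_amplitudes(self, grid):
        pool = MotorUnitPool(n_units=1,
                             recruitment_thresholds=np.array([0.1]))
        (tpl,) = generate_muap_templates(pool, grid, seed=0)
        from tests.conftest import make_train
        drift = DriftSchedule(amplitude_end=0.8, amplitude_spread=0.0,
                              template_morph=0.0, duration_s=10.0)
        train = make_train([100, 19600])
        rec = synthesize_emg([tpl], [train], None, drift, 2000.0,
                             n_samples=20000)
        early = np.ptp(rec.samples[100:100 + tpl.length], axis=0).max()
        late = np.ptp(rec.samples[19600:19600 + tpl.length], axis=0).max()
        assert late / early == pytest.approx(0.8, abs=0.01)

    def test_snr_on_silence_rejected(self, grid):
        tpl = generate_muap_templates(MotorUnitPool(), grid, seed=0)[0]
        from tests.conftest import make_train
        with pytest.raises(ValueError):
            synthesize_emg([tpl], [make_train([])], noise_snr_db=20.0,
                           drift=None, fs=2000.0, n_samples=1000)


class TestGroundTruthForce:
    def test_no_spikes_no_force(self):
        from tests.conftest import make_train
        force = ground_truth_force([make_train([])], np.array([1.0]), 2000.0,
                                   1000)
        assert not force.any()

    def test_single_twitch_peaks_at_contraction_time(self):
        from tests.conftest import make_train
        force = ground_truth_force([make_train([200])], np.array([1.0]),
                                   2000.0, 2000, normalize=False)
        t_peak = (force.argmax() - 200) / 2000.0
        assert t_peak == pytest.approx(contraction_time(1.0), abs=1e-3)
        assert force.max() == pytest.approx(1.0, rel=1e-3)

    def test_distant_spikes_superpose(self):
        from tests.conftest import make_train
        both = ground_truth_force([make_train([200, 1800])], np.array([1.0]),
                                  2000.0, 4000, normalize=False)
        one = ground_truth_force([make_train([200])], np.array([1.0]),
                                 2000.0, 4000, normalize=False)
        two = ground_truth_force([make_train([1800])], np.array([1.0]),
                                 2000.0, 4000, normalize=False)
        np.testing.assert_allclose(both, one + two, atol=1e-10)

    def test_ramp_force_is_nondecreasing_for_regular_single_unit(self):
        pool = MotorUnitPool(n_units=1,
                             recruitment_thresholds=np.array([0.02]),
                             isi_cv=1e-4)
        exc = make_trapezoid_profile(0.3, 2, 3, 2000)
        (train,) = simulate_firing(pool, exc, 2000.0, seed=0)
        force = ground_truth_force([train], np.array([1.0]), 2000.0, exc.size)
        ramp = force[train.spikes[0]:4000]
        drops = np.diff(ramp)
        # sampling/tetanic ripple only: no decrease beyond 5% of the range
        assert drops.min() > -0.05 * ramp.max()


class TestSessionReproducibility:
    def test_seeded_session_is_bit_identical(self):
        a = simulate_session(SimulationConfig(seed=3, n_trials=1))
        b = simulate_session(SimulationConfig(seed=3, n_trials=1))
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.force, b.force)
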