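"""Twitch-force model: analytic values, continuity, and a brute-force oracle."""

import numpy as np
import pytest

from mudrive.core import GridGeometry
from mudrive.twitch import (GAIN_KNEE, K_GAIN, TwitchParams, build_feature_window,
                            contraction_time, discharge_gain, discharge_gains,
                            feature_windows, spikes_to_twitch_train,
                            twitch_kernel, twitch_trains_for_bank)
from tests.conftest import make_template, make_train

PARAMS = TwitchParams()


class TestContractionTime:
    def test_unit_amplitude_gives_maximal_contraction_time(self):
        assert contraction_time(1.0) == pytest.approx(0.090, abs=1e-12)

    def test_power_law_value(self):
        # direct evaluation of 0.09 * 16^(-1/4.2)
        assert contraction_time(16.0) == pytest.approx(
            0.090 * 16.0 ** (-1.0 / 4.2), rel=1e-12)

    def test_monotone_decreasing_in_amplitude(self):
        p = np.linspace(1.0, 50.0, 200)
        t = contraction_time(p)
        assert np.all(np.diff(t) < 0)

    def test_capped_at_maximal_contraction_time(self):
        assert contraction_time(0.25) == pytest.approx(0.090)

    def test_rejects_nonpositive_amplitude(self):
        with pytest.raises(ValueError):
            contraction_time(0.0)


class TestTwitchKernel:
    def test_peak_is_amplitude_at_contraction_time(self):
        p, t_c = 3.7, 0.055
        t = np.linspace(0, 0.5, 20001)
        values = twitch_kernel(p, t_c, t)
        k = values.argmax()
        assert abs(t[k] - t_c) < 1e-3
        assert values.max() == pytest.approx(p, rel=1e-6)

    def test_zero_at_origin(self):
        assert twitch_kernel(1.0, 0.09, np.array([0.0]))[0] == 0.0

    def test_value_at_twice_contraction_time(self):
        t_c = 0.09
        val = twitch_kernel(1.0, t_c, np.array([2 * t_c]))[0]
        assert val == pytest.approx(2 * np.e**-1, rel=1e-12)

    def test_rejects_nonpositive_contraction_time(self):
        with pytest.raises(ValueError):
            twitch_kernel(1.0, 0.0, np.array([0.1]))


class TestDischargeGain:
    def test_unity_below_knee(self):
        # normalized stimulus rate 0.25 -> low-rate branch
        assert discharge_gain(0.09, 0.09 / 0.25) == 1.0

    def test_continuous_at_knee(self):
        eps = 1e-9
        below = discharge_gain(GAIN_KNEE - eps, 1.0)
        above = discharge_gain(GAIN_KNEE + eps, 1.0)
        assert abs(below - above) < 1e-6

    def test_continuity_constant(self):
        assert K_GAIN == pytest.approx(0.4 / (1 - np.exp(-2 * 0.4**3)), rel=1e-12)

    def test_nonlinear_branch_formula(self):
        x = 0.8
        expected = K_GAIN * (1 - np.exp(-2 * x**3)) / x
        assert discharge_gain(x, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_first_discharge_gets_unit_gain(self):
        gains = discharge_gains(np.array([100, 130, 160]), 0.09, 2000.0)
        assert gains[0] == 1.0
        assert gains.shape == (3,)

    def test_rejects_nonpositive_isi(self):
        with pytest.raises(ValueError):
            discharge_gain(0.09, 0.0)


def brute_force_twitch_train(spikes, template, n_samples, fs):
    """Independent per-discharge summation of the gain-scaled kernel."""
    params = TwitchParams()
    out = np.zeros((n_samples, template.n_channels))
    ptp = template.peak_to_peak
    for c in range(template.n_channels):
        p = ptp[c]
        if p <= 0:
            continue
        t_c = min(params.t_max * (1.0 / p) ** (1.0 / params.c), params.t_max)
        for j, s in enumerate(spikes.spikes):
            if j == 0:
                g = 1.0
            else:
                isi = (spikes.spikes[j] - spikes.spikes[j - 1]) / fs
                x = t_c / isi
                g = 1.0 if x <= 0.4 else K_GAIN * (1 - np.exp(-2 * x**3)) / x
            for i in range(s, n_samples):
                t = (i - s) / fs
                v = p * t / t_c * np.exp(1 - t / t_c)
                if t / t_c > 1 and v < 1e-4 * p:
                    break
                out[i, c] += g * v
    return out


class TestSpikesToTwitchTrain:
    def test_single_spike_is_scaled_kernel(self):
        tpl = make_template(n_channels=4, amp=8.0)
        train = make_train([100])
        out = spikes_to_twitch_train(train, tpl, 2000)
        fs = 2000.0
        for c in range(4):
            p = tpl.peak_to_peak[c]
            t_c = contraction_time(p)
            t = np.arange(2000 - 100) / fs
            expected = twitch_kernel(p, t_c, t)
            np.testing.assert_allclose(out[100:, c], expected, atol=1e-12)
        assert np.all(out[:100] == 0)

    def test_two_slow_spikes_superpose_unscaled(self):
        # T/ISI = 0.2 -> both kernels at gain 1
        tpl = make_template(n_channels=2, amp=4.0)
        fs = 2000.0
        t_c = contraction_time(tpl.peak_to_peak.max())
        isi = int(round(t_c / 0.2 * fs))
        train = make_train([50, 50 + isi])
        n = 50 + isi + 3000
        out = spikes_to_twitch_train(train, tpl, n)
        single_a = spikes_to_twitch_train(make_train([50]), tpl, n)
        single_b = spikes_to_twitch_train(make_train([50 + isi]), tpl, n)
        np.testing.assert_allclose(out, single_a + single_b, atol=1e-10)

    def test_matches_brute_force_oracle(self):
        tpl = make_template(n_channels=6, amp=12.0, seed=3)
        train = make_train([60, 160, 230, 300, 420])  # 30 Hz-ish, rate gain active
        n = 1200
        fast = spikes_to_twitch_train(train, tpl, n)
        slow = brute_force_twitch_train(train, tpl, n, 2000.0)
        np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_empty_train_is_silent(self):
        tpl = make_template(n_channels=4)
        out = spikes_to_twitch_train(make_train([]), tpl, 500)
        assert not out.any()


class TestFeatureWindow:
    def test_tensor_shape_is_grid_by_units(self, grid):
        trains = [make_train([100 + 37 * i]) for i in range(5)]
        tpls = [make_template(mu_id=i, seed=i) for i in range(5)]
        stacked = twitch_trains_for_bank(trains, tpls, 800)
        fw = build_feature_window(stacked, 0, grid, np.linspace(0, 1, 800))
        assert fw.tensor.shape == (400, 8, 8, 5)
        assert fw.label.shape == (400,)

    def test_grid_reshape_roundtrip(self, grid):
        x = np.arange(64.0)
        np.testing.assert_array_equal(grid.to_channels(grid.to_grid(x)), x)

    def test_empty_trains_give_zero_tensor(self, grid):
        stacked = twitch_trains_for_bank(
            [make_train([])], [make_template()], 400)
        fw = build_feature_window(stacked, 0, grid, np.zeros(400))
        assert not fw.tensor.any()

    def test_window_beyond_data_rejected(self, grid):
        stacked = twitch_trains_for_bank([make_train([])], [make_template()], 500)
        with pytest.raises(ValueError):
            build_feature_window(stacked, 200, grid, np.zeros(500))

    def test_tiling_covers_record_in_steps(self, grid):
        stacked = twitch_trains_for_bank([make_train([10])], [make_template()],
                                         2000)
        windows = feature_windows(stacked, np.zeros(2000), grid)
        assert [w.start_sample for w in windows] == [0, 400, 800, 1200, 1600]
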