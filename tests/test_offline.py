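"""Offline decomposition building blocks on small constructed instances."""

import numpy as np
import pytest

from mudrive.core import EmgRecording, SpikeTrain
from mudrive.offline import (EmptyBankError, estimate_muap, fastica_one_unit,
                             otsu_spike_detect, peel_off, reconstruct_train,
                             run_apfp, unit_quality)
from mudrive.preprocess import apply_whitening, extend, fit_whitening
from tests.conftest import make_template, make_train

FS = 2000.0


def sparse_source(rng, n, n_spikes, amp=8.0):
    s = rng.standard_normal(n) * 0.1
    idx = np.sort(rng.choice(np.arange(50, n - 50, 25), n_spikes,
                             replace=False))
    s[idx] += amp
    return s, idx


class TestFastIcaOneUnit:
    def _toy_mixture(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 6000
        s1, _ = sparse_source(rng, n, 60)
        s2, _ = sparse_source(rng, n, 55)
        mixing = rng.standard_normal((2, 6))
        x = np.stack([s1, s2], axis=1) @ mixing
        model = fit_whitening(x, 1)
        z = apply_whitening(model, x)
        return z, s1, s2

    def test_recovers_a_true_source(self):
        z, s1, s2 = self._toy_mixture()
        vec = fastica_one_unit(z, seed=3)
        src = z @ vec.weights
        corr = max(abs(np.corrcoef(src, s1)[0, 1]),
                   abs(np.corrcoef(src, s2)[0, 1]))
        assert corr > 0.99

    def test_same_seed_same_vector_up_to_sign(self):
        z, *_ = self._toy_mixture()
        a = fastica_one_unit(z, seed=11)
        b = fastica_one_unit(z, seed=11)
        assert abs(a.weights @ b.weights) == pytest.approx(1.0, abs=1e-12)

    def test_true_unmixing_row_is_a_fast_fixed_point(self):
        z, s1, _ = self._toy_mixture()
        w_true = z.T @ s1 / z.shape[0]
        vec = fastica_one_unit(z, init_vector=w_true, max_iter=2)
        assert vec.converged

    def test_output_is_unit_norm(self):
        z, *_ = self._toy_mixture()
        vec = fastica_one_unit(z, seed=0)
        assert np.linalg.norm(vec.weights) == pytest.approx(1.0)


class TestOtsuSpikeDetect:
    def test_detects_clean_peaks(self, rng):
        src = np.zeros(8000)
        idx = np.arange(100, 8000, 150)
        src[idx] = 1.0
        train = otsu_spike_detect(src, FS)
        np.testing.assert_array_equal(train.spikes, idx)

    def test_flat_source_gives_empty_train(self):
        assert otsu_spike_detect(np.zeros(1000), FS).n_spikes == 0

    def test_successive_step_drops_distinctly_low_class(self, rng):
        src = rng.normal(0, 0.01, 12000)
        tall = np.arange(100, 6000, 290)
        small = np.arange(6100, 12000, 290)
        src[tall] = 1.0
        src[small] = 0.1
        train = otsu_spike_detect(src, FS)
        assert set(train.spikes) == set(tall)

    def test_unimodal_heights_are_kept_whole(self, rng):
        # tightly clustered spike heights must not be split in half by the
        # successive step (bimodality guard)
        src = rng.normal(0, 0.005, 12000)
        idx = np.arange(100, 12000, 140)
        src[idx] = rng.uniform(0.9, 1.1, idx.size)
        train = otsu_spike_detect(src, FS)
        assert train.n_spikes == idx.size


class TestUnitQuality:
    def test_clean_regular_unit_accepted(self, rng):
        src = rng.normal(0, 0.02, 30000)
        idx = np.arange(200, 29800, 130)  # ~15 Hz regular
        src[idx] += 1.0
        train = make_train(idx)
        score, ok = unit_quality(train, src)
        assert ok
        assert score > 4

    def test_white_noise_detection_rejected(self, rng):
        src = rng.standard_normal(20000)
        train = otsu_spike_detect(src, FS)
        if train.n_spikes >= 2:
            _, ok = unit_quality(train, src)
            assert not ok

    def test_single_spike_rejected(self, rng):
        src = rng.normal(0, 0.01, 2000)
        src[500] = 1.0
        _, ok = unit_quality(make_train([500]), src)
        assert not ok


class TestEstimateMuap:
    def test_noiseless_recovery_is_exact(self):
        tpl = make_template(n_channels=8, length=40, amp=50.0)
        spikes = make_train(np.arange(300, 9500, 400))
        signal = reconstruct_train(tpl, spikes, 10000)
        est = estimate_muap(signal, spikes, pre_s=0.0, post_s=0.02)
        np.testing.assert_allclose(est.waveforms, tpl.waveforms, atol=1e-8)

    def test_matches_brute_force_normal_equations(self, rng):
        tpl = make_template(n_channels=3, length=30, amp=20.0, seed=9)
        # overlapping spikes: ISIs shorter than the template
        spikes = make_train(np.sort(rng.choice(np.arange(100, 3900, 18), 40,
                                               replace=False)))
        signal = reconstruct_train(tpl, spikes, 4000)
        signal += rng.normal(0, 0.5, signal.shape)
        est = estimate_muap(signal, spikes, pre_s=0.0, post_s=0.015)
        # independent dense solver
        length = 30
        s_mat = np.zeros((4000, length))
        for s in spikes.spikes:
            for k in range(length):
                if s + k < 4000:
                    s_mat[s + k, k] += 1.0
        brute, *_ = np.linalg.lstsq(s_mat, signal, rcond=None)
        np.testing.assert_allclose(est.waveforms, brute.T, atol=1e-6)

    def test_sta_equivalence_for_separated_spikes(self, rng):
        tpl = make_template(n_channels=4, length=30, amp=10.0, seed=2)
        spikes = make_train(np.arange(200, 7800, 500))
        signal = reconstruct_train(tpl, spikes, 8000)
        noise = rng.normal(0, 1.0, signal.shape)
        est = estimate_muap(signal + noise, spikes, pre_s=0.0, post_s=0.015)
        sta = np.stack([(signal + noise)[spikes.spikes + k].mean(axis=0)
                        for k in range(30)], axis=1)
        np.testing.assert_allclose(est.waveforms, sta, atol=1e-6)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            estimate_muap(np.zeros((100, 4)), make_train([]))


class TestPeelOff:
    def test_peeling_own_signal_leaves_nothing(self):
        tpl = make_template(n_channels=6, amp=30.0)
        spikes = make_train(np.arange(100, 3900, 300))
        signal = reconstruct_train(tpl, spikes, 4000)
        residual = peel_off(signal, [tpl], [spikes])
        assert np.sum(residual**2) < 1e-10 * np.sum(signal**2)

    def test_empty_trains_are_identity(self, rng):
        signal = rng.standard_normal((500, 4))
        residual = peel_off(signal, [make_template(n_channels=4)],
                            [make_train([])])
        np.testing.assert_array_equal(residual, signal)

    def test_peeling_one_of_two_units_leaves_the_other(self):
        tpl_a = make_template(mu_id=0, n_channels=6, amp=30.0, seed=1)
        tpl_b = make_template(mu_id=1, n_channels=6, amp=20.0, seed=2)
        tr_a = make_train(np.arange(100, 3900, 310))
        tr_b = make_train(np.arange(150, 3900, 270), mu_id=1)
        signal = (reconstruct_train(tpl_a, tr_a, 4000)
                  + reconstruct_train(tpl_b, tr_b, 4000))
        residual = peel_off(signal, [tpl_a], [tr_a])
        np.testing.assert_allclose(residual,
                                   reconstruct_train(tpl_b, tr_b, 4000),
                                   atol=1e-10)


class TestRunApfpGuards:
    def test_short_recording_rejected(self, rng, grid):
        rec = EmgRecording(samples=rng.standard_normal((2000, 64)), fs=FS,
                           grid=grid)
        with pytest.raises(ValueError):
            run_apfp(rec)

    def test_pure_noise_yields_empty_bank_error(self, rng, grid):
        rec = EmgRecording(samples=rng.standard_normal((12000, 64)), fs=FS,
                           grid=grid)
        with pytest.raises(EmptyBankError):
            run_apfp(rec)
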