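"""Shared fixtures.

The heavy pipeline stages (offline decomposition, network training, online
streaming over the drifting test stream) are computed once per session at
the default study conditions (15-s stationary training data; 60-s drifting
test stream; 10-unit pool; 20 dB SNR; seed 0) and shared by the unit and
acceptance tests that need them.
"""

from __future__ import annotations

import numpy as np
import pytest

from mudrive.adaptive import UpdateConfig, make_update_hook
from mudrive.core import GridGeometry, MuapTemplate, SpikeTrain
from mudrive.experiment import (ExperimentConfig, run_experiment,
                                simulate_test_session,
                                simulate_training_session, train_stage)
from mudrive.offline import run_apfp
from mudrive.online import stream_decompose

STUDY_SEED = 0


@pytest.fixture(scope="session")
def study_cfg() -> ExperimentConfig:
    return ExperimentConfig(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def training_session(study_cfg):
    return simulate_training_session(study_cfg)


@pytest.fixture(scope="session")
def trained(study_cfg, training_session):
    """(bank, offline spike trains, trained force model)."""
    return train_stage(study_cfg, training_session)


@pytest.fixture(scope="session")
def bank(trained):
    return trained[0]


@pytest.fixture(scope="session")
def offline_trains(trained):
    return trained[1]


@pytest.fixture(scope="session")
def test_session(study_cfg):
    return simulate_test_session(study_cfg)


@pytest.fixture(scope="session")
def stationary_online_trains(training_session, bank):
    """Online decomposition of the (stationary) training record, no updates."""
    return stream_decompose(training_session.recording, bank)


@pytest.fixture(scope="session")
def drift_streams(study_cfg, test_session, bank):
    """(frozen trains, updated trains, update events) on the drifting stream."""
    events = []
    hook = make_update_hook(test_session.recording, study_cfg.update, events)
    updated = stream_decompose(test_session.recording, bank, update_hook=hook,
                               update_period_s=study_cfg.update.period_s)
    frozen = stream_decompose(test_session.recording, bank)
    return frozen, updated, events


@pytest.fixture(scope="session")
def experiment_result(study_cfg, trained, test_session, drift_streams):
    return run_experiment(study_cfg, trained=trained, test=test_session,
                          streams=drift_streams)


# ---- small deterministic helpers used by unit tests ----

@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def grid():
    return GridGeometry()


def make_template(mu_id: int = 0, n_channels: int = 64, length: int = 40,
                  amp: float = 100.0, seed: int = 0) -> MuapTemplate:
    """A deterministic synthetic biphasic template for small tests."""
    rng = np.random.default_rng(seed)
    t = np.arange(length) - length // 2
    wave = t * np.exp(-(t / 6.0) ** 2)
    wave -= wave.mean()
    wave /= np.abs(wave).max()
    spatial = rng.uniform(0.1, 1.0, n_channels)
    spatial[rng.integers(n_channels)] = 1.0
    return MuapTemplate(mu_id=mu_id, waveforms=np.outer(spatial, wave) * amp)


def make_train(spikes, fs: float = 2000.0, mu_id: int = 0) -> SpikeTrain:
    return SpikeTrain(mu_id=mu_id, spikes=np.asarray(spikes, dtype=np.int64),
                      fs=fs)
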