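"""End-to-end experiment harness: update / no-update / FR / RMS arms.

Reproduces the study design on synthetic data: a stationary training session
initializes the separation bank and the force network; a longer drifting
test stream is then decomposed online with and without the backend update,
and the predicted force of the proposed method is compared against the two
conventional regression baselines (firing rate and RMS amplitude).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adaptive import UpdateConfig, UpdateEvent, make_update_hook
from .core import EmgRecording, GridGeometry, SpikeTrain
from .forcenet import (ForceNet, NetConfig, baseline_fr, baseline_rms,
                       predict_window, stitch, train)
from .metrics import best_lag_match, pair_musts, r_squared, rmsd
from .offline import ApfpConfig, SeparationBank, run_apfp
from .online import stream_decompose
from .preprocess import bandpass_notch
from .synthetic import (DriftSchedule, MotorUnitPool, generate_muap_templates,
                        ground_truth_force, repeated_trapezoids,
                        simulate_firing, synthesize_emg)
from .twitch import feature_windows, twitch_trains_for_bank

logger = logging.getLogger(__name__)

#: Samples before the first committed window (1-s window minus 0.2-s step).
WARMUP_SAMPLES = 1600
WINDOW_SAMPLES = 400


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions for one synthetic experiment."""

    pool: MotorUnitPool = field(default_factory=MotorUnitPool)
    grid: GridGeometry = field(default_factory=GridGeometry)
    fs: float = 2000.0
    level: float = 0.30
    ramp_s: float = 2.0
    hold_s: float = 3.0
    train_trials: int = 3      # 15 s of training data
    test_trials: int = 12      # 60 s drifting test stream
    noise_snr_db: float = 20.0
    drift: DriftSchedule = field(default_factory=lambda: DriftSchedule(
        amplitude_end=0.8, template_morph=0.2, onset_s=0.0, duration_s=60.0))
    apfp: ApfpConfig = field(default_factory=ApfpConfig)
    update: UpdateConfig = field(default_factory=UpdateConfig)
    net: NetConfig = field(default_factory=NetConfig)
    seed: int = 0


@dataclass
class SessionData:
    recording: EmgRecording      # filtered
    raw: EmgRecording
    true_trains: list[SpikeTrain]
    force: np.ndarray            # normalized ground-truth force


def _simulate(cfg: ExperimentConfig, templates, n_trials: int,
              drift: DriftSchedule | None, firing_seed: int,
              noise_seed: int) -> SessionData:
    excitation = repeated_trapezoids(cfg.level, cfg.ramp_s, cfg.hold_s,
                                     cfg.fs, n_trials)
    trains = simulate_firing(cfg.pool, excitation, cfg.fs, seed=firing_seed)
    n = excitation.size
    force = ground_truth_force(trains, cfg.pool.twitch_amplitudes, cfg.fs, n,
                               normalize=False)
    peak = force.max() if force.max() > 0 else 1.0
    force = cfg.level * force / peak
    raw = synthesize_emg(templates, trains, cfg.noise_snr_db, drift, cfg.fs,
                         seed=noise_seed, grid=cfg.grid, n_samples=n,
                         force=force)
    return SessionData(recording=bandpass_notch(raw), raw=raw,
                       true_trains=trains, force=force)


def simulate_training_session(cfg: ExperimentConfig) -> SessionData:
    templates = generate_muap_templates(cfg.pool, cfg.grid, fs=cfg.fs,
                                        seed=cfg.seed)
    return _simulate(cfg, templates, cfg.train_trials, drift=None,
                     firing_seed=cfg.seed + 1, noise_seed=cfg.seed + 2)


def simulate_test_session(cfg: ExperimentConfig) -> SessionData:
    templates = generate_muap_templates(cfg.pool, cfg.grid, fs=cfg.fs,
                                        seed=cfg.seed)  # same muscle
    return _simulate(cfg, templates, cfg.test_trials, drift=cfg.drift,
                     firing_seed=cfg.seed + 3, noise_seed=cfg.seed + 4)


def train_stage(cfg: ExperimentConfig, session: SessionData
                ) -> tuple[SeparationBank, list[SpikeTrain], ForceNet]:
    """Offline decomposition + network training on the stationary session."""
    bank, offline_trains = run_apfp(session.recording, cfg.apfp, seed=cfg.seed)
    trains_tensor = twitch_trains_for_bank(offline_trains, bank.templates,
                                           session.recording.n_samples)
    windows = feature_windows(trains_tensor, session.force, cfg.grid,
                              WINDOW_SAMPLES)
    model = ForceNet(bank.n_units, cfg.net, (cfg.grid.rows, cfg.grid.cols))
    train(model, windows, cfg.net)
    return bank, offline_trains, model


def predict_force(model: ForceNet, bank: SeparationBank,
                  committed: list[SpikeTrain], session: SessionData,
                  grid: GridGeometry) -> np.ndarray:
    """Twitch features from committed trains -> stitched network prediction.

    Twitch trains use the training-stage MUAP templates (per-MU identity is
    fixed by the bank), starting at the 0.8-s warmup boundary.
    """
    n = session.recording.n_samples
    tensor = twitch_trains_for_bank(committed, bank.templates, n)
    windows = feature_windows(tensor, session.force, grid, WINDOW_SAMPLES,
                              start=WARMUP_SAMPLES)
    outputs = [predict_window(model, w) for w in windows]
    return stitch(windows, outputs, WINDOW_SAMPLES)


def mean_accuracy(committed: list[SpikeTrain], reference: list[SpikeTrain],
                  start: int = WARMUP_SAMPLES) -> float:
    """Mean best-match MR of committed trains vs a reference set, after warmup."""
    clipped_c = [SpikeTrain(t.mu_id, t.spikes[t.spikes >= start], t.fs)
                 for t in committed]
    clipped_r = [SpikeTrain(t.mu_id, t.spikes[t.spikes >= start], t.fs)
                 for t in reference]
    accuracies = []
    for tr in clipped_c:
        best = max(best_lag_match(tr, ref)[0].mr for ref in clipped_r)
        accuracies.append(best)
    return float(np.mean(accuracies))


@dataclass
class ExperimentResult:
    table: pd.DataFrame
    accuracy_update: float
    accuracy_no_update: float
    update_events: list[UpdateEvent]
    bank_size: int


def run_experiment(cfg: ExperimentConfig = ExperimentConfig(),
                   trained: tuple | None = None,
                   test: SessionData | None = None,
                   streams: tuple | None = None) -> ExperimentResult:
    """Run all four arms and return the per-arm metrics table.

    ``trained`` (bank, offline trains, model), ``test`` and ``streams``
    (frozen trains, updated trains, update events) can be passed in to
    reuse precomputed stages.
    """
    training = None
    if trained is None:
        training = simulate_training_session(cfg)
        trained = train_stage(cfg, training)
    bank, offline_trains, model = trained
    if test is None:
        test = simulate_test_session(cfg)
    fs = cfg.fs

    if streams is None:
        events: list[UpdateEvent] = []
        hook = make_update_hook(test.recording, cfg.update, events)
        trains_update = stream_decompose(test.recording, bank,
                                         update_hook=hook,
                                         update_period_s=cfg.update.period_s)
        trains_frozen = stream_decompose(test.recording, bank,
                                         update_hook=None)
    else:
        trains_frozen, trains_update, events = streams

    eval_slice = slice(WARMUP_SAMPLES, WARMUP_SAMPLES + (
        (test.recording.n_samples - WARMUP_SAMPLES) // WINDOW_SAMPLES)
        * WINDOW_SAMPLES)
    meas = test.force[eval_slice]

    pred_update = predict_force(model, bank, trains_update, test, cfg.grid)
    pred_frozen = predict_force(model, bank, trains_frozen, test, cfg.grid)

    if training is None:
        training = simulate_training_session(cfg)
    fr = baseline_fr(offline_trains, training.force, fs)
    rms = baseline_rms(training.recording.samples, training.force, fs)
    pred_fr = fr.predict(trains_update, test.recording.n_samples)[eval_slice]
    pred_rms = rms.predict(test.recording.samples,
                           test.recording.n_samples)[eval_slice]

    rows = []
    for arm, pred in (("proposed_update", pred_update),
                      ("proposed_no_update", pred_frozen),
                      ("fr", pred_fr), ("rms", pred_rms)):
        rows.append({"arm": arm, "seed": cfg.seed, "level": cfg.level,
                     "rmsd_pct": rmsd(pred, meas),
                     "r2": r_squared(pred, meas)})
    acc_update = mean_accuracy(trains_update, test.true_trains)
    acc_frozen = mean_accuracy(trains_frozen, test.true_trains)
    return ExperimentResult(table=pd.DataFrame(rows),
                            accuracy_update=acc_update,
                            accuracy_no_update=acc_frozen,
                            update_events=events,
                            bank_size=bank.n_units)
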