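"""Forward simulator for high-density surface EMG during isometric tasks.

Emulates an 8x8 electrode grid over a small hand muscle performing trapezoid
force tasks (ramp to 20-30 % MVC, then hold): a rate-coded motor unit pool
fires, each discharge leaves a spatiotemporal MUAP on the grid, channels sum
linearly, and white Gaussian noise is added.  A drift schedule applies slow
per-channel amplitude decay and waveform morphing to emulate the
nonstationarity (fiber-length and conduction-velocity changes) that degrades
a frozen decomposition over time.

The firing model is Fuglevand-style rate coding: a unit is recruited when the
excitation drive exceeds its threshold, its instantaneous rate interpolates
linearly between a minimum and peak rate with excitation, and inter-spike
intervals are Gaussian with a fixed coefficient of variation, floored at a
10-ms refractory period.  Twitch amplitudes follow the size principle
(recruitment order = amplitude order), so the same pool parameterizes both
the electrical and the mechanical (ground-truth force) side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import REFRACTORY_S, EmgRecording, GridGeometry, MuapTemplate, SpikeTrain
from .twitch import TwitchParams, contraction_time, discharge_gains, kernel_support_samples, twitch_kernel

#: Grid-max peak-to-peak amplitude of a unit with twitch amplitude 1, µV.
UV_PER_TWITCH_UNIT = 80.0


@dataclass(frozen=True)
class MotorUnitPool:
    """A recruitment-ordered pool of motor units."""

    n_units: int = 10
    recruitment_thresholds: np.ndarray | None = None
    min_rate: float = 8.0
    peak_rate: float = 35.0
    isi_cv: float = 0.15
    twitch_amplitudes: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("pool needs at least one unit")
        if not 0 < self.isi_cv < 1:
            raise ValueError("isi_cv must be in (0, 1)")
        if self.recruitment_thresholds is None:
            thr = np.linspace(0.02, 0.25, self.n_units)
            object.__setattr__(self, "recruitment_thresholds", thr)
        else:
            thr = np.asarray(self.recruitment_thresholds, dtype=np.float64)
            if np.any(np.diff(thr) <= 0):
                raise ValueError("recruitment thresholds must be strictly increasing")
            object.__setattr__(self, "recruitment_thresholds", thr)
        if self.twitch_amplitudes is None:
            # size principle: amplitude grows geometrically with threshold rank
            amps = np.geomspace(1.0, 5.0, self.n_units)
            object.__setattr__(self, "twitch_amplitudes", amps)
        else:
            amps = np.asarray(self.twitch_amplitudes, dtype=np.float64)
            if np.any(amps <= 0):
                raise ValueError("twitch amplitudes must be positive")
            object.__setattr__(self, "twitch_amplitudes", amps)
        for arr, name in ((self.recruitment_thresholds, "thresholds"),
                          (self.twitch_amplitudes, "amplitudes")):
            if arr.shape != (self.n_units,):
                raise ValueError(f"{name} must have length n_units")


@dataclass(frozen=True)
class DriftSchedule:
    """Slow nonstationarity applied to the MUAP templates over a trial.

    Each channel ramps linearly from gain 1.0 (at ``onset_s``) to its own
    endpoint, drawn once per simulation from
    ``amplitude_end ± amplitude_spread``; the per-channel differences are
    what actually rotate the mixing vectors (a uniform gain would only
    rescale the sources).  ``template_morph`` is the fraction of a
    1-sample-shifted template mixed in at the end of the ramp.
    """

    amplitude_end: float = 0.8
    amplitude_spread: float = 0.15
    template_morph: float = 0.2
    onset_s: float = 0.0
    duration_s: float = 60.0

    def __post_init__(self) -> None:
        if self.amplitude_end - self.amplitude_spread <= 0:
            raise ValueError("amplitude multipliers must stay positive")
        if not 0 <= self.template_morph <= 1:
            raise ValueError("morph fraction must be in [0, 1]")

    def channel_endpoints(self, n_channels: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return self.amplitude_end + self.amplitude_spread * rng.uniform(
            -1.0, 1.0, n_channels)

    def progress(self, t_s: float | np.ndarray) -> np.ndarray:
        """Drift progress in [0, 1] at time t (seconds)."""
        t_s = np.asarray(t_s, dtype=np.float64)
        if self.duration_s <= 0:
            return np.where(t_s >= self.onset_s, 1.0, 0.0)
        return np.clip((t_s - self.onset_s) / self.duration_s, 0.0, 1.0)


def make_trapezoid_profile(level: float, ramp_s: float, hold_s: float,
                           fs: float) -> np.ndarray:
    """Trapezoid excitation/force profile: linear ramp then constant hold."""
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    if ramp_s <= 0 or hold_s <= 0:
        raise ValueError("ramp and hold durations must be positive")
    n = int(round((ramp_s + hold_s) * fs))
    t = np.arange(n) / fs
    return level * np.clip(t / ramp_s, 0.0, 1.0)


def repeated_trapezoids(level: float, ramp_s: float, hold_s: float,
                        fs: float, n_trials: int) -> np.ndarray:
    """Back-to-back trapezoid trials (the repeated 5-s task protocol)."""
    one = make_trapezoid_profile(level, ramp_s, hold_s, fs)
    return np.tile(one, n_trials)


def _spatial_profile(grid: GridGeometry, center: tuple[float, float],
                     sigma: float) -> np.ndarray:
    rows = np.arange(grid.rows)[:, None]
    cols = np.arange(grid.cols)[None, :]
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    profile = np.exp(-d2 / (2.0 * sigma**2)).ravel()
    return profile / profile.max()  # grid maximum carries the nominal amplitude


def _temporal_waveform(length: int, fs: float, width_ms: float,
                       triphasic_mix: float) -> np.ndarray:
    """Zero-mean biphasic/triphasic waveform from Gaussian derivatives."""
    t = (np.arange(length) - length // 2) / fs
    s = width_ms * 1e-3
    g1 = -t / s**2 * np.exp(-(t**2) / (2 * s**2))             # biphasic
    g2 = (t**2 / s**4 - 1 / s**2) * np.exp(-(t**2) / (2 * s**2))  # triphasic
    w = (1 - triphasic_mix) * g1 / np.abs(g1).max() + triphasic_mix * g2 / np.abs(g2).max()
    w -= w.mean()
    return w / (w.max() - w.min())


def generate_muap_templates(pool: MotorUnitPool, grid: GridGeometry,
                            duration_ms: float = 20.0, fs: float = 2000.0,
                            seed: int = 0) -> list[MuapTemplate]:
    """One spatiotemporal MUAP template per unit.

    Each template is a smooth unimodal spatial profile (distinct territory
    center per unit) times a zero-mean biphasic/triphasic temporal waveform,
    scaled so the grid-maximum peak-to-peak amplitude is proportional to the
    unit's twitch amplitude.
    """
    if duration_ms < 15.0:
        raise ValueError("duration_ms must cover the MUAP support (>= 15 ms)")
    rng = np.random.default_rng(seed)
    length = int(round(duration_ms * 1e-3 * fs))
    templates = []
    for i in range(pool.n_units):
        center = (rng.uniform(1, grid.rows - 2), rng.uniform(1, grid.cols - 2))
        sigma = rng.uniform(1.2, 2.2)
        spatial = _spatial_profile(grid, center, sigma)
        width = rng.uniform(1.5, 3.0)
        mix = rng.uniform(0.0, 1.0)
        wave = _temporal_waveform(length, fs, width, mix)
        target_ptp = UV_PER_TWITCH_UNIT * pool.twitch_amplitudes[i]
        waveforms = np.outer(spatial, wave) * target_ptp
        templates.append(MuapTemplate(mu_id=i, waveforms=waveforms))
    return templates


def simulate_firing(pool: MotorUnitPool, excitation: np.ndarray, fs: float,
                    seed: int = 0) -> list[SpikeTrain]:
    """Rate-coded discharge times for every unit given the excitation drive.

    A unit fires only while the excitation is at or above its recruitment
    threshold; the instantaneous rate interpolates min_rate -> peak_rate
    linearly between threshold and full excitation; ISIs are Gaussian with
    the pool's CV, floored at the 10-ms refractory period.
    """
    excitation = np.asarray(excitation, dtype=np.float64)
    if np.any(excitation < 0) or np.any(excitation > 1):
        raise ValueError("excitation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = excitation.size
    refractory = int(np.ceil(REFRACTORY_S * fs))
    trains = []
    for i in range(pool.n_units):
        thr = pool.recruitment_thresholds[i]
        active = excitation >= thr
        spikes: list[int] = []
        t = 0
        while t < n:
            if not active[t]:
                t += 1
                continue
            exc = excitation[t]
            frac = (exc - thr) / (1.0 - thr) if thr < 1 else 1.0
            rate = pool.min_rate + (pool.peak_rate - pool.min_rate) * frac
            mean_isi = fs / rate
            isi = rng.normal(mean_isi, pool.isi_cv * mean_isi)
            isi = max(int(round(isi)), refractory)
            t_next = t + isi
            if t_next >= n:
                break
            if active[t_next]:
                spikes.append(t_next)
                t = t_next
            else:
                t = t_next  # derecruited before the next discharge
        trains.append(SpikeTrain(mu_id=i, spikes=np.asarray(spikes, dtype=np.int64), fs=fs))
    return trains


def _clean_signal(templates: list[MuapTemplate], spike_trains: list[SpikeTrain],
                  n_samples: int, fs: float,
                  drift: DriftSchedule | None, seed: int = 0) -> np.ndarray:
    n_ch = templates[0].n_channels
    out = np.zeros((n_samples, n_ch))
    endpoints = (drift.channel_endpoints(n_ch, seed)
                 if drift is not None else None)
    for tpl, train in zip(templates, spike_trains):
        if train.n_spikes == 0:
            continue
        w = tpl.waveforms  # (n_ch, L)
        w_shift = np.roll(w, 1, axis=1)
        length = tpl.length
        for s in train.spikes:
            if drift is not None:
                prog = float(drift.progress(s / fs))
                amp = 1.0 + (endpoints - 1.0) * prog  # per channel
                morph = drift.template_morph * prog
                wav = amp[:, None] * ((1.0 - morph) * w + morph * w_shift)
            else:
                wav = w
            stop = min(s + length, n_samples)
            out[s:stop] += wav[:, : stop - s].T
    return out


def synthesize_emg(templates: list[MuapTemplate], spike_trains: list[SpikeTrain],
                   noise_snr_db: float | None, drift: DriftSchedule | None,
                   fs: float, seed: int = 0,
                   grid: GridGeometry | None = None,
                   n_samples: int | None = None,
                   force: np.ndarray | None = None) -> EmgRecording:
    """Sum MUAP trains over the grid, apply drift, add white Gaussian noise.

    ``noise_snr_db`` is the target signal-to-noise ratio over the whole
    contraction; ``None`` adds no noise.  Ground-truth spikes and the clean
    (noise-free) signal are kept in ``meta``.
    """
    if len(templates) != len(spike_trains):
        raise ValueError("templates and spike trains must be index-aligned")
    grid = grid or GridGeometry()
    if n_samples is None:
        n_samples = max((int(t.spikes[-1]) + templates[0].length
                         for t in spike_trains if t.n_spikes), default=0)
        if force is not None:
            n_samples = max(n_samples, force.size)
    if n_samples == 0:
        raise ValueError("no spikes and no force profile: nothing to synthesize")
    clean = _clean_signal(templates, spike_trains, n_samples, fs, drift, seed)
    samples = clean.copy()
    if noise_snr_db is not None:
        p_signal = np.mean(clean**2)
        if p_signal == 0:
            raise ValueError("cannot set an SNR on an all-zero signal")
        sigma = np.sqrt(p_signal / 10.0 ** (noise_snr_db / 10.0))
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, sigma, samples.shape)
    return EmgRecording(
        samples=samples, fs=fs, grid=grid, force=force,
        meta={"true_spikes": spike_trains, "clean": clean,
              "noise_snr_db": noise_snr_db},
    )


def ground_truth_force(spike_trains: list[SpikeTrain],
                       twitch_amplitudes: np.ndarray, fs: float,
                       n_samples: int,
                       params: TwitchParams = TwitchParams(),
                       normalize: bool = True) -> np.ndarray:
    """Whole-muscle force: sum of rate-gain-scaled twitches over all units."""
    out = np.zeros(n_samples)
    for train, p in zip(spike_trains, np.asarray(twitch_amplitudes, dtype=np.float64)):
        if train.n_spikes == 0:
            continue
        t_c = contraction_time(p, params)
        support = min(kernel_support_samples(t_c, fs), n_samples)
        kernel = twitch_kernel(p, t_c, np.arange(support) / fs)
        gains = discharge_gains(train.spikes, t_c, fs, params)
        for s, g in zip(train.spikes, gains):
            if s >= n_samples:
                break
            stop = min(s + support, n_samples)
            out[s:stop] += g * kernel[: stop - s]
    if normalize and out.max() > 0:
        out = out / out.max()
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """One simulated trial set: pool + task + noise + drift."""

    pool: MotorUnitPool = field(default_factory=MotorUnitPool)
    grid: GridGeometry = field(default_factory=GridGeometry)
    level: float = 0.30
    ramp_s: float = 2.0
    hold_s: float = 3.0
    n_trials: int = 3
    fs: float = 2000.0
    noise_snr_db: float | None = 20.0
    drift: DriftSchedule | None = None
    seed: int = 0


def simulate_session(cfg: SimulationConfig) -> EmgRecording:
    """End-to-end simulation of a repeated-trapezoid session.

    The recording's ``force`` channel is the ground-truth twitch-model force
    normalized to the session maximum (the MVC-normalized label analogue);
    ground-truth spikes, templates and the excitation profile live in ``meta``.
    """
    excitation = repeated_trapezoids(cfg.level, cfg.ramp_s, cfg.hold_s,
                                     cfg.fs, cfg.n_trials)
    templates = generate_muap_templates(cfg.pool, cfg.grid, fs=cfg.fs,
                                        seed=cfg.seed)
    trains = simulate_firing(cfg.pool, excitation, cfg.fs, seed=cfg.seed + 1)
    n = excitation.size
    force = ground_truth_force(trains, cfg.pool.twitch_amplitudes, cfg.fs, n,
                               normalize=False)
    peak = force.max() if force.max() > 0 else 1.0
    force = cfg.level * force / peak  # scale so the hold sits at the target level
    rec = synthesize_emg(templates, trains, cfg.noise_snr_db, cfg.drift,
                         cfg.fs, seed=cfg.seed + 2, grid=cfg.grid,
                         n_samples=n, force=force)
    rec.meta["templates"] = templates
    rec.meta["excitation"] = excitation
    rec.meta["config"] = cfg
    return rec
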