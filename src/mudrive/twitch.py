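"""Electricity-to-force transform: motor unit twitch model.

A single discharge of motor unit *i* produces the second-order impulse
response

    f_i(t) = (P_i * t / T_i) * exp(1 - t / T_i)

with twitch amplitude ``P_i`` and contraction time ``T_i``.  The kernel
peaks at t = T_i with value exactly P_i.  Contraction time follows an
inverse power law of amplitude,

    T_i = T_L * (1 / P_i)^(1/c)

with maximal contraction time T_L = 90 ms and exponent c = 4.2.  During
sustained firing, each discharge is scaled by a rate-dependent gain

    g = 1                                   if  T_i / ISI <= 0.4
    g = k * (1 - exp(-2 (T_i/ISI)^3)) / (T_i/ISI)   otherwise

where ISI is the interval to the *preceding* discharge ("normalized
stimulus rate" x = T/ISI).  ``k`` is fixed by continuity at the x = 0.4
knee: k = 0.4 / (1 - exp(-2 * 0.4**3)).

The model is applied per electrode channel, with the per-channel twitch
amplitude taken proportional to the MUAP's peak-to-peak amplitude on that
channel; the resulting per-MU twitch-force trains are sliced into 0.2-s
windows over the 8x8 grid as input to the force network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GridGeometry, MuapTemplate, SpikeTrain

#: Maximal contraction time, s.
T_L = 0.090
#: Inverse power law exponent.
C_EXPONENT = 4.2
#: Knee of the rate-gain curve (normalized stimulus rate).
GAIN_KNEE = 0.4
#: Gain scale fixed by continuity at the knee.
K_GAIN = GAIN_KNEE / (1.0 - np.exp(-2.0 * GAIN_KNEE**3))
#: Relative amplitude below which the twitch kernel is truncated.
KERNEL_CUTOFF = 1e-4


@dataclass(frozen=True)
class TwitchParams:
    """Constants of the twitch model (defaults are the model's stated values)."""

    t_max: float = T_L
    c: float = C_EXPONENT
    k: float = K_GAIN
    amplitude_scale: float = 1.0  # P = amplitude_scale * peak-to-peak


@dataclass
class FeatureWindow:
    """One network sample: (400, rows, cols, N) twitch tensor + 400-point label."""

    tensor: np.ndarray
    label: np.ndarray
    start_sample: int

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        self.label = np.asarray(self.label, dtype=np.float64)
        if self.tensor.ndim != 4:
            raise ValueError("tensor must be (time, rows, cols, n_mus)")
        if self.label.shape != (self.tensor.shape[0],):
            raise ValueError("label length must equal the tensor's time axis")


def contraction_time(p: float | np.ndarray, params: TwitchParams = TwitchParams()) -> np.ndarray | float:
    """Contraction time T from twitch amplitude P via the inverse power law.

    T is capped at the maximal contraction time ``t_max`` (amplitudes below 1
    in normalized units would otherwise exceed the physiological maximum).
    """
    p_arr = np.asarray(p, dtype=np.float64)
    if np.any(p_arr <= 0):
        raise ValueError("twitch amplitude P must be positive")
    t = params.t_max * (1.0 / p_arr) ** (1.0 / params.c)
    t = np.minimum(t, params.t_max)
    return float(t) if np.isscalar(p) or p_arr.ndim == 0 else t


def twitch_kernel(p: float, t_contr: float, t_grid: np.ndarray) -> np.ndarray:
    """Evaluate the single-twitch impulse response on a time grid (seconds)."""
    if t_contr <= 0:
        raise ValueError("contraction time must be positive")
    t_grid = np.asarray(t_grid, dtype=np.float64)
    x = t_grid / t_contr
    out = p * x * np.exp(1.0 - x)
    # truncate the decayed tail (support bound for efficiency)
    out[(x > 1.0) & (out < KERNEL_CUTOFF * p)] = 0.0
    return out


def kernel_support_samples(t_contr: float, fs: float) -> int:
    """Number of samples until the kernel decays below the truncation cutoff."""
    # solve x * e^(1-x) = cutoff for the decaying branch: x - ln x = 1 - ln cutoff
    target = 1.0 - np.log(KERNEL_CUTOFF)
    x = target
    for _ in range(50):
        x = target + np.log(x)
    return int(np.ceil(x * t_contr * fs)) + 1


def discharge_gain(t_contr: float | np.ndarray, isi: float | np.ndarray,
                   params: TwitchParams = TwitchParams()) -> np.ndarray | float:
    """Rate-dependent gain of a discharge given the preceding ISI (seconds)."""
    isi_arr = np.asarray(isi, dtype=np.float64)
    if np.any(isi_arr <= 0):
        raise ValueError("ISI must be positive")
    x = np.asarray(t_contr, dtype=np.float64) / isi_arr
    with np.errstate(over="ignore"):
        nonlinear = params.k * (1.0 - np.exp(-2.0 * x**3)) / np.where(x > 0, x, 1.0)
    g = np.where(x <= GAIN_KNEE, 1.0, nonlinear)
    return float(g) if g.ndim == 0 else g


def discharge_gains(spikes: np.ndarray, t_contr: float, fs: float,
                    params: TwitchParams = TwitchParams()) -> np.ndarray:
    """Gain for every discharge in a train; the first discharge gets gain 1."""
    spikes = np.asarray(spikes)
    if spikes.size == 0:
        return np.empty(0)
    gains = np.ones(spikes.size)
    if spikes.size > 1:
        isis = np.diff(spikes) / fs
        gains[1:] = discharge_gain(t_contr, isis, params)
    return gains


def spikes_to_twitch_train(spikes: SpikeTrain, template: MuapTemplate,
                           n_samples: int,
                           params: TwitchParams = TwitchParams()) -> np.ndarray:
    """Superpose per-channel twitches for every discharge of one MU.

    Returns an (n_samples, n_channels) array of twitch force.  Channel c uses
    P_c proportional to the MUAP peak-to-peak on that channel; channels with
    zero amplitude stay silent.
    """
    n_ch = template.n_channels
    out = np.zeros((n_samples, n_ch))
    if spikes.n_spikes == 0:
        return out
    fs = spikes.fs
    ptp = params.amplitude_scale * template.peak_to_peak
    for c in range(n_ch):
        p_c = ptp[c]
        if p_c <= 0:
            continue
        t_c = contraction_time(p_c, params)
        support = min(kernel_support_samples(t_c, fs), n_samples)
        t_grid = np.arange(support) / fs
        kernel = twitch_kernel(p_c, t_c, t_grid)
        gains = discharge_gains(spikes.spikes, t_c, fs, params)
        for s, g in zip(spikes.spikes, gains):
            if s >= n_samples:
                break
            stop = min(s + support, n_samples)
            out[s:stop, c] += g * kernel[: stop - s]
    return out


def twitch_trains_for_bank(spike_trains: list[SpikeTrain],
                           templates: list[MuapTemplate],
                           n_samples: int,
                           params: TwitchParams = TwitchParams()) -> np.ndarray:
    """Stack per-MU twitch trains into (n_samples, n_channels, N)."""
    if len(spike_trains) != len(templates):
        raise ValueError("spike trains and templates must be index-aligned")
    trains = [
        spikes_to_twitch_train(st, tpl, n_samples, params)
        for st, tpl in zip(spike_trains, templates)
    ]
    return np.stack(trains, axis=-1)


def build_feature_window(twitch_trains: np.ndarray, start: int, grid: GridGeometry,
                         force: np.ndarray, window_samples: int = 400,
                         label_points: int | None = None) -> FeatureWindow:
    """Slice one 0.2-s window out of stacked twitch trains.

    ``twitch_trains`` is (n_samples, n_channels, N); the window's channel axis
    is reshaped to the electrode grid (row-major).  The force label is the
    measured (already MVC-normalized) force over the same samples, resampled
    to ``window_samples`` points if it was recorded on a coarser grid.
    """
    n_samples = twitch_trains.shape[0]
    stop = start + window_samples
    if start < 0 or stop > n_samples:
        raise ValueError("window exceeds the available data")
    block = twitch_trains[start:stop]  # (400, n_channels, N)
    tensor = grid.to_grid(np.moveaxis(block, 1, -1))  # (400, N, rows, cols)
    tensor = np.moveaxis(tensor, 1, -1)  # (400, rows, cols, N)
    label = np.asarray(force[start:stop], dtype=np.float64)
    if label_points is not None and label_points != window_samples:
        # label recorded at a lower rate: resample to the sample grid
        coarse = np.linspace(0, 1, label_points)
        fine = np.linspace(0, 1, window_samples)
        label = np.interp(fine, coarse, label[:label_points])
    return FeatureWindow(tensor=tensor, label=label, start_sample=start)


def feature_windows(twitch_trains: np.ndarray, force: np.ndarray,
                    grid: GridGeometry, window_samples: int = 400,
                    start: int = 0) -> list[FeatureWindow]:
    """Tile non-overlapping 0.2-s windows over the full record."""
    n = twitch_trains.shape[0]
    return [
        build_feature_window(twitch_trains, s, grid, force, window_samples)
        for s in range(start, n - window_samples + 1, window_samples)
    ]
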