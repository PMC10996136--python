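"""Shared domain types for the MU-driven force prediction pipeline.

These containers are deliberately thin: numpy arrays with invariants checked
at construction, passed between the simulator, the decomposition stages and
the force model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Refractory floor used everywhere an inter-spike interval is validated, s.
REFRACTORY_S = 0.010


@dataclass(frozen=True)
class GridGeometry:
    """Electrode grid layout. Channel index = row * cols + col (row-major)."""

    rows: int = 8
    cols: int = 8
    inter_electrode_distance_mm: float = 4.0

    @property
    def n_channels(self) -> int:
        return self.rows * self.cols

    def to_grid(self, channels: np.ndarray) -> np.ndarray:
        """Reshape a trailing channel axis (..., rows*cols) to (..., rows, cols)."""
        channels = np.asarray(channels)
        if channels.shape[-1] != self.n_channels:
            raise ValueError(
                f"expected {self.n_channels} channels, got {channels.shape[-1]}"
            )
        return channels.reshape(channels.shape[:-1] + (self.rows, self.cols))

    def to_channels(self, grid: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_grid`."""
        grid = np.asarray(grid)
        if grid.shape[-2:] != (self.rows, self.cols):
            raise ValueError(f"expected trailing shape {(self.rows, self.cols)}")
        return grid.reshape(grid.shape[:-2] + (self.n_channels,))


@dataclass
class EmgRecording:
    """Multichannel sampled EMG (n_samples x n_channels, µV) with optional force.

    ``force`` is the simultaneously sampled contraction force normalized to
    [0, 1] of maximum voluntary contraction (MVC).
    """

    samples: np.ndarray
    fs: float
    grid: GridGeometry = field(default_factory=GridGeometry)
    force: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] == 0:
            raise ValueError("samples must be a non-empty (n_samples, n_channels) array")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.shape[1] != self.grid.n_channels:
            raise ValueError(
                f"channel count {self.samples.shape[1]} does not match grid "
                f"({self.grid.n_channels})"
            )
        if self.force is not None:
            self.force = np.asarray(self.force, dtype=np.float64)
            if self.force.shape != (self.samples.shape[0],):
                raise ValueError("force must match the number of samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SpikeTrain:
    """Discharge times of one motor unit as strictly increasing sample indices."""

    mu_id: int
    spikes: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes, dtype=np.int64).ravel()
        if self.spikes.size and np.any(np.diff(self.spikes) <= 0):
            raise ValueError("spikes must be strictly increasing")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_spikes(self) -> int:
        return self.spikes.size

    def isis_s(self) -> np.ndarray:
        """Inter-spike intervals in seconds."""
        return np.diff(self.spikes) / self.fs

    def rate_hz(self) -> float:
        """Mean firing rate over the active span (0 for < 2 spikes)."""
        if self.n_spikes < 2:
            return 0.0
        span = (self.spikes[-1] - self.spikes[0]) / self.fs
        return (self.n_spikes - 1) / span if span > 0 else 0.0

    def isi_cv(self) -> float:
        """Coefficient of variation of the inter-spike intervals."""
        isis = self.isis_s()
        if isis.size < 2 or isis.mean() == 0:
            return np.inf
        return float(isis.std() / isis.mean())

    def within(self, start: int, stop: int) -> np.ndarray:
        """Spike indices falling in [start, stop)."""
        s = self.spikes
        return s[(s >= start) & (s < stop)]


@dataclass
class MuapTemplate:
    """Per-channel motor unit action potential waveforms (n_channels x L, µV).

    ``pre_samples`` is the number of waveform samples preceding the spike
    marker (0 for onset-aligned simulator templates; positive for templates
    estimated around a detected peak).
    """

    mu_id: int
    waveforms: np.ndarray
    pre_samples: int = 0

    def __post_init__(self) -> None:
        self.waveforms = np.asarray(self.waveforms, dtype=np.float64)
        if self.waveforms.ndim != 2:
            raise ValueError("waveforms must be (n_channels, L)")

    @property
    def n_channels(self) -> int:
        return self.waveforms.shape[0]

    @property
    def length(self) -> int:
        return self.waveforms.shape[1]

    @property
    def peak_to_peak(self) -> np.ndarray:
        """Per-channel peak-to-peak amplitude, µV."""
        return self.waveforms.max(axis=1) - self.waveforms.min(axis=1)
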