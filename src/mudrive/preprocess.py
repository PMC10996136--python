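"""Filtering, observation extension and whitening shared by both decomposition stages.

The convolutive EMG mixture is made (approximately) instantaneous by
*extension* — augmenting every channel with R delayed copies — and then
*whitened* by an eigenvalue decomposition of the extended covariance.
Filtering is causal (cascaded second-order sections) so the same filters are
valid on the online stream; using them offline too keeps the separation
vectors transferable between stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import EmgRecording

#: Default extension factor (delayed copies per channel).
DEFAULT_R = 10
#: Relative eigenvalue floor guarding the whitening inversion.
DEFAULT_EIG_FLOOR = 1e-6

BAND_HZ = (20.0, 500.0)
BAND_ORDER = 10
NOTCH_HZ = 50.0
NOTCH_Q = 30.0


def design_filters(fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Band-pass + notch cascade as second-order sections."""
    if fs <= 2 * BAND_HZ[1]:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    sos_band = signal.butter(BAND_ORDER, BAND_HZ, btype="bandpass", fs=fs,
                             output="sos")
    b, a = signal.iirnotch(NOTCH_HZ, NOTCH_Q, fs=fs)
    sos_notch = signal.tf2sos(b, a)
    return sos_band, sos_notch


def bandpass_notch(recording: EmgRecording) -> EmgRecording:
    """Causal 20-500 Hz Butterworth band-pass then 50 Hz notch, per channel."""
    sos_band, sos_notch = design_filters(recording.fs)
    filtered = signal.sosfilt(sos_band, recording.samples, axis=0)
    filtered = signal.sosfilt(sos_notch, filtered, axis=0)
    return EmgRecording(samples=filtered, fs=recording.fs, grid=recording.grid,
                        force=recording.force, meta=dict(recording.meta))


def extend(signals: np.ndarray, r: int) -> np.ndarray:
    """Augment each channel with r delayed copies (zero-padded at the start).

    Channel c, delay d maps to output column c*r + d.
    """
    if r < 1:
        raise ValueError("extension factor must be >= 1")
    signals = np.asarray(signals, dtype=np.float64)
    n, n_ch = signals.shape
    out = np.zeros((n, n_ch * r))
    for d in range(r):
        cols = np.arange(n_ch) * r + d
        if d == 0:
            out[:, cols] = signals
        else:
            out[d:, cols] = signals[:-d]
    return out


@dataclass
class WhiteningModel:
    """Mean-removal + eigenvalue whitening of extended EMG.

    ``matrix`` maps centered extended data to the retained whitened space
    (shape kept x extended_dim); directions with eigenvalues below
    ``eig_floor`` times the largest are discarded.
    """

    extension_factor: int
    channel_means: np.ndarray
    matrix: np.ndarray
    eigenvalues: np.ndarray
    eig_floor: float = DEFAULT_EIG_FLOOR

    @property
    def extended_dim(self) -> int:
        return self.channel_means.size

    @property
    def kept_dim(self) -> int:
        return self.matrix.shape[0]


def fit_whitening(extended: np.ndarray, r: int = DEFAULT_R,
                  eig_floor: float = DEFAULT_EIG_FLOOR) -> WhiteningModel:
    """Fit the whitening model so the fitted data's covariance is identity."""
    extended = np.asarray(extended, dtype=np.float64)
    n, dim = extended.shape
    if n <= dim:
        raise ValueError("need more samples than extended channels")
    means = extended.mean(axis=0)
    centered = extended - means
    cov = centered.T @ centered / n
    eigval, eigvec = np.linalg.eigh(cov)
    keep = eigval > eig_floor * eigval[-1]
    if keep.sum() < 2:
        raise ValueError("rank-deficient input: fewer than 2 retained dimensions")
    eigval = eigval[keep]
    eigvec = eigvec[:, keep]
    matrix = (eigvec / np.sqrt(eigval)).T  # (kept, dim)
    return WhiteningModel(extension_factor=r, channel_means=means,
                          matrix=matrix, eigenvalues=eigval, eig_floor=eig_floor)


def apply_whitening(model: WhiteningModel, extended: np.ndarray) -> np.ndarray:
    """Project extended data into the retained whitened space."""
    extended = np.asarray(extended, dtype=np.float64)
    if extended.shape[1] != model.extended_dim:
        raise ValueError("extended dimension does not match the model")
    return (extended - model.channel_means) @ model.matrix.T


def extend_and_whiten(signals: np.ndarray, model: WhiteningModel) -> np.ndarray:
    """Convenience: extension with the model's factor, then whitening."""
    return apply_whitening(model, extend(signals, model.extension_factor))
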