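"""Frontend real-time decomposition over sliding 1-s windows.

The stream is cut into 1-s windows advancing by 0.2 s.  Each window is
extended, whitened with the bank's stored model and projected through every
separation vector; spikes are extracted per unit.  Identity over time is
carried by the separation vector itself (bank mu_id): spikes found in the
0.8-s overlap are matched against already-committed spikes to confirm
continuity, and only spikes from the final 0.2 s of each window are
committed to the output trains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import EmgRecording, SpikeTrain
from .metrics import DEFAULT_TOL_MS, MatchResult, match_spikes
from .offline import SeparationBank, otsu_spike_detect, threshold_spike_detect
from .preprocess import extend_and_whiten

logger = logging.getLogger(__name__)

WINDOW_S = 1.0
INCREMENT_S = 0.2


@dataclass
class StreamWindow:
    """One 1-s slice of the stream in absolute coordinates."""

    start_sample: int
    data: np.ndarray
    fs: float

    @property
    def length(self) -> int:
        return self.data.shape[0]


@dataclass
class OnlineMustBuffer:
    """Committed (append-only) per-MU spike trains plus per-window provisional state."""

    fs: float
    tol_ms: float = DEFAULT_TOL_MS
    committed: dict[int, list[int]] = field(default_factory=dict)
    unstable: dict[int, bool] = field(default_factory=dict)

    def train(self, mu_id: int) -> SpikeTrain:
        return SpikeTrain(mu_id=mu_id,
                          spikes=np.asarray(self.committed.get(mu_id, []),
                                            dtype=np.int64),
                          fs=self.fs)

    def trains(self) -> list[SpikeTrain]:
        return [self.train(mu_id) for mu_id in sorted(self.committed)]


def process_window(window: StreamWindow, bank: SeparationBank) -> dict[int, np.ndarray]:
    """Decompose one window; returns per-MU spike indices in absolute coordinates."""
    if bank.n_units == 0:
        raise ValueError("separation bank is empty")
    expected = int(round(WINDOW_S * window.fs))
    if window.length < expected:
        raise BufferError("window not fully buffered")
    z = extend_and_whiten(window.data, bank.whitening)
    out: dict[int, np.ndarray] = {}
    for vec in bank.vectors:
        source = z @ vec.weights
        if vec.threshold > 0:
            train = threshold_spike_detect(source, window.fs, vec.threshold,
                                           mu_id=vec.mu_id)
        else:
            train = otsu_spike_detect(source, window.fs, mu_id=vec.mu_id)
        out[vec.mu_id] = train.spikes + window.start_sample
    return out


def track_and_commit(buffer: OnlineMustBuffer, window: StreamWindow,
                     window_spikes: dict[int, np.ndarray]) -> OnlineMustBuffer:
    """Confirm identity over the 0.8-s overlap, commit the final 0.2 s.

    Overlap spikes are matched (±tol) to already-committed spikes; an MR
    below 0.5 over the overlap flags the unit unstable for this window but
    identity is kept (it is carried by the separation vector).  Only spikes
    in the final increment are appended, merging duplicates within ±tol.
    """
    fs = window.fs
    tol = buffer.tol_ms * 1e-3 * fs
    commit_start = window.start_sample + window.length - int(round(INCREMENT_S * fs))
    overlap_start = window.start_sample
    for mu_id, spikes in window_spikes.items():
        committed = buffer.committed.setdefault(mu_id, [])
        overlap_new = spikes[(spikes >= overlap_start) & (spikes < commit_start)]
        prev = np.asarray(
            [s for s in committed if overlap_start <= s < commit_start],
            dtype=np.int64)
        if prev.size or overlap_new.size:
            n_com = match_spikes(np.sort(overlap_new), prev, tol)
            mr = MatchResult(overlap_new.size, prev.size, n_com).mr
            buffer.unstable[mu_id] = mr < 0.5
        to_commit = np.sort(spikes[spikes >= commit_start])
        for s in to_commit:
            if committed and abs(int(s) - committed[-1]) <= tol:
                continue  # duplicate within tolerance
            if committed and s <= committed[-1]:
                continue  # keep trains strictly increasing
            committed.append(int(s))
    return buffer


UpdateHook = Callable[[SeparationBank, int, OnlineMustBuffer], SeparationBank]


def stream_decompose(recording: EmgRecording, bank: SeparationBank,
                     update_hook: UpdateHook | None = None,
                     update_period_s: float = 10.0,
                     log_events: list | None = None) -> list[SpikeTrain]:
    """Slide 1-s windows by 0.2 s over a filtered recording.

    ``update_hook(bank, at_sample, buffer) -> bank`` is invoked at every
    10-s boundary (backend update); the returned bank is adopted before the
    next window (atomic swap in stream time).
    """
    if bank.n_units == 0:
        raise ValueError("separation bank is empty")
    fs = recording.fs
    win = int(round(WINDOW_S * fs))
    step = int(round(INCREMENT_S * fs))
    period = int(round(update_period_s * fs))
    buffer = OnlineMustBuffer(fs=fs)
    for mu_id in bank.mu_ids:
        buffer.committed.setdefault(mu_id, [])
    next_update = period
    last_start = recording.n_samples - win
    for start in range(0, last_start + 1, step):
        window = StreamWindow(start_sample=start,
                              data=recording.samples[start:start + win], fs=fs)
        spikes = process_window(window, bank)
        track_and_commit(buffer, window, spikes)
        if log_events is not None:
            log_events.append({
                "window_start": start,
                "bank_version": bank.version,
                "spike_counts": {int(k): int(v.size) for k, v in spikes.items()},
            })
        # backend update: fires once the stream has delivered the boundary
        # sample; the refreshed bank is adopted before the next window
        if (update_hook is not None and start + win >= next_update
                and start < last_start):
            bank = update_hook(bank, next_update, buffer)
            next_update += period
    return buffer.trains()
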