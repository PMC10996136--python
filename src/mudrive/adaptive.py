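"""Backend separation-vector update with constrained FastICA.

Every 10 s the most recent 5-s segment is re-whitened and each unit's
separation vector is re-converged by a constrained fixed-point iteration
anchored on the unit's recent (committed) spike train: the reference defines
a constraint vector with the closed form Z' r / n on whitened data, and the
iteration alternates spike detection with the least-squares fixed point of
the detected train.  The anchor is what lets the update re-converge quickly
and onto the SAME unit; an unconstrained contrast would drift weak units
onto stronger neighbours.

The refreshed bank is swapped in atomically between windows; committed
spikes inside the update segment are replaced by the post-update detection
(the update's retroactive error-correction horizon is the segment itself).
No peel-off is performed in the update.
"""

from __future__ import annotations

import logging
import threading
from dataclasses import dataclass, field

import numpy as np

from .core import EmgRecording, SpikeTrain
from .offline import (SeparationBank, SeparationVector, detection_threshold,
                      estimate_muap, otsu_spike_detect, threshold_spike_detect,
                      unit_quality, vector_for_source)
from .online import OnlineMustBuffer, UpdateHook
from .preprocess import extend, extend_and_whiten, fit_whitening

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UpdateConfig:
    period_s: float = 10.0
    segment_s: float = 5.0
    max_iter: int = 100
    tol: float = 1e-6
    lam: float = 0.5          # blend weight of the constraint vector at init
    min_ref_spikes: int = 5

    def __post_init__(self) -> None:
        if self.segment_s > self.period_s:
            raise ValueError("segment must fit inside the update period")


@dataclass
class UpdateEvent:
    at_sample: int
    version_before: int
    version_after: int
    converged: dict[int, bool] = field(default_factory=dict)
    skipped: dict[int, bool] = field(default_factory=dict)
    spikes_before: dict[int, int] = field(default_factory=dict)
    spikes_after: dict[int, int] = field(default_factory=dict)


def constrained_fastica(z: np.ndarray, reference: np.ndarray,
                        init: np.ndarray, fs: float,
                        cfg: UpdateConfig) -> tuple[np.ndarray, bool]:
    """Re-converge one separation vector on a whitened segment.

    ``reference`` is the unit's binary spike indicator over the segment; the
    constraint vector it defines has the closed form z' r / n on whitened
    data (covariance = identity).  The iteration starts from a blend of the
    carried-over vector and the constraint vector, then alternates spike
    detection with the least-squares fixed point w <- z' b / n of the
    detected train — a reference-anchored update that tracks waveform drift
    without letting the unconstrained contrast migrate a weak unit onto a
    stronger one.  If the result no longer matches the reference train, the
    carried-over vector is returned unchanged (flagged unconverged).

    Returns (unit vector, converged flag).
    """
    n = z.shape[0]
    w_ref = vector_for_source(z, reference)
    ref_norm = np.linalg.norm(w_ref)
    if ref_norm == 0:
        w0 = np.asarray(init, dtype=np.float64).ravel()
        return w0 / np.linalg.norm(w0), False
    w_ref = w_ref / ref_norm
    w_init = np.asarray(init, dtype=np.float64).ravel().copy()
    init_norm = np.linalg.norm(w_init)
    w_init = w_init / init_norm if init_norm > 0 else w_ref
    w = cfg.lam * w_ref + (1.0 - cfg.lam) * w_init
    w /= np.linalg.norm(w)
    ref_train = SpikeTrain(mu_id=-1, spikes=np.flatnonzero(reference), fs=fs)
    train = ref_train
    converged = False
    for _ in range(cfg.max_iter):
        source = z @ w
        # detection threshold calibrated from the unit's own spike heights
        # (an Otsu split of a short segment is hostage to single outliers)
        thr = detection_threshold(source, train if train.n_spikes else ref_train)
        train = threshold_spike_detect(source, fs, thr)
        if train.n_spikes < 2:
            return w_init, False
        binary = np.zeros(n)
        binary[train.spikes] = 1.0
        w_new = z.T @ binary / n
        w_new /= np.linalg.norm(w_new)
        if abs(1.0 - abs(w_new @ w)) < cfg.tol:
            w = w_new
            converged = True
            break
        w = w_new
    from .metrics import best_lag_match  # local import avoids a cycle

    match, _ = best_lag_match(train, ref_train, max_lag_ms=5.0)
    if match.mr < 0.5:
        return w_init, False
    return w, converged


def update_bank(
    bank: SeparationBank, segment: EmgRecording,
    committed: list[SpikeTrain], segment_start: int,
    cfg: UpdateConfig = UpdateConfig(),
) -> tuple[SeparationBank, UpdateEvent, dict[int, SpikeTrain]]:
    """Refresh every separation vector on the most recent segment.

    ``segment`` holds the raw (filtered) samples of the last ``segment_s``
    seconds; ``segment_start`` is its absolute start sample; ``committed``
    are the frontend's current trains in absolute coordinates.  Units with
    fewer than ``min_ref_spikes`` reference spikes in the segment keep their
    old vector (skip-flagged).  Returns the new bank (version + 1), the
    update event, and the per-unit re-detected segment-local trains for the
    caller to splice into the committed buffer.
    """
    fs = bank.fs
    n_seg = segment.n_samples
    expected = int(round(cfg.segment_s * fs))
    if n_seg != expected:
        raise ValueError(f"segment must be {expected} samples, got {n_seg}")
    event = UpdateEvent(at_sample=segment_start + n_seg,
                        version_before=bank.version,
                        version_after=bank.version + 1)
    by_id = {t.mu_id: t for t in committed}
    try:
        ext = extend(segment.samples, bank.whitening.extension_factor)
        new_whitening = fit_whitening(ext, bank.whitening.extension_factor,
                                      bank.whitening.eig_floor)
    except ValueError:
        logger.warning("whitening refit failed at sample %d; keeping old bank",
                       segment_start)
        event.version_after = bank.version
        return bank, event, {}
    z_new = (ext - new_whitening.channel_means) @ new_whitening.matrix.T
    # map old vectors into the new whitened space via their old-source estimate
    z_old = extend_and_whiten(segment.samples, bank.whitening)
    new_vectors: list[SeparationVector] = []
    new_templates = []
    new_trains: dict[int, SpikeTrain] = {}
    for vec, tpl in zip(bank.vectors, bank.templates):
        ref_train = by_id.get(vec.mu_id)
        ref_local = (ref_train.within(segment_start, segment_start + n_seg)
                     - segment_start) if ref_train is not None else np.empty(0, int)
        event.spikes_before[vec.mu_id] = int(ref_local.size)
        source_old = z_old @ vec.weights
        init = vector_for_source(z_new, source_old)
        if ref_local.size < cfg.min_ref_spikes:
            # too little recent activity to re-converge: carry the old vector
            # over, re-expressed in the refit whitened space
            event.skipped[vec.mu_id] = True
            carried = SeparationVector(weights=init, mu_id=vec.mu_id,
                                       quality=vec.quality,
                                       threshold=vec.threshold)
            new_vectors.append(carried)
            new_templates.append(tpl)
            continue
        reference = np.zeros(n_seg)
        reference[ref_local] = 1.0
        if np.linalg.norm(init) == 0:
            init = vector_for_source(z_new, reference)
        w, conv = constrained_fastica(z_new, reference, init, fs, cfg)
        event.converged[vec.mu_id] = conv
        event.skipped[vec.mu_id] = False
        # validate before swapping: a vector re-estimated from 5 s carries
        # more variance than the bank's, so adopt it only if it separates
        # the unit better on this segment than the carried-over vector
        ref_local_train = SpikeTrain(mu_id=vec.mu_id, spikes=ref_local, fs=fs)
        w_carried = init / np.linalg.norm(init)
        best_w, best_train, best_source, best_score = None, None, None, -np.inf
        for w_cand in (w, w_carried):
            source = z_new @ w_cand
            thr = detection_threshold(source, ref_local_train) or vec.threshold
            train = threshold_spike_detect(source, fs, thr, mu_id=vec.mu_id)
            score, _ = unit_quality(train, source)
            if score > best_score:
                best_w, best_train, best_source = w_cand, train, source
                best_score = score
        new_vec = SeparationVector(weights=best_w, mu_id=vec.mu_id,
                                   quality=best_score, converged=conv)
        train_local = best_train
        recalibrated = detection_threshold(best_source, train_local)
        if recalibrated > 0 and vec.threshold > 0:
            # damp the 5-s recalibration's sampling noise (a median over a
            # few dozen spikes) toward the running value; geometric mean
            # because thresholds live on an energy scale
            new_vec.threshold = float(np.sqrt(recalibrated * vec.threshold))
        else:
            new_vec.threshold = recalibrated or vec.threshold
        event.spikes_after[vec.mu_id] = train_local.n_spikes
        new_trains[vec.mu_id] = train_local
        new_vectors.append(new_vec)
        if train_local.n_spikes:
            new_templates.append(estimate_muap(segment.samples, train_local,
                                               mu_id=vec.mu_id))
        else:
            new_templates.append(tpl)
    new_bank = SeparationBank(whitening=new_whitening, vectors=new_vectors,
                              templates=new_templates, fs=fs,
                              created_at=segment_start + n_seg,
                              version=bank.version + 1)
    event.version_after = new_bank.version
    return new_bank, event, new_trains


#: Samples excluded at each end of the update segment when splicing: the
#: extension zero-padding and whitening-boundary transients make detections
#: there unreliable.
SPLICE_MARGIN = 40


def _splice_committed(buffer: OnlineMustBuffer, segment_start: int,
                      segment_len: int, trains: dict[int, SpikeTrain]) -> None:
    """Replace committed spikes inside the segment core with the post-update
    detection (the retroactive error-correction step), keeping the old
    commits near the segment edges."""
    lo = segment_start + SPLICE_MARGIN
    hi = segment_start + segment_len - SPLICE_MARGIN
    for mu_id, train in trains.items():
        old = buffer.committed.get(mu_id, [])
        kept = [s for s in old if s < lo or s >= hi]
        replaced = [int(s) + segment_start for s in train.spikes
                    if lo <= s + segment_start < hi]
        merged = sorted(set(kept + replaced))
        # collapse near-duplicates at the splice boundaries
        tol = buffer.tol_ms * 1e-3 * buffer.fs
        deduped: list[int] = []
        for s in merged:
            if deduped and s - deduped[-1] <= tol:
                continue
            deduped.append(s)
        buffer.committed[mu_id] = deduped


def make_update_hook(recording: EmgRecording,
                     cfg: UpdateConfig = UpdateConfig(),
                     events: list[UpdateEvent] | None = None,
                     parallel: bool = False) -> UpdateHook:
    """Build the backend-update hook for :func:`mudrive.online.stream_decompose`.

    In sequential mode the update runs inline at each 10-s boundary.  In
    parallel mode the computation runs in a worker thread and the refreshed
    bank is swapped in under a lock before the next window — modelling a
    backend whose latency (in stream time) is below the window increment.
    Both modes produce identical committed trains.
    """
    seg_len = int(round(cfg.segment_s * recording.fs))
    lock = threading.Lock()

    def hook(bank: SeparationBank, at_sample: int,
             buffer: OnlineMustBuffer) -> SeparationBank:
        seg_start = at_sample - seg_len
        if seg_start < 0:
            return bank
        segment = EmgRecording(
            samples=recording.samples[seg_start:at_sample],
            fs=recording.fs, grid=recording.grid)
        result: dict = {}

        def work() -> None:
            new_bank, event, seg_trains = update_bank(
                bank, segment, buffer.trains(), seg_start, cfg)
            with lock:
                result["bank"] = new_bank
                result["event"] = event
                result["trains"] = seg_trains

        if parallel:
            worker = threading.Thread(target=work)
            worker.start()
            worker.join()  # rendezvous before the next window (atomic swap)
        else:
            work()
        with lock:
            new_bank = result["bank"]
            event = result["event"]
            seg_trains = result["trains"]
        if events is not None:
            events.append(event)
        if seg_trains:
            _splice_committed(buffer, seg_start, seg_len, seg_trains)
        return new_bank

    return hook
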