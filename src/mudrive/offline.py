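"""Training-stage (offline) decomposition.

Builds the bank of motor unit separation vectors from an initial recording:
iterate { whiten the residual -> one-unit FastICA (skewness contrast, multiple
restarts) -> Otsu spike extraction -> quality gate -> least-squares MUAP
estimation -> duplicate check -> peel the reconstructed MUAP train off }
until no further units are found.  The accepted vectors are re-expressed in
the whitened space of the ORIGINAL (unpeeled) recording so the online stage
can apply them directly to the raw stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.signal import find_peaks
from skimage.filters import threshold_multiotsu, threshold_otsu

from .core import REFRACTORY_S, EmgRecording, MuapTemplate, SpikeTrain
from .metrics import best_lag_match
from .preprocess import (DEFAULT_EIG_FLOOR, DEFAULT_R, WhiteningModel,
                         apply_whitening, extend, fit_whitening)

logger = logging.getLogger(__name__)

#: Template window around the detected spike marker, s.  Asymmetric: causal
#: band-pass filtering smears each MUAP into a decaying low-frequency tail,
#: so most of the energy lies after the detected peak.
TEMPLATE_PRE_S = 0.020
TEMPLATE_POST_S = 0.125
#: Duplicate threshold: a new unit matching an accepted one above this MR is discarded.
DUPLICATE_MR = 0.5
#: Initializations per unit search (highest-energy residual instants).
N_RESTARTS = 20
#: Quality gate thresholds.
MIN_QUALITY = 4.0
MAX_ISI_CV = 0.4
RATE_RANGE_HZ = (4.0, 40.0)
#: Minimum fraction of ISIs that are within-burst (not pauses): a real
#: regularly-firing unit discharges in runs, sparse false detections do not.
MIN_BURST_FRACTION = 0.5


@dataclass
class SeparationVector:
    """Unit-norm unmixing row in a whitening model's retained space.

    ``threshold`` is the unit's detection threshold on the squared source,
    calibrated from its spike heights when the vector was (re)estimated;
    the online stage applies it directly instead of re-estimating a
    threshold from a 1-s window (part of the knowledge transferred from the
    offline stage).
    """

    weights: np.ndarray
    mu_id: int
    quality: float = 0.0
    threshold: float = 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        norm = np.linalg.norm(self.weights)
        if norm > 0:
            self.weights = self.weights / norm


@dataclass
class SeparationBank:
    """The transferable decomposition state: whitening + vectors + templates."""

    whitening: WhiteningModel
    vectors: list[SeparationVector]
    templates: list[MuapTemplate]
    fs: float
    created_at: int = 0
    version: int = 1

    def __post_init__(self) -> None:
        ids_v = [v.mu_id for v in self.vectors]
        ids_t = [t.mu_id for t in self.templates]
        if ids_v != ids_t:
            raise ValueError("vectors and templates must be index-aligned by mu_id")
        if len(set(ids_v)) != len(ids_v):
            raise ValueError("mu_ids must be unique within a bank")

    @property
    def n_units(self) -> int:
        return len(self.vectors)

    @property
    def mu_ids(self) -> list[int]:
        return [v.mu_id for v in self.vectors]


class EmptyBankError(RuntimeError):
    """Raised when offline decomposition accepts zero units."""


def fastica_one_unit(whitened: np.ndarray, seed: int | None = None,
                     init_vector: np.ndarray | None = None,
                     deflate_against: np.ndarray | None = None,
                     tol: float = 1e-6, max_iter: int = 100) -> SeparationVector:
    """Fixed-point one-unit FastICA with the skewness contrast G(u) = u^3.

    The update is w <- E[z (w'z)^2] (the cubic contrast's gradient on
    whitened data), deflation-orthogonalized against ``deflate_against``
    (rows = accepted vectors) and normalized each iteration.  Skewness fixes
    spike polarity: sparse positive-going sources come out positive.
    """
    z = np.asarray(whitened)
    n, dim = z.shape
    if init_vector is not None:
        w = np.asarray(init_vector, dtype=np.float64).ravel().copy()
    else:
        rng = np.random.default_rng(seed)
        w = rng.standard_normal(dim)
    if deflate_against is not None and deflate_against.size:
        b = np.asarray(deflate_against)
        w = w - b.T @ (b @ w)
    norm = np.linalg.norm(w)
    if norm < 1e-12:  # init lay in the deflated subspace
        w = np.random.default_rng(seed).standard_normal(dim)
        if deflate_against is not None and deflate_against.size:
            w = w - b.T @ (b @ w)
        norm = np.linalg.norm(w)
    w /= norm
    converged = False
    for _ in range(max_iter):
        s = z @ w
        w_new = z.T @ (s * s) / n
        if deflate_against is not None and deflate_against.size:
            w_new = w_new - b.T @ (b @ w_new)
        norm = np.linalg.norm(w_new)
        if norm == 0:
            break
        w_new /= norm
        if abs(1.0 - abs(w_new @ w)) < tol:
            w = w_new
            converged = True
            break
        w = w_new
    return SeparationVector(weights=w, mu_id=-1, converged=converged)


def refine_vector(z: np.ndarray, weights: np.ndarray, fs: float,
                  max_iter: int = 10) -> tuple[np.ndarray, SpikeTrain]:
    """Spike-triggered refinement of a converged separation vector.

    Alternates spike detection on the current source with re-estimating the
    vector as the least-squares reconstructor of the detected binary train
    (closed form z' b / n on whitened data), until the detected train stops
    changing.  A vector that initially exposes only the largest discharges
    converges onto one exposing the unit's full train.
    """
    n = z.shape[0]
    w = np.asarray(weights, dtype=np.float64).copy()
    w /= np.linalg.norm(w)
    prev: np.ndarray | None = None
    train = otsu_spike_detect(z @ w, fs)
    for _ in range(max_iter):
        if train.n_spikes < 2:
            break
        binary = np.zeros(n)
        binary[train.spikes] = 1.0
        w_new = z.T @ binary / n
        norm = np.linalg.norm(w_new)
        if norm == 0:
            break
        w_new /= norm
        new_train = otsu_spike_detect(z @ w_new, fs)
        w = w_new
        if prev is not None and new_train.n_spikes == train.n_spikes and \
                np.array_equal(new_train.spikes, train.spikes):
            train = new_train
            break
        prev = train.spikes
        train = new_train
    return w, train


def detection_threshold(source: np.ndarray, spikes: SpikeTrain,
                        jitter: int = 2) -> float:
    """Per-unit threshold on the squared source: half the median spike height.

    Heights are taken as the local energy maximum within ±``jitter`` samples
    of each spike, so the calibration tolerates the small peak shifts that
    re-whitening introduces.
    """
    if spikes.n_spikes == 0:
        return 0.0
    energy = np.asarray(source) ** 2
    n = energy.size
    heights = [energy[max(0, s - jitter):min(n, s + jitter + 1)].max()
               for s in spikes.spikes]
    return float(0.5 * np.median(heights))


def threshold_spike_detect(source: np.ndarray, fs: float, threshold: float,
                           mu_id: int = -1) -> SpikeTrain:
    """Peaks of the squared source above a precalibrated threshold (>= 10 ms apart)."""
    energy = np.asarray(source, dtype=np.float64) ** 2
    distance = max(int(np.ceil(REFRACTORY_S * fs)), 1)
    peaks, _ = find_peaks(energy, height=threshold, distance=distance)
    return SpikeTrain(mu_id=mu_id, spikes=peaks.astype(np.int64), fs=fs)


def otsu_spike_detect(source: np.ndarray, fs: float, mu_id: int = -1) -> SpikeTrain:
    """Spike extraction by successive multi-threshold Otsu on the squared source.

    A 3-class Otsu split of the squared-amplitude histogram provides the
    upper threshold; local maxima above it (>= 10 ms apart) are candidate
    spikes (2-class Otsu stands in when the histogram has too few distinct
    levels).  When the peaks above the LOWER threshold form a single
    population — the class above the upper threshold is not at least twice
    the middle class in mean height — the upper split is an artefact of a
    two-class histogram and the lower threshold gates instead.  The
    successive step re-applies 2-class Otsu to the retained peak heights and
    drops the low class when it is distinctly lower: class means separated
    by more than 3 low-class standard deviations AND the high mean at least
    double the low mean (the same bimodality rule, keeping the step from
    splitting the unimodal height distribution of a clean unit).
    """
    source = np.asarray(source, dtype=np.float64)
    energy = source**2
    if energy.max() <= 0 or np.ptp(energy) == 0:
        return SpikeTrain(mu_id=mu_id, spikes=np.empty(0, dtype=np.int64), fs=fs)
    distance = max(int(np.ceil(REFRACTORY_S * fs)), 1)
    try:
        lower, upper = threshold_multiotsu(energy, classes=3, nbins=256)
        peaks, props = find_peaks(energy, height=lower, distance=distance)
        heights = props["peak_heights"]
        middle = heights[heights <= upper]
        top = heights[heights > upper]
        if top.size and middle.size and top.mean() > 2.0 * middle.mean():
            keep = heights > upper  # genuine second population above `upper`
            peaks, heights = peaks[keep], heights[keep]
    except ValueError:  # fewer than 3 distinct grey levels
        try:
            gate = threshold_otsu(energy, nbins=256)
        except ValueError:
            return SpikeTrain(mu_id=mu_id, spikes=np.empty(0, dtype=np.int64),
                              fs=fs)
        peaks, props = find_peaks(energy, height=gate, distance=distance)
        heights = props["peak_heights"]
    if peaks.size == 0:
        return SpikeTrain(mu_id=mu_id, spikes=np.empty(0, dtype=np.int64), fs=fs)
    if peaks.size >= 4 and np.ptp(heights) > 0:
        try:
            split = threshold_otsu(heights, nbins=256)
        except ValueError:
            split = None
        if split is not None:
            low, high = heights[heights <= split], heights[heights > split]
            if low.size and high.size:
                sd_low = low.std() if low.size > 1 else 0.0
                if (high.mean() - low.mean() > 3.0 * sd_low
                        and high.mean() > 2.0 * low.mean()):
                    peaks = peaks[heights > split]
    return SpikeTrain(mu_id=mu_id, spikes=peaks.astype(np.int64), fs=fs)


def unit_quality(spikes: SpikeTrain, source: np.ndarray) -> tuple[float, bool]:
    """Separability score and the accept/reject decision for a candidate unit.

    Score: (mean spike peak height - mean sub-threshold local maxima) in
    pooled standard deviation units on the squared source.  Accepted iff
    score >= 4, ISI CV <= 0.3 and mean rate within [4, 40] Hz.
    """
    if spikes.n_spikes < 2:
        return 0.0, False
    energy = np.asarray(source, dtype=np.float64) ** 2
    all_peaks, props = find_peaks(energy, height=0.0)
    if all_peaks.size == 0:
        return 0.0, False
    heights = props["peak_heights"]
    spike_mask = np.isin(all_peaks, spikes.spikes)
    spike_h = heights[spike_mask]
    other_h = heights[~spike_mask]
    if spike_h.size == 0 or other_h.size == 0:
        return 0.0, False
    var_s = spike_h.var(ddof=1) if spike_h.size > 1 else 0.0
    var_o = other_h.var(ddof=1) if other_h.size > 1 else 0.0
    pooled = np.sqrt((var_s + var_o) / 2.0)
    if pooled == 0:
        score = np.inf if spike_h.mean() > other_h.mean() else 0.0
    else:
        score = (spike_h.mean() - other_h.mean()) / pooled
    # ISI statistics over within-burst intervals only: pauses longer than the
    # slowest physiological ISI (task gaps, derecruitment) are excluded
    isis = spikes.isis_s()
    valid = isis[isis <= 1.0 / RATE_RANGE_HZ[0]]
    if valid.size < 2:
        return float(score), False
    cv = valid.std() / valid.mean()
    rate = 1.0 / valid.mean()
    burst_fraction = valid.size / isis.size
    accepted = (score >= MIN_QUALITY and cv <= MAX_ISI_CV
                and RATE_RANGE_HZ[0] <= rate <= RATE_RANGE_HZ[1]
                and burst_fraction >= MIN_BURST_FRACTION)
    return float(score), bool(accepted)


def _spike_matrix_stats(signals: np.ndarray, spikes: np.ndarray,
                        offsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First column/row of S'S (Toeplitz) and S'Y for the LS template problem."""
    n = signals.shape[0]
    length = offsets.size
    diffs = spikes[None, :] - spikes[:, None]
    lags = np.arange(length)
    col = np.array([(diffs == lag).sum() for lag in lags], dtype=np.float64)
    sty = np.zeros((length, signals.shape[1]))
    for a, off in enumerate(offsets):
        idx = spikes + off
        valid = (idx >= 0) & (idx < n)
        sty[a] = signals[idx[valid]].sum(axis=0)
    return col, sty


def estimate_muap(recording_samples: np.ndarray, spikes: SpikeTrain,
                  pre_s: float = TEMPLATE_PRE_S, post_s: float = TEMPLATE_POST_S,
                  mu_id: int | None = None) -> MuapTemplate:
    """Least-squares MUAP template (handles overlapping spikes exactly).

    Solves min_h || y - S h ||^2 per channel, where S places a copy of the
    window [-pre_s, post_s] around every discharge.  Reduces to
    spike-triggered averaging when spikes are separated by more than the
    window.  Falls back to the spike-triggered average if the normal matrix
    is singular.
    """
    y = np.asarray(recording_samples, dtype=np.float64)
    if spikes.n_spikes == 0:
        raise ValueError("cannot estimate a template from an empty spike train")
    fs = spikes.fs
    pre = int(round(pre_s * fs))
    post = int(round(post_s * fs))
    offsets = np.arange(-pre, post)
    col, sty = _spike_matrix_stats(y, spikes.spikes, offsets)
    col = col.copy()
    col[0] *= 1.0 + 1e-9  # tiny ridge against near-singular regular trains
    try:
        h = solve_toeplitz((col, col), sty)
        fallback = False
    except np.linalg.LinAlgError:
        h = sty / max(spikes.n_spikes, 1)
        fallback = True
    tpl = MuapTemplate(mu_id=spikes.mu_id if mu_id is None else mu_id,
                       waveforms=h.T, pre_samples=pre)
    if fallback:
        logger.warning("singular normal matrix for mu %s: fell back to STA",
                       tpl.mu_id)
    return tpl


def reconstruct_train(template: MuapTemplate, spikes: SpikeTrain,
                      n_samples: int) -> np.ndarray:
    """Place the template at every discharge, honoring its spike-marker offset."""
    out = np.zeros((n_samples, template.n_channels))
    length = template.length
    w = template.waveforms.T  # (L, n_ch)
    for s in spikes.spikes:
        a = s - template.pre_samples
        b = a + length
        wa, wb = max(0, -a), length - max(0, b - n_samples)
        a, b = max(a, 0), min(b, n_samples)
        out[a:b] += w[wa:wb]
    return out


def peel_off(samples: np.ndarray, templates: list[MuapTemplate],
             spike_trains: list[SpikeTrain]) -> np.ndarray:
    """Subtract reconstructed MUAP trains; returns the residual."""
    residual = np.asarray(samples, dtype=np.float64).copy()
    n = residual.shape[0]
    for tpl, train in zip(templates, spike_trains):
        if train.n_spikes:
            residual -= reconstruct_train(tpl, train, n)
    return residual


def vector_for_source(whitened: np.ndarray, source: np.ndarray) -> np.ndarray:
    """Least-squares vector reproducing ``source`` from whitened data (cov = I)."""
    return whitened.T @ source / whitened.shape[0]


@dataclass
class ApfpConfig:
    max_units: int = 20
    #: consecutive no-accept rounds before stopping; the search is fully
    #: deterministic, so a repeated round cannot turn out differently
    max_rejections: int = 1
    extension_factor: int = DEFAULT_R
    eig_floor: float = DEFAULT_EIG_FLOOR
    n_restarts: int = N_RESTARTS
    template_pre_s: float = TEMPLATE_PRE_S
    template_post_s: float = TEMPLATE_POST_S
    duplicate_mr: float = DUPLICATE_MR
    duplicate_max_lag_ms: float = 50.0
    max_iter: int = 100
    tol: float = 1e-4  # the spike-triggered refinement supplies precision
    init_min_sep_s: float = 0.05  # spacing between energy-peak initializations
    #: source shifts (samples) deflated per accepted unit: a unit's delayed
    #: copies are equally valid convolutive sources and must be blocked too
    deflate_shifts: tuple[int, ...] = tuple(range(-40, 41, 4))


def run_apfp(recording: EmgRecording, cfg: ApfpConfig | None = None,
             seed: int = 0) -> tuple[SeparationBank, list[SpikeTrain]]:
    """Automatic progressive FastICA peel-off over a training recording.

    Returns the separation bank (vectors expressed against the original
    recording's whitening model) and the accepted offline spike trains.
    """
    cfg = cfg or ApfpConfig()
    if recording.duration_s < 5.0:
        raise ValueError("offline decomposition needs at least 5 s of data")
    fs = recording.fs
    rng = np.random.default_rng(seed)
    x0 = recording.samples
    ext0 = extend(x0, cfg.extension_factor)
    whitening0 = fit_whitening(ext0, cfg.extension_factor, cfg.eig_floor)
    z0 = apply_whitening(whitening0, ext0)

    residual = x0.copy()
    accepted_vectors: list[SeparationVector] = []
    accepted_templates: list[MuapTemplate] = []
    accepted_trains: list[SpikeTrain] = []
    accepted_sources: list[np.ndarray] = []
    rejections = 0
    next_id = 0

    def is_duplicate(train: SpikeTrain) -> bool:
        return any(
            best_lag_match(train, acc, max_lag_ms=cfg.duplicate_max_lag_ms)[0].mr
            > cfg.duplicate_mr for acc in accepted_trains)

    while len(accepted_vectors) < cfg.max_units and rejections < cfg.max_rejections:
        ext_r = extend(residual, cfg.extension_factor)
        try:
            wm_r = fit_whitening(ext_r, cfg.extension_factor, cfg.eig_floor)
        except ValueError:
            break
        z_r = apply_whitening(wm_r, ext_r)
        # deflate restarts against the already-accepted sources, mapped into
        # the current whitened space (their peeled remnants otherwise attract
        # the fixed-point iteration back to known units)
        if accepted_sources:
            basis = np.stack([
                vector_for_source(z_r, np.roll(s, d))
                for s in accepted_sources for d in cfg.deflate_shifts
            ])
            n_defl = min(basis.shape[0], z_r.shape[1] - 10)
            q, _ = np.linalg.qr(basis.T)
            deflate = np.ascontiguousarray(q.T[:n_defl])
        else:
            deflate = None
        # initialize at the residual's highest-energy instants: whitened
        # observations at putative discharges converge onto that unit's
        # separation vector far more reliably than random directions
        energy = np.sum(residual**2, axis=1)
        peak_idx, _ = find_peaks(energy,
                                 distance=max(int(cfg.init_min_sep_s * fs), 1))
        init_times = peak_idx[np.argsort(energy[peak_idx])[::-1]]
        init_times = init_times[: cfg.n_restarts]
        candidates: list[tuple[float, SpikeTrain, np.ndarray]] = []
        for t_init in init_times:
            cand = fastica_one_unit(z_r, init_vector=z_r[t_init],
                                    deflate_against=deflate,
                                    tol=cfg.tol, max_iter=cfg.max_iter)
            if not cand.converged:
                continue
            w_ref, train = refine_vector(z_r, cand.weights, fs)
            train.mu_id = next_id
            source = z_r @ w_ref
            score, ok = unit_quality(train, source)
            logger.debug("  init t=%d: n=%d score=%.1f ok=%s", t_init,
                         train.n_spikes, score, ok)
            if ok:
                candidates.append((score, train, source))
        # best non-duplicate candidate wins the round (the highest-scoring
        # one is often a residue of an already-peeled unit)
        accepted_one = False
        for score, train, source in sorted(candidates, key=lambda c: -c[0]):
            # duplicate check with lag alignment (the same unit can be
            # recovered at a different constant delay in a different
            # whitened space)
            if is_duplicate(train):
                continue
            template = estimate_muap(residual, train, cfg.template_pre_s,
                                     cfg.template_post_s)
            # re-express the unit in the ORIGINAL whitened space: LS vector
            # reproducing the detected source from the unpeeled stream
            w0 = vector_for_source(z0, source)
            vec = SeparationVector(weights=w0, mu_id=next_id, quality=score)
            # re-detect on the original stream with the re-expressed vector
            # so the bank's trains are exactly what the online stage produces
            source0 = z0 @ vec.weights
            train0 = otsu_spike_detect(source0, fs, mu_id=next_id)
            score0, ok0 = unit_quality(train0, source0)
            if not ok0 or is_duplicate(train0):
                logger.debug("round: candidate failed re-expression (ok=%s)",
                             ok0)
                continue
            vec.quality = score0
            vec.threshold = detection_threshold(source0, train0)
            accepted_vectors.append(vec)
            accepted_templates.append(template)
            accepted_trains.append(train0)
            accepted_sources.append(source)
            next_id += 1
            residual = peel_off(residual, [template], [train])
            logger.info("accepted unit %d (quality %.1f, %d spikes)",
                        vec.mu_id, score0, train0.n_spikes)
            accepted_one = True
            break
        if accepted_one:
            rejections = 0
        else:
            logger.debug("round: no acceptable new unit (rejection %d)",
                         rejections + 1)
            rejections += 1
    if not accepted_vectors:
        raise EmptyBankError("offline decomposition accepted zero units")
    bank = SeparationBank(whitening=whitening0, vectors=accepted_vectors,
                          templates=accepted_templates, fs=fs)
    return bank, accepted_trains
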