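"""Force-prediction and decomposition-accuracy metrics.

RMSD (percent of the normalized force scale), the coefficient of
determination R², and the spike-train matching rate

    MR = 2 * N_com / (N1 + N2)

where N_com counts one-to-one matched spikes within a timing tolerance
(default ±1 ms).  MR is the decomposition-accuracy measure: an online train
is scored by its best-matching reference train.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SpikeTrain

#: Default spike-match tolerance wherever two trains are compared, ms.
DEFAULT_TOL_MS = 1.0


def rmsd(pred: np.ndarray, meas: np.ndarray) -> float:
    """Root-mean-square deviation in percent of the normalized force scale."""
    pred = np.asarray(pred, dtype=np.float64)
    meas = np.asarray(meas, dtype=np.float64)
    if pred.shape != meas.shape:
        raise ValueError("pred and meas must have the same length")
    return float(np.sqrt(np.mean((pred - meas) ** 2)) * 100.0)


def r_squared(pred: np.ndarray, meas: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (may be negative)."""
    pred = np.asarray(pred, dtype=np.float64)
    meas = np.asarray(meas, dtype=np.float64)
    if pred.shape != meas.shape:
        raise ValueError("pred and meas must have the same length")
    ss_tot = np.sum((meas - meas.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("measured force is constant; R^2 undefined")
    ss_res = np.sum((pred - meas) ** 2)
    return float(1.0 - ss_res / ss_tot)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching two spike trains."""

    n1: int
    n2: int
    n_common: int

    @property
    def mr(self) -> float:
        if self.n1 + self.n2 == 0:
            return 0.0
        return 2.0 * self.n_common / (self.n1 + self.n2)


def match_spikes(a: np.ndarray, b: np.ndarray, tol_samples: float) -> int:
    """One-to-one greedy matching by temporal proximity; returns N_com.

    Candidate pairs within the tolerance are accepted in order of increasing
    |dt|, each spike used at most once — symmetric in (a, b).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size == 0 or b.size == 0:
        return 0
    # candidate pairs: for each a-spike, b-spikes within tolerance
    lo = np.searchsorted(b, a - tol_samples, side="left")
    hi = np.searchsorted(b, a + tol_samples, side="right")
    pairs = [
        (abs(int(a[i]) - int(b[j])), i, j)
        for i in range(a.size)
        for j in range(lo[i], hi[i])
    ]
    pairs.sort()
    used_a = np.zeros(a.size, dtype=bool)
    used_b = np.zeros(b.size, dtype=bool)
    n_com = 0
    for _, i, j in pairs:
        if not used_a[i] and not used_b[j]:
            used_a[i] = used_b[j] = True
            n_com += 1
    return n_com


def matching_rate(a: SpikeTrain, b: SpikeTrain,
                  tol_ms: float = DEFAULT_TOL_MS) -> MatchResult:
    """Matching rate between two spike trains at the given tolerance."""
    if a.fs != b.fs:
        raise ValueError("spike trains must share a sampling rate")
    tol_samples = tol_ms * 1e-3 * a.fs
    n_com = match_spikes(a.spikes, b.spikes, tol_samples)
    return MatchResult(n1=a.n_spikes, n2=b.n_spikes, n_common=n_com)


def best_lag_match(a: SpikeTrain, b: SpikeTrain, tol_ms: float = DEFAULT_TOL_MS,
                   max_lag_ms: float = 25.0) -> tuple[MatchResult, int]:
    """Matching rate after aligning ``b`` by its best constant lag.

    Convolutive decomposition recovers each source up to an arbitrary
    constant delay (bounded by the MUAP support plus the extension depth),
    so comparisons against ground truth or across whitening spaces first
    estimate the dominant lag from the pairwise spike-time differences, then
    match at the usual tolerance.  Returns the match and the lag (samples)
    that was applied to ``b``.
    """
    if a.fs != b.fs:
        raise ValueError("spike trains must share a sampling rate")
    max_lag = int(round(max_lag_ms * 1e-3 * a.fs))
    tol_samples = tol_ms * 1e-3 * a.fs
    if a.n_spikes == 0 or b.n_spikes == 0:
        return MatchResult(a.n_spikes, b.n_spikes, 0), 0
    diffs = []
    lo = np.searchsorted(b.spikes, a.spikes - max_lag, side="left")
    hi = np.searchsorted(b.spikes, a.spikes + max_lag, side="right")
    for i in range(a.n_spikes):
        diffs.extend(int(a.spikes[i]) - b.spikes[lo[i]:hi[i]])
    if not diffs:
        return MatchResult(a.n_spikes, b.n_spikes, 0), 0
    # lag with the most pairwise differences within the tolerance of it
    diffs_sorted = np.sort(np.asarray(diffs))
    candidates = np.unique(diffs_sorted)
    scores = (np.searchsorted(diffs_sorted, candidates + tol_samples, "right")
              - np.searchsorted(diffs_sorted, candidates - tol_samples, "left"))
    lag = int(candidates[np.argmax(scores)])
    n_com = match_spikes(a.spikes, b.spikes + lag, tol_samples)
    return MatchResult(a.n_spikes, b.n_spikes, n_com), lag


def pair_musts(online: list[SpikeTrain], reference: list[SpikeTrain],
               tol_ms: float = DEFAULT_TOL_MS) -> list[dict]:
    """Score each online train by its best-matching reference train.

    Returns one record per online train with the paired reference mu_id and
    the maximum MR (the decomposition accuracy).  Ties go to the lower
    reference mu_id.
    """
    if not online or not reference:
        raise ValueError("both spike-train sets must be non-empty")
    results = []
    for tr in online:
        best_mr, best_ref = -1.0, None
        for ref in sorted(reference, key=lambda r: r.mu_id):
            mr = matching_rate(tr, ref, tol_ms).mr
            if mr > best_mr:
                best_mr, best_ref = mr, ref.mu_id
        results.append({"mu_id": tr.mu_id, "ref_id": best_ref, "accuracy": best_mr})
    return results
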