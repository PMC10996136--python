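# Methods

`mudrive` implements an online, motor-unit-driven muscle force predictor for
high-density surface EMG (HD-sEMG), together with the forward simulator used
to validate it. This note records the models, the numerical choices, and the
places where the design was genuinely open.

## Problem setting

A 64-channel electrode grid (8 × 8, 4-mm pitch, 2 kHz sampling) over a small
hand muscle records the superposition of motor unit action potential (MUAP)
trains during isometric trapezoid force tasks (2-s ramp to 20–30 % MVC, 3-s
hold). The goal is to predict the contraction force in real time from the
discharge timings of individual motor units (MUs), and to keep doing so
during prolonged contractions, when slow changes in the tissue and
electrode–muscle geometry degrade any decomposition model fitted once at the
start.

The system is two-stage:

1. **Training stage (offline).** The first 15 s of data are decomposed by an
   automatic progressive FastICA peel-off loop into a bank of per-MU
   *separation vectors* (linear projections of the extended, whitened EMG
   that isolate one MU's spike source), per-MU detection thresholds, and
   least-squares MUAP templates. The decoded spike trains are transformed
   into per-channel twitch-force trains and a small convolutional-recurrent
   network is trained to map 0.2-s twitch-force maps to the measured force.
2. **Online stage.** A frontend slides a 1-s window in 0.2-s steps over the
   stream, applies the stored whitening and separation vectors, detects
   spikes with the stored per-unit thresholds, tracks identity over the
   0.8-s overlap and commits only the newest 0.2 s. A backend refreshes
   every separation vector by a reference-anchored constrained fixed-point
   iteration on the latest 5-s segment at 10-s intervals, and the refreshed
   bank is swapped in atomically between windows.

## Twitch-force model

Each discharge of MU *i* contributes a second-order twitch

    f_i(t) = (P_i · t / T_i) · exp(1 − t / T_i),

which peaks at t = T_i with value exactly P_i. Contraction time follows the
inverse power law T_i = T_L · (1/P_i)^(1/c) with T_L = 90 ms and c = 4.2;
amplitudes below 1 (normalized units) are capped at T_L, which keeps the
physiological meaning of "maximal contraction time" for low-amplitude
channels. During sustained firing each discharge is scaled by the gain

    g = 1                                          if T/ISI ≤ 0.4,
    g = k · (1 − exp(−2 (T/ISI)³)) / (T/ISI)       otherwise,

where ISI is the interval to the preceding discharge and
k = 0.4 / (1 − exp(−2·0.4³)) ≈ 3.3293 makes the gain continuous at the
knee. The first discharge of a train has no preceding ISI and receives
g = 1 (the low-rate limit). The model is applied per electrode channel with
P taken equal to the channel's MUAP peak-to-peak amplitude (the
proportionality constant is absorbed by the downstream network). Per-MU
twitch trains are sliced into non-overlapping 400-sample (0.2-s) windows
and reshaped to the 8 × 8 grid, giving 400 × 8 × 8 × N tensors; the label is
the MVC-normalized measured force over the same samples (labels recorded on
a coarser grid are linearly resampled to 400 points).

## Decomposition

**Preprocessing.** Causal 10th-order Butterworth band-pass (20–500 Hz,
second-order sections) followed by a 50 Hz notch (Q = 30). Causal filtering
is used offline as well, so the separation vectors transfer to the online
stream unchanged. Each channel is *extended* with R = 10 delayed copies
(the conventional factor for 64-channel decomposition), and the extended
data are whitened by an eigenvalue decomposition, discarding eigenvalues
below 10⁻⁶ of the largest.

**Unit search.** The training-stage loop repeats: re-extend and re-whiten
the current residual; run one-unit FastICA with the skewness contrast
G(u) = u³ (spike sources are sparse and positively skewed, and the cubic
contrast fixes polarity) from 20 deterministic initializations — the
whitened observation vectors at the residual's highest-energy instants,
which converge onto genuine units far more reliably than random directions;
refine each converged candidate by alternating spike detection with the
least-squares fixed point w ← Zᵀb/n of the detected binary train (this
"spike-triggered" refinement turns a vector that exposes only the tallest
discharges into one exposing the unit's full train); gate candidates on a
separability score (≥ 4 pooled-s.d. units between spike and non-spike peak
heights), within-burst ISI statistics (CV ≤ 0.4, rate 4–40 Hz, at least
half of all ISIs within-burst), and a lag-aligned duplicate check; accept
the best new unit, estimate its MUAP by least squares, and peel its
reconstruction from the residual. The search stops at `max_units` or after
a round that accepts nothing (the loop is fully deterministic, so repeating
a failed round cannot help).

Numerical details that proved load-bearing:

- **Spike detection** squares the source and takes local maxima (≥ 10 ms
  apart) above the upper threshold of a 3-class Otsu split — unless the
  peaks above the *lower* threshold form a single population (high class
  mean < 2 × middle class mean), in which case the upper split is an
  artefact of an effectively two-class histogram and the lower threshold
  gates instead. A successive 2-class Otsu over the retained peak heights
  then drops the lower class only when it is *distinctly* lower (class
  means ≥ 3 low-class s.d. apart *and* high mean ≥ 2 × low mean). Without
  these bimodality guards the thresholds bisect the unimodal height
  distribution of a clean unit, discarding half its discharges.
- **Template windows** are asymmetric, −20 ms to +125 ms around the
  detected peak: the causal 20-Hz high-pass edge rings, smearing each MUAP
  into a decaying tail (measured 1 %-support ≈ 125 ms); shorter windows
  leave spike-locked residue that the peel-off cannot remove and the unit
  search keeps rediscovering. The least-squares estimator solves the full
  Toeplitz normal equations, so overlapping discharges are handled exactly;
  it reduces to spike-triggered averaging for well-separated spikes.
- **Delayed copies.** In the extension framework every unit is recoverable
  at a range of constant delays. Comparisons against ground truth or across
  whitening spaces therefore align trains by their dominant pairwise lag
  before matching; the duplicate check searches lags up to ±50 ms; and the
  search deflates candidate vectors against the already-accepted sources
  *and their time-shifted copies* (±40 samples).
- **Transferable thresholds.** Each accepted unit stores a detection
  threshold (half the median spike energy height on its source). The online
  stage applies the stored threshold directly — re-estimating an Otsu
  threshold inside a single 1-s window is unstable whenever the window
  catches a silent ramp.

**Online tracking.** Per window: extend, whiten with the bank's stored
model, project each separation vector, detect with the stored threshold.
Spikes in the 0.8-s overlap confirm identity against already-committed
spikes (matching rate ≥ 0.5; failure flags the unit unstable for that
window but identity is kept — it is carried by the separation vector);
only spikes in the final 0.2 s are committed, with ±1 ms duplicate merging.
Spike-time comparisons throughout use a ±1 ms tolerance.

**Backend update.** Every 10 s, on the latest 5-s segment: refit the
whitening (drift invalidates the old second-order statistics — this is the
point of the update); map each vector into the new space through its
projected source; re-converge it with the committed spikes in the segment
as reference, blending the carried vector with the closed-form constraint
vector Zᵀr/n and iterating the spike-triggered fixed point; verify identity
against the reference (≥ 0.5 matching rate, else keep the carried vector);
and adopt the re-converged vector only if it separates the unit on the
segment better than the carried one — a vector re-estimated from 5 s
carries more variance than the bank's, and swapping it in unconditionally
measurably degraded stationary units. The unit's detection threshold is
recalibrated from its spike heights on the adopted source, damped by a
geometric mean with the running value (the 5-s re-estimate is a median
over a few dozen spikes and correspondingly noisy). Units with fewer than
5 reference spikes in the segment are skipped (carried over, re-expressed
in the new space). Committed spikes inside the segment (excluding 40-sample edge
margins) are replaced by the post-update detection; the correction horizon
is the segment itself. No peel-off is run online. In the deterministic
sequential mode the update executes at its 10-s boundary before the next
window; the threaded mode computes it in a worker and swaps under a lock at
the same boundary, so both modes commit identical trains.

## Force network

Per 0.2-s sample (400 × 8 × 8 × N): a time-distributed 3 × 3 convolution
with 16 filters (stride 1, same padding, ReLU) over the grid, flattened and
fed to LSTM(64) → LSTM(1), both returning sequences, then a per-step linear
readout → 400 × 1 force. Training: Adam at 0.001, batch 32, RMSD loss
(per-window RMSD in percent, averaged over the batch), chronological 2:1
train/validation split, best-validation-epoch weights kept. Inputs are
scaled by the training set's maximum absolute value (stored with the
model); predictions are clipped to [0, 1.2] MVC. The desk-scale default is
30 epochs (the full recipe, 150, is a config switch away; on the synthetic
data the validation loss plateaus well before 30). The layers, backprop and
Adam are implemented in numpy inside the package (float32, single-threaded,
bit-deterministic given the seed).

The comparison baselines are quadratic polynomial regressions of force on
(a) the pooled MU firing count and (b) the channel-averaged RMS amplitude,
both over 250-ms windows advanced by 50 ms, with window-centre predictions
linearly interpolated back to the sample grid.

## Synthetic data

No recordings accompany the method, so validation uses a forward simulator
whose defaults define the study conditions: a 10-unit pool with recruitment
thresholds uniform in [0.02, 0.25] of maximal drive, rates interpolating
8→35 Hz with excitation, Gaussian ISIs with CV 0.15 floored at a 10-ms
refractory period, and twitch amplitudes geometric from 1 to 5 (size
principle; the modest spread keeps all units decomposable at the grid's
dynamic range). MUAPs are smooth unimodal spatial profiles (distinct
territory centres, σ 1.2–2.2 electrodes) times zero-mean
biphasic/triphasic Gaussian-derivative waveforms (width 1.5–3 ms), with
grid-maximum peak-to-peak amplitude 80 µV per unit of twitch amplitude.
Channels sum MUAP trains linearly; white Gaussian noise is added at a
20 dB session SNR. Excitation follows the task profile (default: three
5-s trapezoids to 30 % MVC for training; twelve for the 60-s test stream),
and the ground-truth force is the twitch-model superposition over the pool,
scaled so the hold sits at the target level.

Nonstationarity is modelled by a drift schedule: each channel's gain ramps
linearly from 1.0 to its own endpoint, drawn once from 0.8 ± 0.15, and 20 %
of a 1-sample-shifted template is mixed in by the end of the trial. The
per-channel endpoint spread matters: a channel-uniform ramp only rescales
the sources and leaves the separation vectors valid, whereas differential
per-channel scaling rotates the mixing directions — the phenomenon the
backend update exists to track. Under these conditions (60-s stream) the
frozen bank's mean per-MU matching rate falls to ≈ 0.964 while the updated
bank holds ≈ 0.994, with the gap concentrated in the final 20 s.

What the simulator does **not** model: volume-conductor physics, spatially
correlated noise, fatigue-induced spectral compression, electrode-skin
impedance changes, non-isometric geometry, and MUAP shape changes beyond
the amplitude/shift drift above. Passing tests on this data therefore show
the pipeline's algorithmic correctness and its drift-tracking behaviour
under controlled nonstationarity — not performance on real recordings.

## Degenerate inputs and tie-breaks

Flat sources detect no spikes; sources with fewer than three distinct
energy levels fall back from 3-class to 2-class Otsu; a singular template
normal matrix falls back to spike-triggered averaging (logged); a
rank-deficient whitening fit raises, and during an update aborts the update
leaving the old bank in place; units with fewer than 2 window spikes emit
nothing but stay in the bank; reference ties in MUST pairing go to the
lower reference id. Every stochastic component (pool realization, firing,
noise, network init, batch shuffling) derives from a single integer seed,
and the full pipeline is bit-reproducible given it.

## Problem sizes

The bundled experiments use 15 s of training data (75 network samples),
a 60-s test stream, banks of 8–12 units and 30 training epochs — sizes
chosen so the complete synthetic study runs comfortably on a laptop CPU
while exercising every stage of the method at the task parameters above.
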