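# mudrive

Online motor-unit-driven muscle force prediction from high-density surface
EMG (HD-sEMG), with adaptive real-time decomposition.

Surface EMG over a muscle is the algebraic sum of motor unit action
potential (MUAP) trains. Decomposing a 64-channel (8 × 8) recording into
individual motor unit (MU) spike trains gives direct access to the neural
drive, and the discharge timings predict contraction force better than
global amplitude features — but only while the decomposition stays valid.
During prolonged contractions, slow changes in the tissue and
electrode–muscle geometry degrade separation models fitted once at the
start. `mudrive` is for researchers in myoelectric control and motor
neuroscience who want a complete, testable implementation of a two-stage
answer to that problem:

- **Training stage** — automatic progressive FastICA peel-off over the
  first 15 s of data builds a bank of per-MU *separation vectors* (linear
  projections of the extended, whitened EMG isolating one MU's spike
  source), detection thresholds and least-squares MUAP templates; decoded
  spike trains become twitch-force maps that train a conv + LSTM network to
  predict force.
- **Online stage** — a frontend decomposes sliding 1-s windows (0.2-s
  increment) with the stored bank and feeds per-window twitch-force tensors
  to the network, while a backend refreshes every separation vector by
  constrained (reference-anchored) FastICA on the latest 5-s segment every
  10 s and swaps the bank atomically between windows.

The force model is the classical twitch superposition: each discharge of
MU *i* adds f_i(t) = (P_i·t/T_i)·e^{1−t/T_i}, with contraction time
T_i = T_L·(1/P_i)^{1/c} (T_L = 90 ms, c = 4.2) and a piecewise rate gain
g = 1 for T/ISI ≤ 0.4, else k·(1−e^{−2(T/ISI)³})/(T/ISI) with k fixed by
continuity (≈ 3.329). Performance metrics are RMSD (percent of the
normalized force scale), R², and the matching rate between spike trains,
MR = 2·N_com/(N₁+N₂) at ±1 ms tolerance.

Because no public dataset accompanies the method, the package ships a
forward simulator (`mudrive.synthetic`) that generates grid EMG from a
rate-coded motor unit pool performing trapezoid force tasks, with
controllable noise and slow waveform drift to exercise the adaptive update.
See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
from mudrive.experiment import ExperimentConfig, run_experiment

result = run_experiment(ExperimentConfig(seed=0))
print(result.table.to_string(index=False))
print(f"mean MR: update {result.accuracy_update:.3f}, "
      f"no update {result.accuracy_no_update:.3f}")
```

prints (seed 0):

```
               arm  seed  level  rmsd_pct       r2
   proposed_update     0    0.3  2.334756 0.937896
proposed_no_update     0    0.3  2.402211 0.934255
                fr     0    0.3  3.529734 0.858054
               rms     0    0.3  4.148710 0.803906
mean MR: update 0.994, no update 0.964
```

Reading it: a 15-s stationary synthetic session initializes the bank
(10-unit pool, 30 % MVC trapezoids, 20 dB SNR) and trains the network; a
60-s drifting test stream is then decomposed online four ways. The
MU-driven predictions (2.3–2.4 % RMSD, R² ≈ 0.94) beat the firing-rate and
RMS regression baselines, and the backend update comes out ahead of the
frozen bank on every metric. The last line gives mean per-MU decomposition
accuracies (matching rate against the simulator's ground-truth spike
trains): the update's clearest effect is here — it recovers the three
accuracy points the frozen bank loses as the waveforms drift, with the gap
concentrated in the last third of the stream.

The same stages are scriptable from the shell:

```bash
mudrive simulate --seed 0 --trials 3 --out session.h5
mudrive train --data session.h5 --bank bank.h5
mudrive stream --data test.h5 --bank bank.h5 --out spikes.csv
mudrive eval --seed 0 --out results.csv
```

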