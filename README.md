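# emgflow

Two-stage hand-gesture recognition from multichannel surface EMG (sEMG):

1. **Relabel** — cue-paced label streams lag actual muscle activity by the
   subject's reaction time. The discrete Teager–Kaiser energy
   ψ[x](n) = x(n)² − x(n−1)·x(n+1), averaged over channels, smoothed, and
   thresholded with duration hysteresis, locates activity in the signal
   itself and rewrites the labels.
2. **Coarse stage** — gestures are grouped into superclasses (finger /
   wrist / functional movements) that differ in contraction force; an SVM
   (RBF, C = 18) on per-window time-domain features (RMS, MAV, DASDV, …)
   routes each 400 ms window to a superclass.
3. **Decompose** — multivariate variational mode decomposition (MVMD)
   extracts K joint narrow-band modes u_k(t), one shared center frequency
   ω_k per mode, by ADMM in the frequency domain:

       minimize  Σ_k Σ_c ‖∂_t[u⁺_k,c(t) e^{−jω_k t}]‖²
       subject to Σ_k u_k,c(t) = x_c(t)

   The lowest-frequency mode (the "modified EMG") carries the repeatable
   movement information.
4. **Fine stage** — per superclass, a compact CNN on the per-window mode
   stack resolves the exact gesture. Every convolution is
   depthwise-separable (k·k·c + c·N + N trainable parameters instead of
   k·k·c·N + N), implemented in NumPy with exact per-layer parameter
   accounting.

It targets researchers prototyping sEMG recognition pipelines: every stage
is a scikit-learn-style estimator usable on Ninapro DB1 MAT-files
(10 channels, 100 Hz, 52 gestures) or on the built-in synthetic generator,
so the whole framework is testable without any download.

## Worked example

```python
import numpy as np
import emgflow as ef
from emgflow.classifiers import ScnnSpec

# 1. simulate the reference task at a small size: 12 gestures, 8 repetitions
plan = ef.benchmark_plan(n_repetitions=8, seed=42)
rec = ef.zscore(ef.simulate_recording(plan))

# 2. relabel active segments from the signal itself
relabeler = ef.TeagerRelabeler()
rec = relabeler.transform(rec)
print(f"detected {len(relabeler.intervals_.intervals)} active intervals "
      f"(true: {len(ef.true_intervals(plan))})")

# 3. cut 400 ms windows and decompose
scmap = ef.benchmark_superclass_map(plan)
wins = ef.segment(rec, 400, scmap)
X = np.stack([w.data for w in wins])
y = np.array([w.label for w in wins])
print(f"{len(wins)} windows of shape {X.shape[1:]}")

mt = ef.mvmd_decompose(X[0], fs=100.0)
print("window 0 center frequencies (Hz):", np.round(mt.center_freqs, 2))

# 4. parameter accounting of the fine-stage network
_, counts = ef.build_scnn(ScnnSpec(input_shape=(30, 10, 1), n_classes=12))
for row in counts:
    print(f"{row.layer_name:<14} standard {row.params_standard:>7}  "
          f"separable {row.params_separable:>7}")

# 5. train and evaluate the two-stage pipeline (fivefold here for speed)
tax = ef.GestureTaxonomy.from_map(scmap)
model = ef.TwoStageClassifier(tax, fs=100.0, conv_filters=(8, 16, 32),
                              dense_units=64, epochs=15, patience=5,
                              random_state=0)
report = ef.crossvalidate(X, y, model, folds=5, seed=0)
print(f"stage-1 accuracy {report.stage1_accuracy:.3f}, "
      f"end-to-end accuracy {report.end_to_end_accuracy:.3f}")
```

Output:

```
detected 96 active intervals (true: 96)
192 windows of shape (40, 10)
window 0 center frequencies (Hz): [1.000e-02 1.988e+01 2.368e+01 3.581e+01]
Input          standard       0  separable       0
Convolution1   standard     320  separable      73
Convolution2   standard   18496  separable    2400
Convolution3   standard   73856  separable    8896
Dense          standard  344192  separable  344192
Softmax        standard    1548  separable    1548
stage-1 accuracy 1.000, end-to-end accuracy 0.984
```

Reading it: the relabeler recovered all 96 activity intervals despite the
±200 ms label jitter. The first mode of the window sits near DC — the slow
envelope component that makes the "modified EMG" consistent across
repetitions — while the remaining three tile the 15–45 Hz activity band.
The parameter table shows why the separable network is the lightweight
choice: the three convolutions shrink from 320/18 496/73 856 to
73/2400/8896 trainable parameters at identical configuration. The pipeline
separates all three force levels perfectly (stage 1) and nearly all of the
12 gestures end to end.

The same flow is scriptable from the shell:

```sh
emgflow simulate --seed 3 --repetitions 8 --out rec.h5
emgflow relabel --in rec.h5 --out rec_rl.h5 --report intervals.csv
emgflow decompose --in rec.h5 --k 4 --out modes.h5
emgflow features --in rec_rl.h5 --config cfg.yaml --out feats.csv
emgflow train-stage1 --features feats.csv --method svm --out stage1.joblib
emgflow evaluate --in rec.h5 --config cfg.yaml --folds 10 --report report.json
```

where `cfg.yaml` holds the run configuration (window length, mode count K,
detector settings, the gesture→superclass map, seed).

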