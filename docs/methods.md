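# Methods

## The problem and the model

Surface EMG (sEMG) gesture recognition over many classes degrades as the
label set grows: flat classifiers need either heavy feature engineering or
large networks. `emgflow` implements a coarse-to-fine alternative. Gestures
are first partitioned into a small number of *superclasses* (finger, wrist,
functional/grasping movements) that differ mainly in contraction force —
a property that cheap time-domain features track well. A lightweight
classical model (stage 1) routes each analysis window to a superclass; a
compact convolutional network per superclass (stage 2) then resolves the
exact gesture from a spatial–temporal image built by multivariate
variational mode decomposition (MVMD). The stage-1 decision is carried
forward even when wrong, so the predicted gesture always lies in the
predicted superclass.

## Relabeling with the Teager–Kaiser operator

Cue-paced protocols label samples by stimulus timing, so the label stream
lags actual muscle activity by the subject's reaction time. We locate
activity directly in the signal with the discrete Teager–Kaiser energy
ψ[x](n) = x(n)² − x(n−1)·x(n+1) (boundary samples replicate the nearest
interior value), averaged across channels and smoothed with a causal
moving window of `N` samples (default 0.1 s). Detection uses a hard
threshold with duration hysteresis: an interval opens (closes) at the
first sample of a run of at least `min_active_ms` (default 50 ms)
supra-(sub-)threshold samples. Samples inside detected intervals take the
majority original gesture id; everything else becomes rest.

The default threshold is the mean + 3·SD of the *lowest-energy half* of
the smoothed trace. The lower half is rest-dominated whenever rest
occupies at least half the duty cycle (true of cue-paced protocols), and —
unlike a bottom-decile estimate — its spread covers the serial correlation
the moving average induces; a decile-based cut produced hundreds of
spurious rest detections on the synthetic benchmark, the half-based cut
recovers every interval with onset errors of ~3 samples.

## MVMD

MVMD extracts K joint narrow-band modes u_k(t) with one shared center
frequency ω_k per mode, minimizing the summed bandwidth of the
baseband-demodulated analytic mode signals subject to (approximate)
reconstruction. We solve it in the one-sided frequency domain by ADMM with
Gauss–Seidel sweeps: a Wiener-filter mode update per channel
û_k,c ← (x̂_c − Σ_{i≠k} û_i,c + λ̂_c/2)/(1 + 2α(ω − ω_k)²), a joint
spectral-centroid update for ω_k pooled over channels, and dual ascent
with step τ; iteration stops when the relative change
Σ_k Σ_c ‖Δû_k,c‖²/‖û_k,c‖² falls below `tol`.

Numerical choices:

* **α = 2000** (bandwidth penalty): narrow enough to separate tones a few
  Hz apart at fs = 100 Hz, the regime of the data.
* **τ = 0** (default): noise-robust reconstruction; the residual absorbs
  broadband content no mode claims. `reconstruct` (modes + residual) is
  exact by construction; with τ > 0 the dual variable drives the *mode
  sum* itself toward the input.
* **tol = 1e-7, max_iter = 500**; per-window decomposition inside the
  pipeline uses tol = 1e-6, max_iter = 80, which the small 40-sample
  windows reach easily.
* **Initialization**: center frequencies uniformly spaced over [0, 0.5)
  normalized frequency (first mode starts at DC, which lets it claim slow
  envelope content). `octave` and seeded `random` schemes are available.
* **Boundaries**: the signal is mirror-extended by half its length on each
  side before the FFT; the central portion is returned.
* **Degenerate inputs**: a zero signal yields zero modes and the initial
  center frequencies; non-finite samples are rejected.
* Modes are returned sorted by ascending center frequency, so the
  "modified EMG" — the low-frequency oscillation used as the stage-2 input
  and in the consistency analysis — is always `modes[0]`.

Decomposition is applied per fixed window, matching the unit the stage-2
network consumes, rather than per recording.

## Time-domain features

The eight classical per-channel window features (RMS, MAV, WL, ZC, SSC,
DASDV, WA, VAR) follow the printed conventions of this feature family:
VAR is the *uncentered* second moment Σx²/(L−1) (a `centered` option
restores the textbook sample variance), and SSC counts strict local
extrema whose neighbor gaps both reach the threshold T. T defaults to
0.01, appropriate after per-channel z-scoring. The default stage-1
selection is RMS + MAV + DASDV, the force-tracking combination;
features are concatenated channel-major.

## The fine-stage network

The stage-2 classifier is a compact CNN in which every convolution is
depthwise-separable: a k×k per-channel spatial convolution (no bias)
followed by a 1×1 pointwise convolution with biases. Trainable-parameter
counts are therefore k·k·c + c·N + N per layer against k·k·c·N + N for
the standard layer, a ratio of k²cN/(k²c + cN) ignoring biases (→ k² as
N grows). The reference stack on a 30×10 single-channel input —
Conv(32) → Dropout(0.5) → Conv(64) → MaxPool(2×2) → Conv(128) →
ZeroPad(1 column each side of width) → MaxPool(2×2) → Flatten →
Dropout(0.5) → Dense(128) → Softmax(12) — with 'same' convolution padding
yields a 7×3×128 flatten and the layer counts 73 / 2400 / 8896 / 344 192 /
1548 (separable) and 1184-at-depth-4 / 18 496 / 73 856 for the standard
counterfactual. `build_scnn` reports both variants for every layer and the
assembled network allocates exactly the declared arrays. (A frequently
quoted "total parameters drop by about 1/3" does not follow from these
per-layer counts — the dense layer dominates both totals; we keep the
per-layer accounting and note the discrepancy.)

The network is implemented directly in NumPy (`emgflow._nn`): im2col
convolutions, 2×2 max-pooling with argmax routing, inverted dropout,
ReLU, softmax cross-entropy, and Adam (lr 1e-3, batch 256, up to 100
epochs). Early stopping monitors the loss on an internal 10% validation
split with patience 10 and restores the best weights. All randomness
(initialization, dropout, batch order, validation split) flows from one
seed, so training is bit-reproducible. Gradients of every layer are
verified against central finite differences in the test suite.

## Evaluation protocol

Cross-validation shuffles windows with the run seed and splits them into
ten folds, stratified by gesture (stratification is our choice; it
guarantees every class appears in every training set and is why a
class with fewer windows than folds is rejected by name). Each window is
tested exactly once; the report carries the pooled confusion matrix (raw
and row-normalized), per-fold accuracies, and separate stage-1 and
end-to-end accuracies, since routing errors and fine-stage errors are
different failure modes.

The class-consistency analysis computes, per gesture class, the mean over
repetition pairs of the channel-averaged Pearson correlation — once on raw
windows and once on each window's lowest-frequency mode. Inter-repetition
consistency is the one reading of "correlation per class" that yields a
single number per gesture; it quantifies the repeatable content available
to the fine stage.

## The synthetic generator

Real sEMG during contraction is approximated by amplitude-modulated
band-limited Gaussian noise. Each gesture archetype specifies a channel
weight vector (topography), a force scale, and a passband (default
15–45 Hz at fs = 100 Hz). During each active interval the generator adds,
per channel, force·weight·envelope·(carrier + 0.3), where the carrier is
unit-variance band-passed noise regenerated independently per repetition
and the envelope is trapezoidal (10% ramps). The constant 0.3 term makes
the envelope itself a deterministic low-frequency component — the
analogue of the repeatable slow force-related content of real recordings,
and the reason the low-frequency mode is more consistent across
repetitions than the raw signal. Its gain keeps ≥ 80% of active-segment
power inside the passband. Emitted labels are jittered by independent
uniform offsets (default ±200 ms) at every onset and offset, emulating
reaction-time misalignment; `true_intervals` exposes the pre-jitter ground
truth.

The reference benchmark is 3 superclasses × 4 gestures × 40 repetitions
over 10 channels: force scales 1 / 2 / 4 separate the superclasses
(finger < wrist < functional), while gestures within a superclass share
the force level and differ only in which channels they activate — so the
coarse stage must rely on force and the fine stage on topography. Active
and rest segments are 1 s each, giving about two 400 ms windows per
repetition (~960 windows). For tenfold cross-validation on this problem
size the fine stage uses filters (8, 16, 32), 64 dense units and at most
15 epochs — validation accuracy saturates within ~5 epochs here, and the
smaller stack keeps a full tenfold run plus its permuted-label control
around five minutes on one CPU. The full-size reference architecture
(32/64/128, dense 128) remains the default elsewhere.

### What the generator does not emulate

Motor-unit action potentials and recruitment dynamics, electrode lift-off
and powerline/ECG artifacts, inter-subject variability, fatigue drift, and
gesture-dependent spectral shape. Passing benchmarks therefore demonstrate
that the pipeline's machinery — detection, decomposition, routing,
fine classification — works end to end under the statistical structure the
framework exploits (force-separable superclasses, channel topography,
repeatable low-frequency content); they do not certify accuracy on real
recordings such as Ninapro DB1, which must be evaluated with
`read_ninapro_mat` on the actual data.

## Known limitations

* K (the mode count) is fixed, not adapted per signal.
* Relabeling is offline (non-causal smoothing of a full recording).
* The stage-1/stage-2 interface propagates routing errors; there is no
  rejection or re-ranking.
* The NumPy network targets small window images; it is not a general
  deep-learning engine and trains on CPU only.
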