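# Methods

This note documents the models and procedures implemented in `emgknee`,
the parameter choices that matter, what the synthetic data generator does
and does not emulate, and the numerical decisions a maintainer would want
written down.

## Signal model and preprocessing

A recording pairs an sEMG matrix (default 5 kHz) with a knee-flexion
stream (default 100 Hz). Preprocessing applies a Butterworth band-pass
with 10 and 500 Hz cutoffs. We use a zero-phase forward–backward pass of
a 4th-order design: sEMG analysis windows are labelled with the angle at
their **end** time (causal labelling — muscle activity precedes motion),
and any filter phase lag would corrupt that alignment. The two-pass
application squares the magnitude response; the cutoffs quoted are the
design cutoffs.

Windows are 50 ms long with a 20 ms increment (250 samples and 100
samples at 5 kHz), cut from the native-rate signal with no down-sampling.
Windows never straddle trial boundaries. The target for a window is the
linear interpolation of the angle stream at the window's last-sample
time; windows whose end time falls beyond the angle stream are dropped
rather than extrapolated. For network training, targets are affinely
mapped from training-fold extrema to [−1, 1] to match the tanh output
range; held-out targets may leave that interval slightly and are never
clipped when metrics are computed.

## Handcrafted feature bank

The 14 features per window are IEMG, MAV, mean, RMS, sample variance
(ddof 1), Pearson kurtosis m4/m2² (not excess), skewness m3/m2^1.5
(biased central moments), zero crossings, slope-sign changes, waveform
length, and Yule–Walker AR(4) coefficients computed by Levinson–Durbin on
the demeaned window (predictor sign convention, x_t = Σ a_k x_{t−k} + e).
ZC/SSC amplitude thresholds default to 0 and are configurable. Windows
with zero variance return 0 for the moment ratios and AR coefficients so
regressors never see non-finite values; the AR routine additionally flags
such degenerate windows.

A structural property of this bank worth knowing: every one of the 14
features is invariant under time reversal of the window. Any information
carried by within-window temporal asymmetry (e.g. whether the activation
envelope is rising or falling) is invisible to the handcrafted features
but available to the CNN. This is one mechanism by which fused features
can dominate handcrafted ones.

## FG-CNN

Architecture, for a length-250 input: five conv stages with 2, 4, 8, 16,
32 filters of lengths 5, 4, 3, 2, 1; each stage is conv ('same' zero
padding, cross-correlation convention) → batch-norm → LeakyReLU with one
learnable negative slope per layer (initialized at 0.1) → non-overlapping
pairwise max-pool (floor on odd lengths, ties to the earlier sample). The
published layer sizes cannot all be exact simultaneously for any padding
convention; with 'same' padding the lengths run 250 → 125 → 62 → 31 → 15
→ 7, the flattened 7 × 32 = 224 vector feeds FC(192, LeakyReLU) → FC(14)
= the learned features `l`. `input_len` is configurable and the stack
adapts. The fusion output is `ŷ = tanh(w_p·p + w_l·l)`; the handcrafted
vector `p` is z-scored by training-set statistics before entering the
fusion layer (configurable; raw feature scales span orders of magnitude).

Training minimizes batch MSE for 50 epochs at learning rate 1e-3, batch
size 64, with bias-corrected Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8 added
outside the square root) applied to every parameter, the fusion weights
included — their gradients are computed from the closed form rather than
by autodiff, and the tests verify both that the closed form matches
finite differences and that the update trajectory coincides with an
independent Adam transcription to 1e-12. Weights are initialized uniform
fan-in (U(±1/√fan_in)) from a seeded generator; batch-norm uses batch
statistics in training and running statistics (momentum 0.1) at
inference, so training is bit-reproducible per seed and feature
extraction is deterministic.

The unguided baseline shares the conv stack, replaces the feature head by
FC(192) → FC(28), and is trained on the same loss through `ŷ =
tanh(w_l·l)`; its 28 outputs are the "CNN features" of the comparison
study, matching the 28 fused features `[p, l]` in width.

Numerics: training runs in float32 by default (configurable) with the
elementwise-heavy inner loops (convolution, BN–LeakyReLU–pool, Adam)
compiled by numba; the plain-NumPy layer functions retain float64
semantics and serve as the reference implementation in the tests.
Training a full fold (≈26 000 windows × 50 epochs) takes ≈2 minutes on
one CPU core. Because the optimizer is sequential, per-epoch losses are
*not* exactly invariant to batch ordering; on convergent problems the
end-of-training loss is insensitive to it, which is the property tested.

## Downstream regression

Final angle estimates always come from a regressor fitted on the feature
matrix in degrees — the fusion tanh output is only the training signal
for feature learning. Features are z-scored by training statistics inside
the wrapper. Defaults: random forest with 200 trees, max_features = 1/3
(the classic regression-forest heuristic), min_samples_leaf = 2, one
core; LightGBM 500 rounds at learning rate 0.05; MLP one hidden layer of
64; SVR RBF (C = 10, γ = 'scale'); KNN k = 5. All hyperparameters are
overridable through `RegressorSpec` and echoed into the results store.

## Evaluation

NRMSE = RMSE / (y_max − y_min) of the *measured* series, reported in
percent; CC is Pearson's r. Aggregation across folds is plain mean ± SD
(no Fisher transform). Cross-validation defaults to contiguous
trial-level grouping into five folds (trial counts differ by ≤ 1):
overlapping windows from one trial never span the train/test boundary, so
the folds are independent in the sense that matters. A seeded
window-level random scheme exists for leakage ablations. Train/test
disjointness is asserted on every split. Stride averaging resamples each
cycle to a 101-point 0–100 % grid and averages pointwise; cycle starts
come from ground-truth phase for synthetic data or knee-angle minima
(peak detection) for measured data. Method comparisons use the
Kruskal–Wallis rank test (tie-corrected, χ² p-values, α = 0.05).

## Synthetic gait generator

The generator emulates the treadmill protocol the method targets: 11
trials of 60 s at a 0.93 Hz stride rate (≈1.25 m/s walking), six muscle
channels at 5 kHz, angle at 100 Hz. Stride durations get ±3 %
multiplicative jitter; a piecewise-linear phase drives both envelopes and
angle so sEMG and kinematics stay phase-locked. The knee-angle template
is an 8-harmonic Fourier fit to a two-bump flexion curve (stance peak
≈18° at 15 % of the cycle, swing peak ≈60° at 72 %); white measurement
noise of 1.5° SD models IMU-derived angle error. sEMG is band-limited
(10–500 Hz) unit-RMS Gaussian noise amplitude-modulated by the muscle's
envelope, plus sensor noise at 18 dB SNR — representative of good surface
recordings.

Envelopes are sums of wrapped Gaussian bumps placed per classic gait
electromyography (quadriceps in loading response, hamstrings at the
swing–stance transition, gastrocnemius push-off) plus a per-muscle
`coupling` weight blending in the normalized angle profile. The coupling
defaults (LG 0.75, MG 0.70, others ≤ 0.1) make the gastrocnemius channels
the informative ones and make the LG envelope approximately monotone in
the angle, so single-channel estimation is solvable by design. This is a
deliberate idealization: with a purely amplitude-modulated Gaussian
carrier, the handcrafted bank is close to a sufficient statistic of a
window, so the synthetic task mainly exercises the pipeline's
correctness. Passing the end-to-end tests demonstrates that the method
recovers what the generator encodes — not that it would reach the same
accuracy on human recordings, where handcrafted features are further from
sufficiency (non-Gaussian motor-unit structure, electrode artifacts,
inter-stride variability) and learned features have more to add. Motor
units, fatigue and pathological gait are out of scope.

## Reference runs and their sizes

The full protocol (the generator's defaults, LG channel, 50 epochs,
5-fold trial CV, FG-CNN + RF) is the package's headline computation,
≈33 000 windows, ≈12 minutes on one core. The three-way feature-set
comparison runs on a scaled benchmark of 5 trials × 15 s with 10 training
epochs, medians over three seeds: trials, duration and epochs are scaled
*together* because at ≈1/9 of the data the learned features start
memorizing within-trial carrier noise well before 50 epochs — learned
feature quality, not training loss, is what the comparison measures. On
this benchmark the fused features beat both the handcrafted and the CNN
features consistently in the direction reported by studies on measured
data, with small margins, as expected given near-sufficiency of the
handcrafted bank on this signal model.

## Known limitations

* The sEMG carrier is Gaussian; amplitude (plus weak spectral) cues carry
  all angle information, which bounds how much fused features can gain
  over handcrafted ones on synthetic data.
* Batch-norm running statistics make extracted features depend (weakly)
  on training batch composition; extraction itself is deterministic.
* The AR estimator assumes short-window stationarity; windows containing
  sharp envelope transitions violate it mildly.
* Angle targets are interpolated, not filtered; high angle-noise settings
  propagate directly into training targets and metrics.
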