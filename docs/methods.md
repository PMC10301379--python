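# Methods

## Problem and approach

`symaxion` classifies emotional state (3 classes: positive/neutral/negative;
or 5: happy/neutral/sad/angry/fearful) from 62-channel EEG segmented into
1-second epochs at 200 Hz. The premise is that emotional state modulates the
*hemispheric asymmetry* of band-limited EEG power, so the features are built
from the 27 left–right mirror electrode pairs of the extended 10–20 montage.

### Electrode grid

The 62 electrodes are embedded in a 9×9 matrix that preserves scalp
geometry: the frontal-pole row holds 3 electrodes (columns 3–5), the
anterior-frontal row 2 (columns 3 and 5), the F/FC/C/CP/P rows the full 9,
the parieto-occipital row 7 (columns 1–7) and the occipital row 5 (columns
2–6, CB1/O1/OZ/O2/CB2). Midline ("z") electrodes occupy column 4; every
lateral electrode has a mirror partner with the same row and columns summing
to 8. Unoccupied cells are structural zeros. Lateral electrodes are numbered
1…27 over the left hemisphere in reading order with the right partner at
i+27; all internal indices are 0-based, the 1-based convention appears only
in documentation. The layout ships as a CSV table (`data/montage62.csv`) and
can be replaced by any cap that satisfies the same mirror invariants. The
exact identity of each channel cell is a documented package convention
(standard SEED-style 62-channel cap, TP9/TP10 absent as reference
electrodes), not something the feature algebra depends on.

### Features

Two per-epoch descriptions are built on the grid:

* **OEF** — the raw signal, one 9×9 grid per time sample (depth T = 200);
* **DE** — differential entropy per frequency band (δ 1–4, θ 4–8, α 8–12,
  β 12–30, γ 30–50 Hz; depth B = 5). For a Gaussian window,
  h = ½·ln(2πeσ²) nats, with σ² the population variance of the 1-s
  zero-phase band-filtered window (4th-order Butterworth, `sosfiltfilt`).
  Windows are non-overlapping. A variance floor of 1e-12 µV² guards flat
  channels (with a warning); natural log throughout.

From either stack, per depth slice:

* **SSM** (subtract symmetric matrix): d_i = v_i − v_{i+27} for left
  entries, the negative for right entries — antisymmetric under pair swap;
* **QSM** (quotient symmetric matrix): q_i = v_i / v_{i+27} and its
  reciprocal. Denominators with |v| < 1e-6 are clamped to sign(v)·1e-6
  (zero counts as positive), since the raw signal crosses zero constantly.

Midline cells are zero in SSM/QSM maps (at most 54 nonzero cells).
Each depth slice is then min–max normalised to [0, 1] over its supported
cells (constant slices map to 0.5; structural zeros stay 0). Normalisation
is applied to the final symmetric matrices, not to the inputs of the
symmetric transform; the raw/DE stacks themselves are normalised the same
way when used directly.

### Fusion

Each 9×9 slice is upsampled to 64×64 by separable not-a-knot cubic splines
with anchors at 0, 63/8, …, 63 (corners pinned; node values reproduced
exactly; linear ramps exact). Depths are unified to 50 slices by 1-D linear
interpolation between uniformly spaced positions (endpoints preserved;
identity at depth 50). Both resamplings are precomputed linear operators;
they act on different axes and commute, so the pipeline unifies depth on the
small grids before upsampling — this is an exact optimisation, asserted by a
test. The four stacks are concatenated in the fixed order SSM(OEF),
QSM(OEF), SSM(DE), QSM(DE), giving the (200, 64, 64) network input; ablation
subsets concatenate to depth 50·k. Structural zeros are interpolated as
ordinary values — the network sees smooth skirts, not a mask; this is a
known limitation of the spline choice. Throughout, (9, 9) is the size of
the feature maps before interpolation; the network always consumes the
interpolated maps (64×64 by default, configurable for scaled-down runs).

### Classifier

A two-branch convolution/attention network:

* fusion convolution: 1×1 conv + batch norm + ReLU (depth → stem width,
  spatial size unchanged);
* stem: two 3×3 convs (second with stride 2), 64 → 32;
* three stages per branch, each a stride-2 MBConv (expand 1×1 ×4 →
  depthwise 3×3 → squeeze-excitation with reduction 0.25 of the input width
  → project 1×1, batch norm inside, residual only when shape-preserving)
  followed by one pre-norm multi-head self-attention block with residual.
  The local branch partitions the map into non-overlapping P×P windows
  (P = 4); the global branch gathers one element per G×G tile into G²
  dilated groups (G = 4). With a 64×64 input the stages run at 16, 8, 4 —
  the final pre-pooling map is 4×4;
* head: global average pooling of both branches, concatenation, one FC
  layer to the logits.

No relative position bias is used (the depthwise convolution provides
conditional position coding) and the attention blocks carry no MLP/FFN
sub-layer — attention plus MBConv per stage keeps the parameter count small
and was sufficient for separable data. Default widths are (32, 64, 128) with
4 heads per stage; the number of stages follows `stage_channels`, and every
stage's spatial size must divide by P = G (validated at configuration time).
Initialisation: truncated normal (std 0.02, clipped at ±2σ) for attention
and FC weights, fan-out He-normal for convolutions, all drawn from a
seed-controlled generator.

The network and its gradients are implemented in a small reverse-mode
autodiff engine over numpy (`autodiff.py`); every backward rule is checked
against central finite differences in the test suite.

### Training and evaluation

Stratified 7:3 split (seed-reproducible). Cross-entropy loss, SGD with
learning rate 0.01, batch 32, 30 epochs, weight decay 1e-4 applied to
matrix-shaped parameters. "Learning-rate decay 0.01" is read as a
multiplicative per-epoch factor (1 − 0.01)^epoch. SGD carries momentum 0.9
— the conventional meaning of "SGD" in deep-learning practice; plain
gradient descent (momentum 0) is a config switch but descends far more
slowly at this learning rate. Metrics: accuracy, macro recall and macro F1
(classes are balanced by design, so macro averaging is the natural choice),
plus the confusion matrix (rows = true). Divergence (non-finite loss)
raises an error carrying the config. The subject-dependent protocol trains
one model per recording session; repeated-split aggregation is available
through the seed parameter.

Classical baselines (linear SVM, Gaussian naive Bayes, 5-NN) operate on the
flattened fused tensor with the identical split. Deep baselines from other
work are out of scope; the package compares against classical models only.

## Synthetic data

No public recording of the original experiment exists, so the package ships
a generator that emulates exactly the statistical structure the symmetric
matrices are designed to detect. Each epoch is a sum over the five bands of
narrowband-filtered white noise (unit variance per channel, scaled by a
per-band RMS amplitude) plus broadband white noise. Filtering white noise —
rather than summing sinusoids — gives realistic variance estimates and no
degenerate zero-variance windows. Defaults: band amplitudes δ 10, θ 6, α 8,
β 5, γ 3 µV; broadband noise 1 µV; per-channel log-normal gain jitter
(σ = 0.05).

A class's asymmetry ratio r for a band scales left-hemisphere amplitudes by
√r and right by 1/√r (midline: geometric mean, i.e. 1), so the mirror-pair
band-power ratio is r² and the expected DE difference per pair is ln r.
Default 3-class profile: positive α ratio 2 (left excess), neutral
symmetric, negative α ratio 0.5; the 5-class profile adds β ratio 2 / 0.5
for angry/fearful. With ratio 2 the planted α-DE difference is
ln 2 ≈ 0.693 nats, which `effect_audit` recovers within sampling error.

What the generator does *not* emulate: volume conduction, artifacts
(blinks, EMG), non-stationarity, inter-subject variability, or any
correlation structure between mirror channels. Passing the end-to-end tests
therefore shows that the pipeline recovers planted asymmetries — it says
nothing about accuracy on real human EEG, and the original study's accuracy
tables are not reproducible targets here.

## Problem sizes used in tests and the acceptance script

The defaults above define the method; the automated runs use reduced model
widths so the whole suite completes quickly on a single CPU:

* end-to-end recovery: default generator (100 epochs/class, 3 classes,
  ratio-2 α, seed 0), full 64×64 fusion, stage widths (8, 16, 32) with
  2 heads, 30 training epochs — reaches ≥ 90% test accuracy in a few
  minutes. The permuted-label chance control reuses the same configuration
  with 15 training epochs (a chance-level control does not need full
  convergence).
* ablation monotonicity: same dataset, 16×16 fusion, stem width 16, one
  stage of width 8, 30 training epochs, the four singleton feature sets and
  the full fusion over 5 seeds.

## Numerical choices and edge cases

* Population variance (divide by N) in DE; log base e.
* Min–max normalisation per slice; a constant slice maps to 0.5.
* Quotient guard ε = 1e-6 (sign-preserving clamp, zero treated as +ε).
* Batch norm: momentum 0.1, ε 1e-5; layer norm ε 1e-5.
* float32 for network data and weights; the autodiff engine is
  dtype-agnostic and gradient checks run in float64.
* EDF export quantises to 16 bits over the per-channel physical range.

## Known limitations

* Spline interpolation smears structural zeros into neighbouring cells, so
  logits are not invariant to values placed in unoccupied cells.
* The per-slice min–max normalisation discards absolute scale between
  epochs; only within-slice contrast survives.
* The montage assumes a left/right-mirror cap; caps with unpaired lateral
  electrodes are rejected rather than partially paired.
* Training is single-threaded numpy; it is sized for hundreds, not tens of
  thousands, of epochs.
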