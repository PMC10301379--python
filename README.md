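# symaxion

EEG emotion recognition from hemispheric-symmetry feature matrices, with a
multi-axis (window + grid) self-attention classifier — for researchers who
want to study asymmetry-based affective decoding pipelines end to end
without access to private recordings.

## The method

Emotional state modulates the left–right balance of band-limited EEG power.
`symaxion` turns a 62-channel, 200 Hz recording segmented into 1-second
epochs into four spatial feature matrices on a 9×9 electrode grid and
classifies them with a convolution/attention network:

1. **Grid embedding.** The 62 electrodes of the extended 10–20 montage map
   onto a 9×9 matrix (midline electrodes in the central column; 27
   left–right mirror pairs; empty cells are zero).
2. **Features.** Per epoch: the raw signal (one grid per sample, depth
   T = 200) and the per-band differential entropy
   h = ½·ln(2πeσ²), σ² the 1-s band variance, for δ, θ, α, β, γ (depth
   B = 5).
3. **Symmetric matrices.** For each depth slice, the subtract symmetric
   matrix SSM (dᵢ = vᵢ − vᵢ₊₂₇ and its negation) and the quotient symmetric
   matrix QSM (qᵢ = vᵢ / vᵢ₊₂₇ and its reciprocal) over the 27 mirror
   pairs, followed by per-slice min–max normalisation.
4. **Fusion.** Each 9×9 map is cubic-spline upsampled to 64×64, each stack
   linearly resampled to depth 50, and SSM(OEF), QSM(OEF), SSM(DE), QSM(DE)
   are concatenated into the (200, 64, 64) network input.
5. **Classifier.** A 1×1 fusion convolution and a two-conv stem feed two
   parallel branches of stride-2 MBConv + self-attention stages: the local
   branch attends within non-overlapping P×P windows (P = 4), the global
   branch within G² dilated groups that each gather one element per G×G
   tile (G = 4). Branch outputs are pooled, concatenated, and mapped to 3-
   or 5-class logits. Training: SGD (lr 0.01, 1 %/epoch decay, momentum
   0.9, weight decay 1e-4), batch 32, 30 epochs, stratified 7:3 split.

Because no public recording of the original experiment exists, the package
includes a synthetic generator that plants class-dependent hemispheric
band-power asymmetries (amplitude ratio r ⇒ pairwise DE difference ln r),
so the whole pipeline is testable from scratch. See `docs/methods.md` for
assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from symaxion import (SynthConfig, generate, effect_audit, ModelConfig,
                      TrainConfig, run_experiment)

epochs = generate(SynthConfig(n_epochs_per_class=100, seed=0))
audit = effect_audit(epochs)
print(audit.query("`class` == 'positive' and band == 'alpha'")
      [["class", "band", "mean_de_diff"]].to_string(index=False))

report, history = run_experiment(
    epochs,
    ModelConfig(stage_channels=(8, 16, 32), heads=2),  # reduced widths (CPU)
    TrainConfig(epochs=30, seed=0),
)
print(f"test accuracy {report.accuracy:.1f}%  macro F1 {report.macro_f1:.1f}%")
print(report.confusion)
```

Output:

```
   class  band  mean_de_diff
positive alpha      0.674558
test accuracy 94.4%  macro F1 94.5%
[[29  1  0]
 [ 0 30  0]
 [ 0  4 26]]
```

The audit confirms the planted α-band asymmetry (amplitude ratio 2 ⇒
expected DE difference ln 2 ≈ 0.693 nats between mirror electrodes of the
"positive" class), and the trained network recovers the three classes from
the fused symmetric matrices at 94% test accuracy on the held-out 30%.

The same pipeline is available from the shell:

```bash
symaxion simulate --out run/sim --seed 0
symaxion train --data run/sim/epochs --out run/train
symaxion ablate --data run/sim/epochs --out run/ablate
symaxion topomap --data run/sim/epochs --out run/topo
```

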