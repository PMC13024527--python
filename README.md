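# dudem

Dual-branch CNN–capsule lesion detection for gastric capsule endoscopy,
with the surrounding study apparatus: diagnostic metrics, a
perturbation-robustness protocol, an ablation harness, clinical
sample-size calculators, and a seeded synthetic endoscopy-frame generator
so the whole pipeline runs without any clinical data.

## Who this is for

Researchers prototyping lesion-triage models for magnetically controlled
capsule endoscopy (MCCE) screening, and anyone who needs the study-design
arithmetic (sample sizes, sensitivity/specificity/Youden/AUC analytics,
robustness reporting) that accompanies a diagnostic-AI evaluation.

## The model

A convolutional branch (ResNet50 topology) extracts a local-texture map
`F_c`; a capsule branch models pose and part–whole structure: primary
capsules `u_i = squash(z_i)` vote for category capsules via
`û_{j|i} = W_ij u_i`, and routing-by-agreement

```
c_ij = softmax_j(b_ij),  s_j = Σ_i c_ij û_{j|i},  v_j = squash(s_j),
b_ij ← b_ij + û_{j|i}·v_j
```

re-weights each vote by its agreement with the emerging category capsule.
The re-spatialized capsule map `F_v` is fused with `F_c` by a learned
channel-attention gate, `F = α⊙F_c + (1−α)⊙φ(F_v)` with
`α = σ(MLP(GAP([F_c;F_v])))`, and two heads produce class probabilities
and a normalized bounding box, trained with
`L = CE + λ·SmoothL1`.  Seven ablation variants (A0–A6: branch removals,
fusion swaps, pooling swap, shallow head) are constructible from the same
configuration.  Everything runs on a compact NumPy reverse-mode autodiff
core (`dudem.nn`) — no deep-learning framework required.

## Worked example

```python
import numpy as np
from dudem.model import DuDeM, tiny_config
from dudem.synthetic import SyntheticSpec, generate_arrays
from dudem.training import TrainConfig, fit, split_indices, evaluate_model

spec = SyntheticSpec(n_images=800, image_size=32, seed=1)
images, labels, boxes, has_box = generate_arrays(spec)
cfg = TrainConfig(epochs=35, seed=1, stop_at_val_metric=0.95)
tr, va, te = split_indices(len(images), cfg, seed=1)
model = DuDeM(tiny_config(seed=1))
hist = fit(model, images[np.r_[tr, va]], labels[np.r_[tr, va]],
           boxes[np.r_[tr, va]], has_box[np.r_[tr, va]], cfg=cfg)
cm, rep = evaluate_model(model, images[te], labels[te],
                         normalization=hist["normalization"])
print(cm)
print(f"accuracy {100*np.trace(cm)/cm.sum():.1f}%  "
      f"sensitivity {100*rep.sensitivity:.1f}%  "
      f"specificity {100*rep.specificity:.1f}%  AUC {rep.auc:.3f}")
```

Output (under a minute on one CPU):

```
[[100   3   0]
 [ 13  31   0]
 [  0   0  13]]
accuracy 90.0%  sensitivity 77.2%  specificity 97.1%  AUC 0.942
```

The 3×3 matrix counts normal / erosion-like / polyp-like test frames
(rows = truth); the binary metrics collapse the two lesion classes into a
positive set — sensitivity is the fraction of lesion frames flagged,
specificity the fraction of normal frames passed, and AUC the probability
a random lesion frame outscores a random normal frame.  The 64×64 desk
profile (`desk_config()`, 2,000 frames) reaches ≈98% test accuracy in a
few epochs.

More walkthroughs live in `examples/` (sample-size planning, routing
demo, dataset simulation, ablations, robustness reporting), and a CLI
mirrors them: `dudem simulate | train | evaluate | ablate | samplesize`.

## Clinical planning calculators

```
$ dudem samplesize single-arm --pt 0.95 --p0 0.85 --dropout 0.2
per-group n = 78; dropout-adjusted = 98; total (1:1 groups) = 196
$ dudem samplesize diagnostic --p 0.95 --delta 0.05 --dropout 0.2
per-group n = 73; dropout-adjusted = 91; total (positives + negatives) = 182
```

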