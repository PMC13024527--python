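"""Train the dual-branch model on synthetic frames and evaluate it.

Uses the tiny 32x32 profile so the run finishes in about half a minute on a
laptop CPU; the desk 64x64 profile (see ``dudem.model.desk_config``) gives
stronger results at a few minutes' cost.
"""

import numpy as np

from dudem.model import DuDeM, tiny_config
from dudem.synthetic import SyntheticSpec, generate_arrays
from dudem.training import TrainConfig, fit, split_indices, evaluate_model

spec = SyntheticSpec(n_images=800, image_size=32, seed=1)
images, labels, boxes, has_box = generate_arrays(spec)

cfg = TrainConfig(epochs=35, seed=1, stop_at_val_metric=0.95)
tr, va, te = split_indices(len(images), cfg, seed=1)
trv = np.concatenate([tr, va])

model = DuDeM(tiny_config(seed=1))
print(f"model parameters: {model.num_parameters():,}")
hist = fit(model, images[trv], labels[trv], boxes[trv], has_box[trv], cfg=cfg)
print(f"trained {len(hist['epoch'])} epochs; best validation accuracy "
      f"{hist['best_val_metric']:.3f}")

cm, rep = evaluate_model(model, images[te], labels[te],
                         normalization=hist["normalization"])
print("\ntest confusion matrix (rows = truth: normal, erosion, polyp):")
print(cm)
print(f"test accuracy {100 * np.trace(cm) / cm.sum():.1f}%")
print(f"lesion-vs-normal: sensitivity {100*rep.sensitivity:.1f}%, "
      f"specificity {100*rep.specificity:.1f}%, AUC {rep.auc:.3f}")
print("\nSensitivity counts detected lesion frames; specificity counts "
      "correctly passed normal frames.")
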