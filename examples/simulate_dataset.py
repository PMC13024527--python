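"""Generate a seeded synthetic capsule-endoscopy dataset and inspect it.

Writes PNG frames plus CSV/JSON manifests; the class mix defaults to
56% normal, 33% erosion-like and 11% polyp-like with ground-truth boxes
for every lesion frame.
"""

import numpy as np

from dudem.synthetic import SyntheticSpec, generate_dataset

spec = SyntheticSpec(n_images=200, image_size=64, seed=42)
manifest = generate_dataset(spec, "scratch_dataset")
counts = manifest["label"].value_counts()
print("class counts:")
print(counts.to_string())
lesions = manifest[manifest["label"] != "normal"]
print(f"\n{len(lesions)} lesion frames, all with normalized (cx, cy, w, h) boxes;")
print(f"mean box area: {(lesions['w'] * lesions['h']).mean():.4f} of the frame")
print("\nRe-running this script reproduces every PNG byte-for-byte: the")
print("generator derives each frame's RNG from (seed, image index).")
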