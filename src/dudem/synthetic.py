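"""Seeded generator of endoscopy-like frames with ground-truth labels/boxes.

Real gastric capsule-endoscopy data is private, so every stage of the
pipeline is exercised on synthetic frames that emulate its coarse statistics:
3-channel reddish mucosa with low-frequency texture and a vignette, a class
mix of 56% normal frames and 44% lesion frames with lesions split 75/25
between erosion-like (irregular darker patch with texture discontinuity) and
polyp-like (shaded bright ellipse with a specular highlight), ground-truth
normalized (cx, cy, w, h) boxes for lesions, and pose/brightness/contrast
variability.  The renderer is purely procedural — no photorealism is
attempted; what the classes guarantee is *learnability* (a trivial intensity
threshold already separates polyps from normal frames) so that training smoke
tests are meaningful.

Everything is driven by ``numpy``'s Philox-free default PCG64 generator
seeded per image from ``SeedSequence(seed, index)``, which makes regeneration
byte-identical for a given spec.

Perturbation operators mirror a clinical robustness protocol: multiplicative
brightness change, contrast scaling about the per-image mean, and random
basic geometric transforms (flips, small rotations) with boxes updated
coherently.  Default magnitude for brightness/contrast is +/-20%.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "CLASS_NAMES", "SyntheticSpec", "Pose", "LabeledImage",
    "render_image", "perturb", "geometric_transform",
    "generate_arrays", "generate_dataset", "load_manifest",
]

CLASS_NAMES = ("normal", "erosion_like", "polyp_like")
DEFAULT_CLASS_PROBS = (0.56, 0.33, 0.11)   # 56% normal; lesions 75/25


@dataclass
class Pose:
    rotation_deg: float = 0.0
    tx: float = 0.0          # translation as fraction of image size
    ty: float = 0.0
    scale: float = 1.0


@dataclass
class SyntheticSpec:
    n_images: int = 1000
    image_size: int = 64
    class_probs: tuple = DEFAULT_CLASS_PROBS
    rotation_range: float = 180.0     # lesion pose jitter
    translation_range: float = 0.15
    scale_range: tuple = (0.8, 1.25)
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.class_probs, dtype=float)
        if len(p) != 3 or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError("class_probs must be 3 non-negative values summing to 1")


@dataclass
class LabeledImage:
    pixels: np.ndarray            # 3 x H x W float32 in [0, 1]
    label: int
    bbox: tuple | None            # normalized (cx, cy, w, h); None for normal
    seed: int = 0
    index: int = 0


# -- rendering ----------------------------------------------------------------

def _low_freq_noise(rng, size, cells=6, amp=1.0):
    grid = rng.normal(0.0, 1.0, size=(cells, cells))
    xs = np.linspace(0, cells - 1, size)
    gi = np.clip(xs.astype(int), 0, cells - 2)
    fr = xs - gi
    row = grid[gi][:, gi] * (1 - fr)[:, None] * (1 - fr)[None, :] \
        + grid[gi + 1][:, gi] * fr[:, None] * (1 - fr)[None, :] \
        + grid[gi][:, gi + 1] * (1 - fr)[:, None] * fr[None, :] \
        + grid[gi + 1][:, gi + 1] * fr[:, None] * fr[None, :]
    return amp * row


def _mucosa_base(rng, size):
    """Smooth reddish background with vignette."""
    base = np.array([0.72, 0.38, 0.30])        # R, G, B
    tex = _low_freq_noise(rng, size, cells=6, amp=0.06)
    tex2 = _low_freq_noise(rng, size, cells=12, amp=0.02)
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1)
    r2 = (yy - 0.5) ** 2 + (xx - 0.5) ** 2
    vignette = 1.0 - 0.55 * np.clip(r2 / 0.5, 0, 1)
    img = np.empty((3, size, size))
    for c in range(3):
        img[c] = np.clip((base[c] + tex + tex2) * vignette, 0.0, 1.0)
    return img


def _lesion_geometry(rng, pose: Pose, base_radius: float):
    """Lesion center/size under the pose transform, normalized coordinates."""
    r0 = 0.16 * rng.uniform(0.8, 1.2)          # offset of lesion from center
    theta = np.deg2rad(pose.rotation_deg)
    cx = 0.5 + r0 * np.cos(theta) + pose.tx
    cy = 0.5 + r0 * np.sin(theta) + pose.ty
    a = base_radius * pose.scale * rng.uniform(0.85, 1.15)
    b = a * rng.uniform(0.6, 1.0)
    tilt = rng.uniform(0, np.pi)
    # keep the lesion fully inside the frame
    ext_x = abs(a * np.cos(tilt)) + abs(b * np.sin(tilt))
    ext_y = abs(a * np.sin(tilt)) + abs(b * np.cos(tilt))
    cx = float(np.clip(cx, ext_x + 0.02, 0.98 - ext_x))
    cy = float(np.clip(cy, ext_y + 0.02, 0.98 - ext_y))
    return cx, cy, a, b, tilt, ext_x, ext_y


def _ellipse_mask(size, cx, cy, a, b, tilt, wobble=None):
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1)
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(tilt) + dy * np.sin(tilt)
    v = -dx * np.sin(tilt) + dy * np.cos(tilt)
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    if wobble is not None:
        phi = np.arctan2(v, u)
        mod = 1.0 + sum(amp * np.cos(k * phi + ph) for k, amp, ph in wobble)
        r = r / np.maximum(mod, 0.5)
    return r


def render_image(label, pose: Pose | None = None, rng=None,
                 size: int = 64, seed: int = 0, index: int = 0) -> LabeledImage:
    """Render one frame of the given class under a pose transform."""
    if isinstance(label, str):
        label = CLASS_NAMES.index(label)
    if label not in (0, 1, 2):
        raise ValueError(f"unknown class id {label}")
    rng = rng or np.random.default_rng(seed)
    pose = pose or Pose()
    img = _mucosa_base(rng, size)
    bbox = None

    if label == 1:      # erosion-like: irregular darker patch
        cx, cy, a, b, tilt, ex, ey = _lesion_geometry(rng, pose, base_radius=0.14)
        wobble = [(k, rng.uniform(0.05, 0.18), rng.uniform(0, 2 * np.pi))
                  for k in (3, 5, 7)]
        r = _ellipse_mask(size, cx, cy, a, b, tilt, wobble=wobble)
        inside = np.clip(1.0 - r, 0, 1) ** 0.7
        rough = _low_freq_noise(rng, size, cells=max(8, size // 4), amp=0.10)
        dark = 0.45 + 0.15 * rng.uniform()
        for c, chan_gain in enumerate((dark, dark * 0.9, dark * 0.95)):
            img[c] = img[c] * (1 - inside) + np.clip(img[c] * chan_gain + rough, 0, 1) * inside
        bbox = (cx, cy, 2 * ex * 1.15, 2 * ey * 1.15)
    elif label == 2:    # polyp-like: bright shaded ellipse with highlight
        cx, cy, a, b, tilt, ex, ey = _lesion_geometry(rng, pose, base_radius=0.13)
        r = _ellipse_mask(size, cx, cy, a, b, tilt)
        inside = np.clip(1.0 - r, 0, 1) ** 0.5
        shade = np.clip(1.0 - 0.5 * r, 0.3, 1.0)
        bright = np.array([0.98, 0.80, 0.66]) * rng.uniform(0.95, 1.05)
        hl = _ellipse_mask(size, cx - 0.25 * a, cy - 0.25 * b, 0.3 * a, 0.3 * b, tilt)
        highlight = np.clip(1.0 - hl, 0, 1) ** 2
        for c in range(3):
            lesion = np.clip(bright[c] * shade + 0.5 * highlight, 0, 1)
            img[c] = img[c] * (1 - inside) + lesion * inside
        bbox = (cx, cy, 2 * ex * 1.1, 2 * ey * 1.1)

    if bbox is not None:
        cx, cy, w, h = bbox
        w = min(w, 2 * min(cx, 1 - cx))
        h = min(h, 2 * min(cy, 1 - cy))
        bbox = (float(cx), float(cy), float(w), float(h))
    return LabeledImage(img.astype(np.float32), int(label), bbox,
                        seed=seed, index=index)


# -- perturbation operators ---------------------------------------------------

def geometric_transform(image: LabeledImage, hflip: bool = False,
                        vflip: bool = False, angle_deg: float = 0.0) -> LabeledImage:
    """Flip/rotate pixels and transform the box coherently."""
    px = image.pixels.copy()
    bbox = image.bbox
    if hflip:
        px = px[:, :, ::-1].copy()
        if bbox:
            bbox = (1.0 - bbox[0], bbox[1], bbox[2], bbox[3])
    if vflip:
        px = px[:, ::-1, :].copy()
        if bbox:
            bbox = (bbox[0], 1.0 - bbox[1], bbox[2], bbox[3])
    if angle_deg:
        from scipy.ndimage import rotate as nd_rotate
        px = np.stack([nd_rotate(px[c], angle_deg, reshape=False, order=1,
                                 mode="nearest") for c in range(3)])
        px = np.clip(px, 0, 1).astype(np.float32)
        if bbox:
            th = np.deg2rad(angle_deg)
            # scipy rotates image content counterclockwise in array coords;
            # rotate the box center about the image center accordingly
            dx, dy = bbox[0] - 0.5, bbox[1] - 0.5
            cx = 0.5 + dx * np.cos(th) + dy * np.sin(th)
            cy = 0.5 - dx * np.sin(th) + dy * np.cos(th)
            w = abs(bbox[2] * np.cos(th)) + abs(bbox[3] * np.sin(th))
            h = abs(bbox[2] * np.sin(th)) + abs(bbox[3] * np.cos(th))
            cx, cy = float(np.clip(cx, 0, 1)), float(np.clip(cy, 0, 1))
            w = float(min(w, 2 * min(cx, 1 - cx)))
            h = float(min(h, 2 * min(cy, 1 - cy)))
            bbox = (cx, cy, w, h)
    return LabeledImage(px, image.label, bbox, image.seed, image.index)


def perturb(image: LabeledImage, kind: str, magnitude: float = 0.2,
            rng=None) -> LabeledImage:
    """Apply one robustness-protocol perturbation.

    ``brightness``/``contrast`` treat ``magnitude`` as the multiplicative
    factor when >= 0.5 (1.0 = identity), otherwise as a +/- range sampled via
    ``rng``.  ``random_transform`` picks a flip and a small rotation from
    ``rng`` (up to ``magnitude * 90`` degrees).
    """
    if kind == "brightness":
        factor = magnitude if rng is None else 1.0 + rng.uniform(-magnitude, magnitude)
        px = np.clip(image.pixels * factor, 0, 1).astype(np.float32)
        return LabeledImage(px, image.label, image.bbox, image.seed, image.index)
    if kind == "contrast":
        factor = magnitude if rng is None else 1.0 + rng.uniform(-magnitude, magnitude)
        mean = image.pixels.mean()
        px = np.clip(mean + (image.pixels - mean) * factor, 0, 1).astype(np.float32)
        return LabeledImage(px, image.label, image.bbox, image.seed, image.index)
    if kind == "random_transform":
        rng = rng or np.random.default_rng(0)
        hflip = bool(rng.integers(0, 2))
        vflip = bool(rng.integers(0, 2))
        angle = float(rng.uniform(-magnitude * 90, magnitude * 90))
        return geometric_transform(image, hflip=hflip, vflip=vflip, angle_deg=angle)
    raise ValueError(f"unknown perturbation kind {kind!r}")


# -- dataset generation -------------------------------------------------------

def _sample_pose(rng, spec: SyntheticSpec) -> Pose:
    return Pose(rotation_deg=float(rng.uniform(-spec.rotation_range,
                                               spec.rotation_range)),
                tx=float(rng.uniform(-spec.translation_range, spec.translation_range)),
                ty=float(rng.uniform(-spec.translation_range, spec.translation_range)),
                scale=float(rng.uniform(*spec.scale_range)))


def generate_arrays(spec: SyntheticSpec):
    """Generate the dataset in memory.

    Returns ``(images, labels, boxes, has_box)`` with images (n, 3, H, W)
    float32, labels (n,), boxes (n, 4) (zeros where absent), has_box (n,) bool.
    """
    n = spec.n_images
    images = np.zeros((n, 3, spec.image_size, spec.image_size), dtype=np.float32)
    labels = np.zeros(n, dtype=np.int64)
    boxes = np.zeros((n, 4), dtype=np.float32)
    has_box = np.zeros(n, dtype=bool)
    label_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC1A55]))
    drawn = label_rng.choice(3, size=n, p=np.asarray(spec.class_probs))
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i]))
        pose = _sample_pose(rng, spec)
        img = render_image(int(drawn[i]), pose, rng, size=spec.image_size,
                           seed=spec.seed, index=i)
        images[i] = img.pixels
        labels[i] = img.label
        if img.bbox is not None:
            boxes[i] = img.bbox
            has_box[i] = True
    return images, labels, boxes, has_box


def generate_dataset(spec: SyntheticSpec, out_dir) -> pd.DataFrame:
    """Write PNG images plus CSV and JSON manifests; returns the manifest.

    Regeneration with the same spec is byte-identical.
    """
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    images, labels, boxes, has_box = generate_arrays(spec)
    rows = []
    for i in range(spec.n_images):
        arr = (np.clip(images[i], 0, 1) * 255).round().astype(np.uint8)
        path = img_dir / f"img_{i:05d}.png"
        Image.fromarray(arr.transpose(1, 2, 0)).save(path, format="PNG")
        row = {"path": str(path.relative_to(out)), "label": CLASS_NAMES[labels[i]],
               "cx": boxes[i, 0] if has_box[i] else np.nan,
               "cy": boxes[i, 1] if has_box[i] else np.nan,
               "w": boxes[i, 2] if has_box[i] else np.nan,
               "h": boxes[i, 3] if has_box[i] else np.nan,
               "seed": spec.seed}
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    (out / "manifest.json").write_text(
        json.dumps(manifest.replace({np.nan: None}).to_dict(orient="records"),
                   indent=1))
    return manifest


def load_manifest(manifest_path):
    """Load a generated dataset back into arrays (images, labels, boxes, has_box)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path)
    n = len(df)
    first = np.asarray(Image.open(root / df.iloc[0]["path"]), dtype=np.float32)
    size = first.shape[0]
    images = np.zeros((n, 3, size, size), dtype=np.float32)
    labels = np.zeros(n, dtype=np.int64)
    boxes = np.zeros((n, 4), dtype=np.float32)
    has_box = np.zeros(n, dtype=bool)
    for i, row in df.iterrows():
        arr = np.asarray(Image.open(root / row["path"]), dtype=np.float32) / 255.0
        images[i] = arr.transpose(2, 0, 1)
        labels[i] = CLASS_NAMES.index(row["label"])
        if not pd.isna(row["cx"]):
            boxes[i] = (row["cx"], row["cy"], row["w"], row["h"])
            has_box[i] = True
    return images, labels, boxes, has_box


def dataset_digest(spec: SyntheticSpec) -> str:
    """SHA-256 of the generated pixel stream (regeneration check)."""
    images, labels, boxes, has_box = generate_arrays(spec)
    h = hashlib.sha256()
    h.update((np.clip(images, 0, 1) * 255).round().astype(np.uint8).tobytes())
    h.update(labels.tobytes())
    return h.hexdigest()
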