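"""Synthetic generator: determinism, class statistics, label-pixel coherence,
perturbation operators."""

import numpy as np
import pytest

from dudem.synthetic import (SyntheticSpec, Pose, CLASS_NAMES, render_image,
                             perturb, geometric_transform, generate_arrays,
                             generate_dataset, load_manifest, dataset_digest)


def test_regeneration_is_byte_identical():
    spec = SyntheticSpec(n_images=40, image_size=32, seed=7)
    assert dataset_digest(spec) == dataset_digest(spec)


def test_different_seeds_differ():
    a = dataset_digest(SyntheticSpec(n_images=20, image_size=32, seed=1))
    b = dataset_digest(SyntheticSpec(n_images=20, image_size=32, seed=2))
    assert a != b


def test_class_mix_matches_multinomial_expectation():
    n = 1000
    spec = SyntheticSpec(n_images=n, image_size=32, seed=11)
    _, labels, _, _ = generate_arrays(spec)
    counts = np.bincount(labels, minlength=3)
    for k, p in enumerate(spec.class_probs):
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(counts[k] - n * p) < 3 * sigma


def test_lesions_have_boxes_normals_do_not():
    spec = SyntheticSpec(n_images=120, image_size=32, seed=3)
    _, labels, boxes, has_box = generate_arrays(spec)
    assert (has_box == (labels != 0)).all()
    for i in np.nonzero(has_box)[0]:
        cx, cy, w, h = boxes[i]
        assert 0 <= cx - w / 2 and cx + w / 2 <= 1
        assert 0 <= cy - h / 2 and cy + h / 2 <= 1
        assert w > 0 and h > 0


def test_polyp_mean_intensity_higher_inside_box():
    wins = 0
    for seed in range(40):
        img = render_image("polyp_like", Pose(), np.random.default_rng(seed), size=48)
        cx, cy, w, h = img.bbox
        s = 48
        y0, y1 = int((cy - h / 2) * s), int(np.ceil((cy + h / 2) * s))
        x0, x1 = int((cx - w / 2) * s), int(np.ceil((cx + w / 2) * s))
        mask = np.zeros((s, s), dtype=bool)
        mask[y0:y1, x0:x1] = True
        wins += img.pixels[:, mask].mean() > img.pixels[:, ~mask].mean()
    assert wins >= 38


def test_same_inputs_render_identical_pixels():
    a = render_image(2, Pose(30, 0.05, -0.02, 1.1), np.random.default_rng(5))
    b = render_image(2, Pose(30, 0.05, -0.02, 1.1), np.random.default_rng(5))
    assert np.array_equal(a.pixels, b.pixels)
    assert a.bbox == b.bbox


def test_pose_rotation_moves_lesion_center():
    # rotating the pose by 90 degrees rotates the lesion offset about the
    # image center
    a = render_image(2, Pose(0), np.random.default_rng(8))
    b = render_image(2, Pose(90), np.random.default_rng(8))
    va = np.array(a.bbox[:2]) - 0.5
    vb = np.array(b.bbox[:2]) - 0.5
    rotated = np.array([-va[1], va[0]])
    assert np.allclose(vb, rotated, atol=0.05)


def test_unknown_class_and_kind_raise():
    with pytest.raises(ValueError):
        render_image(5)
    img = render_image(0, rng=np.random.default_rng(0))
    with pytest.raises(ValueError):
        perturb(img, "blur")


def test_brightness_and_contrast_identity_at_unit_magnitude():
    img = render_image(2, rng=np.random.default_rng(1))
    assert np.array_equal(perturb(img, "brightness", 1.0).pixels, img.pixels)
    assert np.allclose(perturb(img, "contrast", 1.0).pixels, img.pixels, atol=1e-6)


def test_horizontal_flip_is_an_involution():
    img = render_image(1, Pose(45), np.random.default_rng(2))
    twice = geometric_transform(geometric_transform(img, hflip=True), hflip=True)
    assert np.array_equal(twice.pixels, img.pixels)
    assert np.allclose(twice.bbox, img.bbox, atol=1e-12)


def test_flip_mirrors_box_center():
    img = render_image(2, Pose(30), np.random.default_rng(4))
    flipped = geometric_transform(img, hflip=True)
    assert np.isclose(flipped.bbox[0], 1.0 - img.bbox[0], atol=1e-12)
    assert flipped.bbox[1:] == img.bbox[1:]


def test_boxes_stay_inside_image_after_perturbations():
    rng = np.random.default_rng(6)
    for seed in range(20):
        img = render_image(1 + seed % 2, Pose(float(seed * 31)),
                           np.random.default_rng(seed))
        for kind in ("brightness", "contrast", "random_transform"):
            out = perturb(img, kind, magnitude=0.2, rng=rng)
            if out.bbox is not None:
                cx, cy, w, h = out.bbox
                assert -1e-9 <= cx - w / 2 and cx + w / 2 <= 1 + 1e-9
                assert -1e-9 <= cy - h / 2 and cy + h / 2 <= 1 + 1e-9


def test_intensity_threshold_separates_polyps_from_normals():
    # label-pixel consistency: the classes must be learnable even for a
    # trivial detector
    spec = SyntheticSpec(n_images=400, image_size=64, seed=7)
    imgs, labels, _, _ = generate_arrays(spec)
    sel = labels != 1
    feat = np.array([np.percentile(im, 99) for im in imgs[sel]])
    is_polyp = labels[sel] == 2
    best = max(((feat > t) == is_polyp).mean()
               for t in np.linspace(0.3, 1.0, 71))
    assert best > 0.8


def test_dataset_roundtrip_through_png_manifest(tmp_path):
    spec = SyntheticSpec(n_images=12, image_size=32, seed=13)
    manifest = generate_dataset(spec, tmp_path)
    assert len(manifest) == 12
    assert set(manifest.columns) == {"path", "label", "cx", "cy", "w", "h", "seed"}
    assert (tmp_path / "manifest.json").exists()
    images, labels, boxes, has_box = load_manifest(tmp_path / "manifest.csv")
    ref_images, ref_labels, ref_boxes, ref_hb = generate_arrays(spec)
    assert np.array_equal(labels, ref_labels)
    assert np.array_equal(has_box, ref_hb)
    # PNG quantizes to 8 bits
    assert np.abs(images - ref_images).max() <= 1.0 / 255 + 1e-6
    lesions = manifest[manifest["label"] != "normal"]
    assert lesions[["cx", "cy", "w", "h"]].notna().all().all()
    normals = manifest[manifest["label"] == "normal"]
    assert normals[["cx", "cy", "w", "h"]].isna().all().all()
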