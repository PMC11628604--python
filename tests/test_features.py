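"""Filter-bank and pixel-classifier contracts."""

import numpy as np
import pytest

import gliaquant as gq
from gliaquant.features import (plaque_bank, microglia_bank,
                                FOREGROUND_LABEL, BACKGROUND_LABEL)
from gliaquant.core import ConfigurationError

from conftest import SMALL_FOV_UM


def test_plane_counts():
    assert plaque_bank().n_features == 25     # 6 planes/sigma x 4 + identity
    assert microglia_bank().n_features == 49  # 8 planes/sigma x 6 + identity
    rng = np.random.default_rng(0)
    img = rng.random((64, 64))
    assert gq.compute_feature_stack(img, plaque_bank()).shape == (25, 64, 64)


def test_constant_image_zero_derivative_planes():
    cfg = gq.FeatureBankConfig(sigmas=(1, 2), filters=("dog",
                                                       "gradient_magnitude",
                                                       "log"))
    stack = gq.compute_feature_stack(np.full((32, 32), 7.0), cfg)
    # truncated discrete kernels leave a ~1e-4 relative residual
    assert np.allclose(stack[1:], 0.0, atol=0.01)


def test_sigma_order_enforced():
    with pytest.raises(ConfigurationError):
        gq.FeatureBankConfig(sigmas=(2, 2, 4))
    with pytest.raises(ConfigurationError):
        gq.FeatureBankConfig(filters=("gaussian", "median"))


def test_translation_equivariance_interior():
    rng = np.random.default_rng(1)
    img = rng.random((96, 96))
    cfg = gq.FeatureBankConfig(sigmas=(1, 2), filters=("gaussian", "dog",
                                                       "gradient_magnitude",
                                                       "log", "hessian_eig"))
    dy, dx = 5, 3
    shifted = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
    a = gq.compute_feature_stack(img, cfg)
    b = gq.compute_feature_stack(shifted, cfg)
    # widest kernel is the DoG's 1.6*sigma arm, truncated at 4 SD
    margin = int(np.ceil(4 * 1.6 * max(cfg.sigmas))) + max(dy, dx) + 1
    inner = slice(margin, 96 - margin)
    rolled = np.roll(np.roll(a, dy, axis=1), dx, axis=2)
    assert np.allclose(b[:, inner, inner], rolled[:, inner, inner], atol=1e-8)


def _two_intensity_image():
    img = np.full((40, 40), 10.0)
    img[10:30, 10:30] = 100.0
    # sparse labels on a stride grid, both classes spread across the frame
    gt = img > 50
    labels = np.zeros((40, 40), int)
    labels[2::5, 2::5] = np.where(gt[2::5, 2::5], FOREGROUND_LABEL,
                                  BACKGROUND_LABEL)
    return img, labels


def test_separable_labels_perfect_training_accuracy():
    img, labels = _two_intensity_image()
    cfg = gq.FeatureBankConfig(sigmas=(1, 2))
    stack = gq.compute_feature_stack(img, cfg)
    model = gq.train_classifier(stack, labels, config=cfg, seed=0)
    sel = labels > 0
    pred = model.model.predict(stack[:, sel].T)
    assert (pred == labels[sel]).all()
    mask = gq.predict_mask(model, img, cfg)
    assert mask.mask.shape == img.shape
    assert mask.mask[20, 20] and not mask.mask[1, 1]


def test_single_class_labels_rejected():
    img, labels = _two_intensity_image()
    labels[labels == BACKGROUND_LABEL] = 0
    cfg = gq.FeatureBankConfig(sigmas=(1,))
    stack = gq.compute_feature_stack(img, cfg)
    with pytest.raises(ValueError):
        gq.train_classifier(stack, labels, config=cfg)


def test_feature_count_mismatch_error():
    img, labels = _two_intensity_image()
    cfg = gq.FeatureBankConfig(sigmas=(1, 2))
    stack = gq.compute_feature_stack(img, cfg)
    model = gq.train_classifier(stack, labels, config=cfg)
    with pytest.raises(ValueError, match="[Ff]eature"):
        gq.predict_mask(model, img, gq.FeatureBankConfig(sigmas=(1, 2, 4)))


def _sparse_labels(gt_mask, rng, n_per_class=200):
    labels = np.zeros(gt_mask.shape, int)
    fg = np.argwhere(gt_mask)
    bg = np.argwhere(~gt_mask)
    for cls, pool in ((FOREGROUND_LABEL, fg), (BACKGROUND_LABEL, bg)):
        idx = rng.choice(len(pool), size=n_per_class, replace=False)
        labels[pool[idx, 0], pool[idx, 1]] = cls
    return labels


def test_classifier_recovers_plaques(small_plaque_spec):
    """Trained on 200 sparse px/class of a synthetic plaque FOV: held-out
    pixel accuracy >= 0.95 and mask IoU >= 0.8 against ground truth."""
    fov, gt = gq.generate_fov(small_plaque_spec, 21, fov_size_um=SMALL_FOV_UM)
    chan = fov.channel("plaque")
    gt_mask = gt.plaque_labels > 0
    rng = np.random.default_rng(0)
    labels = _sparse_labels(gt_mask, rng)
    cfg = plaque_bank()
    stack = gq.compute_feature_stack(chan, cfg)
    model = gq.train_classifier(stack, labels, config=cfg, seed=0)
    mask = gq.predict_mask(model, chan, cfg)
    held_out = labels == 0
    acc = (mask.mask[held_out] == gt_mask[held_out]).mean()
    assert acc >= 0.95
    iou = (mask.mask & gt_mask).sum() / (mask.mask | gt_mask).sum()
    assert iou >= 0.8
    # determinism: same labels + same seed -> identical predictions
    model2 = gq.train_classifier(stack, labels, config=cfg, seed=0)
    mask2 = gq.predict_mask(model2, chan, cfg)
    assert np.array_equal(mask.mask, mask2.mask)


def test_accuracy_degrades_monotonically_with_noise(small_plaque_spec):
    """Mean held-out accuracy (10 seeds) is non-increasing in the SD of
    additive noise stacked on the channel."""
    fov, gt = gq.generate_fov(small_plaque_spec, 31, fov_size_um=SMALL_FOV_UM)
    chan = fov.channel("plaque")
    gt_mask = gt.plaque_labels > 0
    cfg = gq.FeatureBankConfig(sigmas=(1, 2, 4))
    accs = []
    for sd in (0.0, 400.0, 2000.0):
        vals = []
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            noisy = chan + rng.normal(0, sd, chan.shape)
            labels = _sparse_labels(gt_mask, rng, n_per_class=100)
            stack = gq.compute_feature_stack(noisy, cfg)
            model = gq.train_classifier(stack, labels, config=cfg, seed=s)
            pred = gq.predict_mask(model, noisy, cfg).mask
            held = labels == 0
            vals.append((pred[held] == gt_mask[held]).mean())
        accs.append(np.mean(vals))
    assert accs[0] >= accs[1] >= accs[2]


def test_threshold_plaques_variants():
    # bimodal channel: bright disks over dim background plus mild noise
    rng = np.random.default_rng(12)
    chan = np.full((128, 128), 10.0)
    gt_mask = np.zeros((128, 128), bool)
    yy, xx = np.mgrid[0:128, 0:128]
    for cy, cx, r in ((30, 30, 12), (90, 50, 16), (50, 100, 9)):
        gt_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    chan[gt_mask] = 150.0
    chan = chan + rng.normal(0, 3.0, chan.shape)
    mask = gq.threshold_plaques(chan)  # otsu default
    iou = (mask.mask & gt_mask).sum() / (mask.mask | gt_mask).sum()
    assert iou >= 0.9
    assert not gq.threshold_plaques(chan, chan.max() + 1).mask.any()
    assert gq.threshold_plaques(np.abs(chan), 0.0).mask.all()
    with pytest.warns(UserWarning):
        empty = gq.threshold_plaques(np.full((8, 8), 3.0), "otsu")
    assert not empty.mask.any()
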