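"""Otsu thresholding, binarization, watershed separation, particle measurement."""

from __future__ import annotations

import numpy as np
import pytest
from skimage import draw

from neuritequant import (
    ImageField,
    binarize,
    label_components,
    measure_particles,
    otsu_threshold,
    watershed_split,
)
from neuritequant.segment import class_separation

from helpers import otsu_bruteforce


def _field(pixels, pixel_size=0.65, bit_depth=16):
    return ImageField(np.asarray(pixels), pixel_size=pixel_size, bit_depth=bit_depth)


# ---------------------------------------------------------------------------
# otsu_threshold


def test_otsu_bimodal_two_values():
    px = np.concatenate([np.full(2048, 10.0), np.full(2048, 200.0)]).reshape(64, 64)
    t = otsu_threshold(_field(px))
    assert 10.0 < t < 200.0
    assert np.array_equal(binarize(px, t), px == 200.0)


@pytest.mark.parametrize("bit_depth,hi", [(8, 255), (16, 65535)])
def test_otsu_matches_exhaustive_search(bit_depth, hi):
    """Equals brute-force maximization of between-class variance."""
    rng = np.random.default_rng(bit_depth)
    for _ in range(10):
        px = rng.integers(0, hi + 1, (64, 64))
        assert otsu_threshold(_field(px, bit_depth=bit_depth)) == otsu_bruteforce(px)


def test_otsu_constant_image_errors():
    with pytest.raises(ValueError, match="no threshold"):
        otsu_threshold(_field(np.full((8, 8), 42.0)))


# ---------------------------------------------------------------------------
# binarize


def test_binarize_is_strict_comparison():
    px = np.array([[0, 5], [10, 15]], dtype=float)
    assert np.array_equal(binarize(px, 5.0), px > 5.0)
    assert not binarize(px, 15.0).any()
    assert binarize(px, -1.0).all()


def test_class_separation_discriminates_signal_from_noise():
    rng = np.random.default_rng(0)
    noise = rng.normal(200, 15, (128, 128)).clip(0)
    t = otsu_threshold(_field(noise))
    assert class_separation(noise, t) < 4.0
    signal = noise.copy()
    signal[40:60, 40:60] = 8000.0
    t = otsu_threshold(_field(signal))
    assert class_separation(signal, t) > 50.0


# ---------------------------------------------------------------------------
# watershed_split


def test_watershed_keeps_convex_objects_single():
    mask = np.zeros((100, 100), bool)
    rr, cc = draw.disk((50, 50), 20)
    mask[rr, cc] = True
    assert watershed_split(mask).max() == 1

    mask = np.zeros((100, 200), bool)
    rr, cc = draw.ellipse(50, 100, 10, 60)
    mask[rr, cc] = True
    assert watershed_split(mask).max() == 1


def test_watershed_splits_two_overlapping_disks():
    """Two equal disks overlapping by less than one radius separate in two."""
    mask = np.zeros((100, 160), bool)
    for cx in (60, 95):  # centers 35 apart, radius 25
        rr, cc = draw.disk((50, cx), 25)
        mask[rr, cc] = True
    labels = watershed_split(mask)
    assert labels.max() == 2
    # split runs along the neck: the two halves are balanced
    sizes = np.bincount(labels.ravel())[1:]
    assert sizes.min() > 0.3 * sizes.sum()


def test_watershed_empty_mask():
    labels = watershed_split(np.zeros((10, 10), bool))
    assert labels.shape == (10, 10) and labels.max() == 0


def test_watershed_label_count_at_least_components(rng):
    mask = rng.random((128, 128)) > 0.8
    from skimage import morphology

    mask = morphology.dilation(mask, morphology.disk(2))
    n_components = label_components(mask).max()
    assert watershed_split(mask).max() >= n_components


def test_watershed_rescues_thin_components():
    """A 1-px-wide line (all distances < 1) still yields one label."""
    mask = np.zeros((30, 30), bool)
    mask[15, 5:25] = True
    assert watershed_split(mask).max() == 1


# ---------------------------------------------------------------------------
# measure_particles


def test_area_filter_is_strictly_greater():
    """Objects of exactly the cutoff area are excluded, larger ones retained."""
    # pixel_size 0.5 → px area 0.25 µm²; blobs of 2, 4, 6 px = 0.5, 1.0, 1.5 µm²
    labels = np.zeros((20, 20), dtype=np.int32)
    labels[1, 1:3] = 1
    labels[5, 1:5] = 2
    labels[10, 1:7] = 3
    img = _field(np.ones((20, 20)), pixel_size=0.5)
    table = measure_particles(labels, img, min_area_um2=1.0)
    assert list(table["label"]) == [3]
    assert table["area_um2"].iloc[0] == pytest.approx(1.5)


def test_ellipse_aspect_ratio_from_moments():
    """A digital 40×10 px ellipse measures AR ≈ 4, a disk AR ≈ 1."""
    mask = np.zeros((120, 120), dtype=np.int32)
    rr, cc = draw.ellipse(60, 60, 10, 40)
    mask[rr, cc] = 1
    img = _field(np.ones((120, 120)), pixel_size=1.0)
    table = measure_particles(mask, img, min_area_um2=1.0)
    assert table["aspect_ratio"].iloc[0] == pytest.approx(4.0, rel=0.05)

    mask = np.zeros((60, 60), dtype=np.int32)
    rr, cc = draw.disk((30, 30), 15)
    mask[rr, cc] = 1
    table = measure_particles(mask, _field(np.ones((60, 60)), pixel_size=1.0))
    assert table["aspect_ratio"].iloc[0] == pytest.approx(1.0, rel=0.05)


@pytest.mark.parametrize("angle_deg", [0, 30, 45, 75])
def test_aspect_ratio_rotation_invariant(angle_deg):
    """AR of a ≥100 px ellipse varies < 5% under rotation."""
    mask = np.zeros((160, 160), dtype=np.int32)
    rr, cc = draw.ellipse(80, 80, 8, 24, rotation=np.deg2rad(angle_deg))
    mask[rr, cc] = 1
    img = _field(np.ones((160, 160)), pixel_size=1.0)
    table = measure_particles(mask, img)
    assert table["aspect_ratio"].iloc[0] == pytest.approx(3.0, rel=0.05)


def test_integrated_intensity_and_centroid():
    labels = np.zeros((12, 12), dtype=np.int32)
    labels[4:7, 4:7] = 1
    px = np.zeros((12, 12))
    px[4:7, 4:7] = 11.0
    table = measure_particles(labels, _field(px, pixel_size=1.0))
    assert table["integrated_intensity"].iloc[0] == pytest.approx(99.0)
    assert table["centroid_x"].iloc[0] == pytest.approx(5.0)
    assert table["centroid_y"].iloc[0] == pytest.approx(5.0)


def test_single_pixel_object_has_unit_aspect_ratio():
    labels = np.zeros((9, 9), dtype=np.int32)
    labels[4, 4] = 1
    table = measure_particles(labels, _field(np.ones((9, 9)), pixel_size=1.5), min_area_um2=1.0)
    assert table["aspect_ratio"].iloc[0] == 1.0  # both axes floored at 1 px


def test_empty_labeling_gives_empty_table():
    table = measure_particles(np.zeros((8, 8), np.int32), _field(np.zeros((8, 8))))
    assert len(table) == 0
    assert list(table.columns) == [
        "label", "area_um2", "centroid_x", "centroid_y",
        "integrated_intensity", "major_um", "minor_um", "aspect_ratio",
    ]
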