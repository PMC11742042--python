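"""Synthetic microscopy generators: determinism, validation, ground truth."""

from __future__ import annotations

import numpy as np
import pytest
from pydantic import ValidationError
from skimage import measure

from neuritequant import (
    ArDistribution,
    NoiseConfig,
    SimConfig,
    simulate_mitochondria,
    simulate_monolayer_field,
    simulate_neurite_field,
)

SMALL = dict(field_area_um2=40_000, n_neurites=6, layout="bands")  # 308 px fields


def test_identical_config_and_seed_are_bit_identical():
    cfg = SimConfig(seed=77, degeneration=0.5, **SMALL)
    ch1, gt1 = simulate_neurite_field(cfg)
    ch2, gt2 = simulate_neurite_field(cfg)
    for name in ch1:
        assert np.array_equal(ch1[name].pixels, ch2[name].pixels)
    assert gt1.true_object_count == gt2.true_object_count
    assert np.array_equal(gt1.object_areas_um2, gt2.object_areas_um2)


def test_different_seeds_differ():
    cfg1 = SimConfig(seed=1, degeneration=0.5, **SMALL)
    cfg2 = SimConfig(seed=2, degeneration=0.5, **SMALL)
    a = simulate_neurite_field(cfg1)[0]["calcein"].pixels
    b = simulate_neurite_field(cfg2)[0]["calcein"].pixels
    assert not np.array_equal(a, b)


def test_out_of_range_config_rejected_naming_field():
    with pytest.raises(ValidationError, match="degeneration"):
        SimConfig(degeneration=1.3)
    with pytest.raises(ValidationError, match="mito_density_per_100um"):
        SimConfig(mito_density_per_100um=-1)
    with pytest.raises(ValidationError, match="polarized_fraction"):
        SimConfig(polarized_fraction=float("nan"))


def test_amplitude_must_fit_bit_depth():
    with pytest.raises(ValidationError, match="bit"):
        SimConfig(bit_depth=8, signal_amplitude=8000.0)


def test_field_dimensions_follow_calibration():
    cfg = SimConfig(field_area_um2=320_000, pixel_size_um=0.65)
    assert cfg.field_px == round(np.sqrt(320_000) / 0.65)


def test_undegenerated_field_has_one_object_per_neurite():
    """d = 0, noise off, banded layout: each neurite is one intact object."""
    cfg = SimConfig(seed=4, degeneration=0.0, noise=NoiseConfig.off(), **SMALL)
    channels, gt = simulate_neurite_field(cfg)
    assert gt.true_object_count == cfg.n_neurites
    assert gt.non_touching
    mask = channels["calcein"].pixels > 0
    assert measure.label(mask, connectivity=2).max() == cfg.n_neurites


def test_expected_count_increases_with_degeneration():
    """Poisson breakage: mean object count is increasing in d (Monte Carlo)."""
    def mean_count(d, seeds):
        counts = []
        for s in seeds:
            cfg = SimConfig(seed=s, degeneration=d, noise=NoiseConfig.off(), **SMALL)
            counts.append(simulate_neurite_field(cfg)[1].true_object_count)
        return np.mean(counts)

    seeds = range(50)
    assert mean_count(0.8, seeds) > mean_count(0.2, seeds)


def test_mean_fragment_area_decreases_with_degeneration():
    def mean_area(d, seeds):
        areas = []
        for s in seeds:
            cfg = SimConfig(seed=s, degeneration=d, noise=NoiseConfig.off(), **SMALL)
            areas.append(simulate_neurite_field(cfg)[1].true_mean_fragment_area_um2)
        return np.mean(areas)

    seeds = range(30)
    assert mean_area(0.2, seeds) > mean_area(0.8, seeds)


def test_certified_fields_match_component_count():
    """Whenever the generator certifies non-touching, recounting the rendered
    mask reproduces the true object count exactly."""
    for s in range(8):
        cfg = SimConfig(seed=s, degeneration=0.6, noise=NoiseConfig.off(), **SMALL)
        channels, gt = simulate_neurite_field(cfg)
        n_comp = measure.label(channels["calcein"].pixels > 0, connectivity=2).max()
        if gt.non_touching:
            assert n_comp == gt.true_object_count
        else:
            assert n_comp != gt.true_object_count


def test_annexin_colocalizes_with_calcein():
    cfg = SimConfig(seed=5, degeneration=0.5, annexin_positive_fraction=1.0,
                    noise=NoiseConfig.off(), **SMALL)
    channels, gt = simulate_neurite_field(cfg)
    assert gt.true_coloc_fraction == pytest.approx(1.0)
    annexin = channels["annexin"].pixels > 0
    calcein = channels["calcein"].pixels > 0
    assert np.array_equal(annexin, calcein)

    cfg0 = cfg.model_copy(update={"annexin_positive_fraction": 0.0})
    _, gt0 = simulate_neurite_field(cfg0)
    assert gt0.true_coloc_fraction == 0.0


# ---------------------------------------------------------------------------
# mitochondria


MITO = dict(field_area_um2=10_000, pixel_size_um=0.1, n_neurites=4, layout="bands")


def test_polarized_fraction_one_fills_both_channels():
    cfg = SimConfig(seed=6, polarized_fraction=1.0, noise=NoiseConfig.off(), **MITO)
    _, gt = simulate_neurite_field(cfg)
    channels, records = simulate_mitochondria(cfg, gt.skeletons)
    assert len(records) > 0
    assert records["polarized"].all()
    # every mitochondrion rendered in both channels (identical footprints)
    assert np.array_equal(channels["tmre"].pixels > 0, channels["cytc"].pixels > 0)


def test_polarized_fraction_zero_leaves_tmre_background_only():
    cfg = SimConfig(seed=6, polarized_fraction=0.0, noise=NoiseConfig.off(), **MITO)
    _, gt = simulate_neurite_field(cfg)
    channels, records = simulate_mitochondria(cfg, gt.skeletons)
    assert len(records) > 0
    assert not records["polarized"].any()
    assert channels["tmre"].pixels.max() == 0
    assert channels["cytc"].pixels.max() > 0


def test_fixed_axes_classify_elongated():
    """4 µm × 1 µm ellipses have AR = 4 > 3 and are recorded as elongated."""
    cfg = SimConfig(
        seed=7,
        mito_ar_distribution=ArDistribution(name="fixed", value=4.0),
        mito_minor_um=1.0,
        **MITO,
    )
    _, gt = simulate_neurite_field(cfg)
    _, records = simulate_mitochondria(cfg, gt.skeletons)
    assert len(records) > 0
    assert (records["shape_class"] == "elongated").all()
    assert (records["aspect_ratio"] == 4.0).all()


def test_shape_class_consistent_with_classification_rule():
    from neuritequant import classify_ar

    cfg = SimConfig(seed=8, **MITO)
    _, gt = simulate_neurite_field(cfg)
    _, records = simulate_mitochondria(cfg, gt.skeletons)
    expected = classify_ar(records["aspect_ratio"].to_numpy())
    assert (records["shape_class"].to_numpy() == expected).all()


def test_ar_distribution_validation():
    with pytest.raises(ValueError, match="choices"):
        ArDistribution(name="choice").sample(np.random.default_rng(0), 5)
    ar = ArDistribution(name="uniform", low=1.0, high=1.2).sample(np.random.default_rng(0), 100)
    assert (ar >= 1.0).all() and (ar <= 1.2).all()


# ---------------------------------------------------------------------------
# monolayer


def test_monolayer_all_nuclei_calcein_positive_when_fully_viable():
    cfg = SimConfig(seed=9, n_nuclei=40, viable_fraction=1.0, field_area_um2=90_000)
    channels, gt = simulate_monolayer_field(cfg)
    assert gt.n_viable == gt.n_nuclei == 40


def test_monolayer_zero_nuclei_gives_valid_empty_images():
    cfg = SimConfig(seed=9, n_nuclei=0, noise=NoiseConfig.off())
    channels, gt = simulate_monolayer_field(cfg)
    assert gt.n_nuclei == 0 and gt.n_viable == 0
    assert channels["hoechst"].pixels.max() == 0
    assert channels["calcein"].pixels.max() == 0


def test_monolayer_deterministic_viability_assignment():
    cfg = SimConfig(seed=10, n_nuclei=200, viable_fraction=0.5,
                    deterministic_viability=True)
    _, gt = simulate_monolayer_field(cfg)
    assert gt.n_viable == 100


def test_monolayer_binomial_viability_near_expectation():
    cfg = SimConfig(seed=11, n_nuclei=200, viable_fraction=0.5)
    _, gt = simulate_monolayer_field(cfg)
    # binomial(200, .5): ±4 SD band
    assert abs(gt.n_viable - 100) < 4 * np.sqrt(200 * 0.25)
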