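"""Derived readouts: degeneration indices, morphometry, colocalization,
densitometry and monolayer scoring."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuritequant import (
    Anchor,
    ImageField,
    NoiseConfig,
    SimConfig,
    classify_ar,
    classify_shapes,
    degeneration_scores,
    integrated_intensity,
    manders,
    mito_density,
    monolayer_scores,
    simulate_monolayer_field,
)

from helpers import manders_bruteforce


def _particles(areas, ars=None):
    n = len(areas)
    return pd.DataFrame(
        {
            "label": np.arange(1, n + 1),
            "area_um2": np.asarray(areas, dtype=float),
            "centroid_x": np.zeros(n),
            "centroid_y": np.zeros(n),
            "integrated_intensity": np.zeros(n),
            "major_um": np.ones(n),
            "minor_um": np.ones(n),
            "aspect_ratio": np.asarray(ars if ars is not None else np.ones(n), dtype=float),
        }
    )


def _field(pixels, channel=""):
    return ImageField(np.asarray(pixels, dtype=np.float64), pixel_size=1.0, channel=channel)


# ---------------------------------------------------------------------------
# degeneration indices


def test_integrity_and_fragmentation_definitions():
    intact = Anchor(mean_area_um2=500.0, count=10, condition_id="uncut")
    degen = Anchor(mean_area_um2=5.0, count=120, condition_id="wt18h")
    scores = degeneration_scores(_particles([125.0] * 30), intact, degen)
    assert scores.integrity_pct == pytest.approx(25.0)
    assert scores.fragmentation_pct == pytest.approx(25.0)


def test_integrity_self_normalization_is_100():
    table = _particles([50.0, 150.0, 100.0])
    anchor = Anchor(mean_area_um2=float(table["area_um2"].mean()), count=3)
    scores = degeneration_scores(table, anchor, Anchor(1.0, 3))
    assert scores.integrity_pct == pytest.approx(100.0)
    assert scores.fragmentation_pct == pytest.approx(100.0)


def test_zero_object_anchor_errors():
    with pytest.raises(ValueError, match="uncut"):
        degeneration_scores(_particles([1.0]), Anchor(0.0, 0, "uncut"), Anchor(1.0, 5))


# ---------------------------------------------------------------------------
# mito density


def test_mito_density_arithmetic():
    mask = np.zeros((100, 100), bool)
    mask[:40, :25] = True  # 1000 px = 10000 µm² at pixel_size ~3.162
    ps = np.sqrt(10.0)  # px area 10 µm²
    density = mito_density(_particles([2.0] * 50), mask, pixel_size=ps)
    assert density == pytest.approx(50 / 10000.0)
    assert mito_density(_particles([]), mask, pixel_size=ps) == 0.0


def test_mito_density_empty_mask_errors():
    with pytest.raises(ValueError, match="neurite mask"):
        mito_density(_particles([2.0]), np.zeros((4, 4), bool), pixel_size=1.0)


# ---------------------------------------------------------------------------
# shape classification


def test_shape_classes_and_boundaries():
    """AR<1.5 round, AR>3 elongated; the boundaries fall in intermediate."""
    assert list(classify_ar([1.2, 2.0, 3.5])) == ["round", "intermediate", "elongated"]
    assert list(classify_ar([1.5, 3.0])) == ["intermediate", "intermediate"]
    stats = classify_shapes(_particles([2.0] * 3, ars=[1.2, 2.0, 3.5]))
    assert (stats.fraction_round, stats.fraction_intermediate, stats.fraction_elongated) == (
        pytest.approx(1 / 3),
        pytest.approx(1 / 3),
        pytest.approx(1 / 3),
    )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=1.0, max_value=20.0), min_size=1, max_size=200))
def test_shape_fractions_sum_to_one(ars):
    stats = classify_shapes(_particles(np.full(len(ars), 2.0), ars=ars))
    assert stats.fraction_round + stats.fraction_intermediate + stats.fraction_elongated == (
        pytest.approx(1.0)
    )


def test_shape_stats_validity_flag():
    """Valid only with >100 mitochondria from ≥5 independent fields."""
    many = _particles(np.full(150, 2.0), ars=np.full(150, 2.0))
    assert classify_shapes(many, n_fields=5).valid
    assert not classify_shapes(many, n_fields=4).valid
    few = _particles(np.full(100, 2.0), ars=np.full(100, 2.0))
    assert not classify_shapes(few, n_fields=5).valid  # needs strictly more than 100


def test_shape_empty_table_flagged():
    stats = classify_shapes(_particles([]))
    assert stats.n_evaluated == 0 and not stats.valid
    assert np.isnan(stats.fraction_round)


# ---------------------------------------------------------------------------
# Manders colocalization


def test_manders_identical_channels_are_total():
    rng = np.random.default_rng(3)
    a = rng.integers(0, 1000, (32, 32)).astype(float)
    res = manders(_field(a), _field(a), thresholds=(100.0, 100.0))
    assert res.m1 == pytest.approx(1.0)
    assert res.m2 == pytest.approx(1.0)


def test_manders_disjoint_supports_are_zero():
    a = np.zeros((10, 10))
    b = np.zeros((10, 10))
    a[:5] = 50.0
    b[5:] = 50.0
    res = manders(_field(a), _field(b), thresholds=(10.0, 10.0))
    assert res.m1 == 0.0 and res.m2 == 0.0


def test_manders_matches_pixel_oracle(rng):
    """Equals an explicit per-pixel double loop on random image pairs."""
    for _ in range(5):
        a = rng.integers(0, 255, (12, 12)).astype(float)
        b = rng.integers(0, 255, (12, 12)).astype(float)
        res = manders(_field(a), _field(b), thresholds=(90.0, 120.0))
        m1, m2 = manders_bruteforce(a, b, 90.0, 120.0)
        assert res.m1 == pytest.approx(m1)
        assert res.m2 == pytest.approx(m2)


def test_manders_invariant_to_joint_rescaling(rng):
    a = rng.integers(0, 255, (16, 16)).astype(float)
    b = rng.integers(0, 255, (16, 16)).astype(float)
    r1 = manders(_field(a), _field(b), thresholds=(80.0, 80.0))
    r2 = manders(_field(3 * a), _field(3 * b), thresholds=(240.0, 240.0))
    assert r1.m1 == pytest.approx(r2.m1)
    assert r1.m2 == pytest.approx(r2.m2)


def test_manders_zero_denominator_names_channel():
    a = np.zeros((8, 8))
    b = np.full((8, 8), 99.0)
    with pytest.raises(ValueError, match="annexin"):
        manders(_field(a, channel="annexin"), _field(b), thresholds=(10.0, 10.0))


# ---------------------------------------------------------------------------
# integrated intensity (densitometry)


def test_integrated_intensity_background_correction():
    px = np.full((20, 20), 10.0)
    obj = np.zeros((20, 20), bool)
    obj[:10, :10] = True
    px[obj] = 50.0
    bg = ~obj
    assert integrated_intensity(_field(px), obj, bg) == pytest.approx(4000.0)


def test_integrated_intensity_uniform_is_zero():
    px = np.full((10, 10), 7.0)
    obj = np.zeros((10, 10), bool)
    obj[:5] = True
    assert integrated_intensity(_field(px), obj, ~obj) == 0.0


def test_integrated_intensity_validation():
    px = np.ones((6, 6))
    obj = np.zeros((6, 6), bool)
    obj[0, 0] = True
    with pytest.raises(ValueError, match="background"):
        integrated_intensity(_field(px), obj, np.zeros((6, 6), bool))
    with pytest.raises(ValueError, match="overlap"):
        integrated_intensity(_field(px), obj, obj)


# ---------------------------------------------------------------------------
# monolayer scoring


def test_monolayer_all_viable_and_none_viable():
    cfg = SimConfig(seed=21, n_nuclei=60, viable_fraction=1.0,
                    field_area_um2=90_000, noise=NoiseConfig.off())
    channels, gt = simulate_monolayer_field(cfg)
    scores = monolayer_scores(channels["calcein"], channels["hoechst"])
    assert scores.n_nuclei == 60
    assert scores.raw_viability == pytest.approx(1.0)

    cfg0 = cfg.model_copy(update={"viable_fraction": 0.0})
    channels, gt = simulate_monolayer_field(cfg0)
    scores = monolayer_scores(channels["calcein"], channels["hoechst"])
    assert scores.raw_viability == 0.0
    assert scores.neurite_area_um2 == 0.0


def test_monolayer_zero_nuclei_errors():
    calcein = _field(np.zeros((64, 64)))
    nuclei = _field(np.zeros((64, 64)))
    with pytest.raises(ValueError, match="nuclei"):
        monolayer_scores(calcein, nuclei)


def test_monolayer_viability_matches_ground_truth():
    cfg = SimConfig(seed=8, n_nuclei=100, viable_fraction=0.5, field_area_um2=160_000)
    channels, gt = simulate_monolayer_field(cfg)
    scores = monolayer_scores(channels["calcein"], channels["hoechst"])
    assert scores.n_nuclei == gt.n_nuclei
    assert scores.raw_viability == pytest.approx(gt.n_viable / gt.n_nuclei, abs=0.05)
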