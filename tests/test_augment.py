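"""Augmentation operators: identities, label semantics, size arithmetic."""

import numpy as np
import pytest

from irfgnet.augment import (
    AugmentationConfig,
    augment_dataset,
    horizontal_shift,
    linear_combination,
    oversample,
    vertical_noise,
)
from irfgnet.catalog import LabelVector
from irfgnet.spectra import DEFAULT_GRID, ProcessedSpectrum
from irfgnet.synth import LabeledSpectrum


def spec_of(values):
    return ProcessedSpectrum(np.asarray(values, dtype=float), grid=DEFAULT_GRID)


def labeled(values, bits, sid="s"):
    return LabeledSpectrum(
        spectrum=spec_of(values),
        labels=LabelVector(bits=np.asarray(bits, dtype=np.int8), source_id=sid),
    )


@pytest.fixture
def bumpy():
    y = np.zeros(600)
    y[100] = 1.0
    y[300] = 0.5
    return spec_of(y)


def test_zero_shift_is_identity(bumpy):
    out = horizontal_shift(bumpy, 0)
    np.testing.assert_array_equal(out.intensities, bumpy.intensities)


def test_shift_moves_argmax(bumpy):
    assert int(np.argmax(horizontal_shift(bumpy, 3).intensities)) == 103
    assert int(np.argmax(horizontal_shift(bumpy, -4).intensities)) == 96


def test_shift_edge_fill_bookkeeping(bumpy):
    back_and_forth = horizontal_shift(horizontal_shift(bumpy, -2), 2)
    # only the final 2 right-edge bins can differ (their values were shifted out)
    np.testing.assert_array_equal(
        back_and_forth.intensities[:-2], bumpy.intensities[:-2]
    )


def test_shift_preserves_length_and_range(bumpy):
    out = horizontal_shift(bumpy, 7)
    assert out.intensities.shape == (600,)
    assert out.intensities.min() >= 0 and out.intensities.max() <= 1


def test_shift_rejects_full_length():
    with pytest.raises(ValueError):
        horizontal_shift(spec_of(np.zeros(600)), 600)


def test_zero_noise_is_identity(bumpy, rng):
    out = vertical_noise(bumpy, 0.0, rng)
    np.testing.assert_array_equal(out.intensities, bumpy.intensities)


def test_noise_keeps_zero_bins_zero(rng):
    y = np.zeros(600)
    y[50:60] = 0.8
    out = vertical_noise(spec_of(y), 0.3, rng)
    np.testing.assert_array_equal(out.intensities[y == 0], 0.0)


def test_noise_law_monte_carlo():
    """x' = x(1 + eps): a constant-0.5 spectrum perturbed at sd_rel = 0.05
    must show per-bin sample sd near 0.5 * 0.05 = 0.025."""
    rng = np.random.default_rng(77)
    base = spec_of(np.full(600, 0.5))
    reps = np.stack(
        [vertical_noise(base, 0.05, rng).intensities for _ in range(10_000)]
    )
    sd = reps.std(axis=0)
    assert np.all(np.abs(sd - 0.025) < 0.05 * 0.025 + 3 * 0.025 / np.sqrt(2 * 10_000))


def test_negative_noise_rejected(bumpy, rng):
    with pytest.raises(ValueError):
        vertical_noise(bumpy, -0.1, rng)


def test_linear_combination_or_labels_and_closed_form():
    a = labeled(np.full(600, 0.2), [1, 0, 0], "a")
    b = labeled(np.full(600, 0.8), [0, 0, 1], "b")
    mixed = linear_combination(a, b, 0.5)
    np.testing.assert_array_equal(mixed.labels.bits, [1, 0, 1])
    # 0.5*0.2 + 0.5*0.8 = 0.5 constant -> degenerate normalization to zeros
    np.testing.assert_array_equal(mixed.spectrum.intensities, np.zeros(600))


def test_linear_combination_lam_one_endpoint():
    y = np.zeros(600)
    y[10] = 1.0
    a = labeled(y, [1, 0], "a")
    b = labeled(np.zeros(600), [0, 1], "b")
    out = linear_combination(a, b, 1.0)  # endpoint permitted in tests
    np.testing.assert_array_equal(out.spectrum.intensities, a.spectrum.intensities)
    np.testing.assert_array_equal(out.labels.bits, [1, 1])


def test_linear_combination_popcount_monotone(rng):
    for _ in range(20):
        ba = (rng.random(5) < 0.5).astype(np.int8)
        bb = (rng.random(5) < 0.5).astype(np.int8)
        a = labeled(rng.random(600), ba, "a")
        b = labeled(rng.random(600), bb, "b")
        out = linear_combination(a, b, 0.4)
        pc = out.labels.bits.sum()
        assert pc >= ba.sum() and pc >= bb.sum()


def test_linear_combination_catalog_mismatch():
    a = labeled(np.zeros(600), [1, 0])
    b = labeled(np.zeros(600), [1, 0, 1])
    with pytest.raises(ValueError, match="catalog"):
        linear_combination(a, b, 0.5)


@pytest.mark.parametrize("fraction,expected", [(0.25, 125), (0.5, 150), (0.75, 175), (1.0, 200)])
def test_oversample_size_arithmetic(fraction, expected, rng):
    ds = [labeled(np.zeros(600), [1], str(i)) for i in range(100)]
    out = oversample(ds, fraction, rng)
    assert len(out) == expected


def test_oversample_full_fraction_duplicates_each_exactly_twice(rng):
    ds = [labeled(np.zeros(600), [1], str(i)) for i in range(100)]
    out = oversample(ds, 1.0, rng)
    ids = [d.labels.source_id for d in out]
    assert all(ids.count(str(i)) == 2 for i in range(100))


def test_oversample_rejects_bad_fraction_and_empty(rng):
    ds = [labeled(np.zeros(600), [1])]
    with pytest.raises(ValueError):
        oversample(ds, 0.3, rng)
    with pytest.raises(ValueError):
        oversample([], 0.5, rng)


def test_augment_dataset_sizes_and_determinism(tiny_dataset):
    ds, _ = tiny_dataset
    for method in ("horizontal_shift", "vertical_noise", "linear_combination", "oversample"):
        cfg = AugmentationConfig(method=method, fraction=0.5, seed=5)
        out1 = augment_dataset(list(ds), cfg)
        out2 = augment_dataset(list(ds), cfg)
        assert len(out1) == len(ds) + round(0.5 * len(ds))
        for a, b in zip(out1, out2):
            np.testing.assert_array_equal(a.spectrum.intensities, b.spectrum.intensities)
            np.testing.assert_array_equal(a.labels.bits, b.labels.bits)


def test_augment_dataset_preserves_length_and_unit_range(tiny_dataset):
    ds, _ = tiny_dataset
    for method in ("horizontal_shift", "vertical_noise", "linear_combination"):
        cfg = AugmentationConfig(method=method, fraction=1.0, seed=3)
        for item in augment_dataset(list(ds), cfg):
            v = item.spectrum.intensities
            assert v.shape == (600,)
            assert v.min() >= 0 and v.max() <= 1


def test_augment_dataset_or_semantics_for_linear_combination(tiny_dataset):
    ds, _ = tiny_dataset
    cfg = AugmentationConfig(method="linear_combination", fraction=1.0, seed=9)
    out = augment_dataset(list(ds), cfg)
    n = len(ds)
    for item in out[n:]:
        assert item.labels.bits.sum() >= max(
            d.labels.bits.sum() for d in ds if set(np.flatnonzero(d.labels.bits)) <= set(np.flatnonzero(item.labels.bits))
        )


def test_augmentation_config_validation():
    with pytest.raises(ValueError):
        AugmentationConfig(method="mixup", fraction=0.5, seed=1)
    with pytest.raises(ValueError):
        AugmentationConfig(method="oversample", fraction=0.3, seed=1)
    with pytest.raises(ValueError):
        AugmentationConfig(method="vertical_noise", fraction=0.5, seed=1, noise_sd_rel=-1)
    with pytest.raises(ValueError):
        AugmentationConfig(method="linear_combination", fraction=0.5, seed=1, mix_low=0.8, mix_high=0.2)
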