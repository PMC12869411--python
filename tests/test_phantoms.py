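"""Unit tests for the lumpy-background phantom and pinhole imaging chain."""

import numpy as np
import pytest

from vsmo.phantoms import (
    ApertureModel,
    PhantomConfig,
    apply_quantum_noise,
    fwhm_to_sigma,
    generate_dataset,
    insert_lesion,
    project_pinhole,
    sample_lumpy_background,
)


def test_no_lumps_gives_constant_background():
    cfg = PhantomConfig(image_size=32, lump_count_mean=0.0, dc_offset=7.5, lesion_margin_px=8)
    ph = sample_lumpy_background(cfg, seed=3)
    assert np.allclose(ph.intensity, 7.5)
    assert not ph.lesion_present and ph.lesion_center is None


def test_lesion_integral_matches_gaussian_area():
    # integral of an isotropic Gaussian: amplitude * pi * FWHM^2 / (4 ln 2)
    cfg = PhantomConfig(
        image_size=128, lump_count_mean=0.0, dc_offset=0.0, lesion_amplitude=5.0
    )
    base = sample_lumpy_background(cfg, seed=0)
    lesioned = insert_lesion(base, (64, 64), cfg)
    measured = lesioned.intensity.sum()
    expected = 5.0 * np.pi * cfg.lesion_fwhm_px**2 / (4.0 * np.log(2.0))
    assert measured == pytest.approx(expected, rel=0.01)


def test_lesion_margin_enforced():
    cfg = PhantomConfig(image_size=64)
    ph = sample_lumpy_background(cfg, seed=1)
    with pytest.raises(ValueError):
        insert_lesion(ph, (4, 32), cfg)
    with pytest.raises(ValueError):
        insert_lesion(ph, (32, 63), cfg)


def test_projection_total_counts_scale_with_aperture_area():
    cfg = PhantomConfig(image_size=64)
    ph = sample_lumpy_background(cfg, seed=5)
    for d_rel in (0.4, 1.0, 2.5):
        ap = ApertureModel(d_rel, reference_counts=5.0e4)
        mean = project_pinhole(ph, ap)
        assert mean.sum() == pytest.approx(5.0e4 * d_rel**2, rel=1e-9)
        assert np.all(mean >= 0.0)


def test_projection_blur_widths_add_in_quadrature():
    # a Gaussian lesion imaged through a Gaussian aperture stays Gaussian with
    # FWHM = sqrt(lesion^2 + aperture^2); measure via second moments
    cfg = PhantomConfig(image_size=128, lump_count_mean=0.0, dc_offset=0.0)
    ph = insert_lesion(sample_lumpy_background(cfg, seed=0), (64, 64), cfg)
    d_rel = 1.5
    mean = project_pinhole(ph, ApertureModel(d_rel))
    r = np.arange(128, dtype=float)
    w = mean / mean.sum()
    mu = (w.sum(axis=1) * r).sum()
    var = (w.sum(axis=1) * (r - mu) ** 2).sum()
    a = cfg.lesion_fwhm_px
    b = d_rel * cfg.lesion_fwhm_px
    expected_sigma = fwhm_to_sigma(np.sqrt(a**2 + b**2))
    assert np.sqrt(var) == pytest.approx(expected_sigma, rel=0.01)


def test_quantum_noise_is_poisson():
    cfg = PhantomConfig(image_size=16, lesion_margin_px=4)
    ph = sample_lumpy_background(cfg, seed=9)
    mean = project_pinhole(ph, ApertureModel(1.0, reference_counts=2.0e4))
    reps = np.stack(
        [apply_quantum_noise(mean, seed=1000 + i).pixels for i in range(500)]
    ).astype(float)
    ratio = reps.var(axis=0, ddof=1) / np.maximum(reps.mean(axis=0), 1e-12)
    assert 0.9 <= np.median(ratio) <= 1.1


def test_quantum_noise_rejects_negative_means():
    with pytest.raises(ValueError):
        apply_quantum_noise(np.array([[-1.0, 2.0]]), seed=0)


def test_dataset_shape_prevalence_and_ordering(small_phantom):
    ds = generate_dataset(small_phantom, ApertureModel(1.0), n_pairs=6, seed=11)
    assert len(ds) == 12
    assert ds.prevalence == 0.5
    labels = [im.lesion_present for im in ds.images]
    assert labels == [True] * 6 + [False] * 6
    for im in ds.images:
        assert im.lesion_present == (im.lesion_center is not None)
        assert im.pixels.shape == (64, 64)
        assert np.issubdtype(im.pixels.dtype, np.integer)


def test_dataset_determinism(small_phantom):
    a = generate_dataset(small_phantom, ApertureModel(1.0), n_pairs=3, seed=42)
    b = generate_dataset(small_phantom, ApertureModel(1.0), n_pairs=3, seed=42)
    for ia, ib in zip(a.images, b.images):
        assert np.array_equal(ia.pixels, ib.pixels)
        assert ia.lesion_center == ib.lesion_center
    c = generate_dataset(small_phantom, ApertureModel(1.0), n_pairs=3, seed=43)
    assert not all(
        np.array_equal(ia.pixels, ic.pixels) for ia, ic in zip(a.images, c.images)
    )


def _pair_correlations(ds, n):
    return [
        np.corrcoef(p.mean_field.ravel(), a.mean_field.ravel())[0, 1]
        for p, a in zip(ds.images[:n], ds.images[n:])
    ]


def test_paired_backgrounds_share_the_lumpy_field(small_phantom):
    ds = generate_dataset(small_phantom, ApertureModel(1.0), n_pairs=4, seed=7)
    # identical lumpy background under the lesion => each present/absent pair
    # is strongly correlated (the lesion itself caps the correlation below 1)
    for r in _pair_correlations(ds, 4):
        assert r > 0.85


def test_unpaired_backgrounds_differ(small_phantom):
    paired = generate_dataset(small_phantom, ApertureModel(1.0), 4, seed=7)
    unpaired = generate_dataset(
        small_phantom, ApertureModel(1.0), 4, seed=7, paired_backgrounds=False
    )
    # present images identical in both designs; absent images differ
    for pp, up in zip(paired.images[:4], unpaired.images[:4]):
        assert np.array_equal(pp.pixels, up.pixels)
    # independent lumpy fields still share the DC offset, so unpaired
    # correlations stay well below the paired ones rather than near zero
    assert np.mean(_pair_correlations(unpaired, 4)) < np.mean(
        _pair_correlations(paired, 4)
    ) - 0.1


def test_config_validation():
    with pytest.raises(ValueError):
        PhantomConfig(image_size=0)
    with pytest.raises(ValueError):
        PhantomConfig(lump_count_mean=-1)
    with pytest.raises(ValueError):
        PhantomConfig(lesion_fwhm_px=0.0)
    with pytest.raises(ValueError):
        PhantomConfig(image_size=32, lesion_margin_px=16)
    with pytest.raises(ValueError):
        ApertureModel(0.0)
    with pytest.raises(ValueError):
        ApertureModel(1.0, reference_counts=0.0)
    with pytest.raises(ValueError):
        generate_dataset(PhantomConfig(image_size=64), ApertureModel(1.0), -1, 0)
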