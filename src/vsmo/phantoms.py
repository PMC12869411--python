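"""Lumpy-background phantom simulation and Gaussian-pinhole planar imaging.

The simulated object is the classic lumpy background: a Poisson-distributed
number of identical, rotationally symmetric Gaussian "lumps" dropped uniformly
at random on a constant background, optionally with a single Gaussian lesion
inserted at a known pixel.  Imaging through a pinhole is modeled as periodic
convolution with a 2D Gaussian aperture whose width scales with the
dimensionless relative diameter, followed by Poisson (quantum) photon noise.
Photon throughput scales with aperture area, so small pinholes give sharp but
noisy images and large pinholes give clean but blurred ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numpy.random import SeedSequence, default_rng

__all__ = [
    "PhantomConfig",
    "Phantom",
    "ApertureModel",
    "ProjectionImage",
    "Dataset",
    "sample_lumpy_background",
    "insert_lesion",
    "project_pinhole",
    "apply_quantum_noise",
    "generate_dataset",
    "fwhm_to_sigma",
]

#: FWHM of a Gaussian = 2*sqrt(2 ln 2) * sigma
_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full width at half maximum to its standard deviation."""
    return fwhm / _FWHM_FACTOR


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the lumpy-background object model.

    Intensity units are arbitrary; the absolute photon scale is imposed later
    by :func:`project_pinhole` through ``ApertureModel.reference_counts``.
    """

    image_size: int = 128
    pixel_size_mm: float = 2.4
    lump_count_mean: float = 50.0
    lump_fwhm_px: float = 28.2
    lump_amplitude: float = 1.0
    dc_offset: float = 10.0
    lesion_fwhm_px: float = 9.4
    lesion_amplitude: float = 14.0
    lesion_margin_px: int = 16

    def __post_init__(self) -> None:
        if self.image_size <= 0:
            raise ValueError(f"image_size must be positive, got {self.image_size}")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        if self.lump_count_mean < 0:
            raise ValueError("lump_count_mean must be nonnegative")
        for name in ("lump_fwhm_px", "lesion_fwhm_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 <= self.lesion_margin_px < self.image_size / 2:
            raise ValueError(
                "lesion_margin_px must lie in [0, image_size/2); got "
                f"{self.lesion_margin_px} for image_size {self.image_size}"
            )


@dataclass(frozen=True)
class Phantom:
    """A noiseless 2D scene: lumpy background, optionally plus one lesion."""

    intensity: np.ndarray
    lesion_present: bool
    lesion_center: Optional[tuple[int, int]]
    config: PhantomConfig

    def __post_init__(self) -> None:
        if self.lesion_present != (self.lesion_center is not None):
            raise ValueError("lesion_center must be present iff lesion_present")


@dataclass(frozen=True)
class ApertureModel:
    """Gaussian pinhole aperture.

    ``relative_diameter`` is the aperture FWHM divided by the lesion FWHM, so
    values above 1 blur the lesion away while values below 1 starve the image
    of photons (mean total counts = reference_counts * relative_diameter**2).
    """

    relative_diameter: float
    reference_counts: float = 5.0e4

    def __post_init__(self) -> None:
        if self.relative_diameter <= 0:
            raise ValueError("relative_diameter must be positive")
        if self.reference_counts <= 0:
            raise ValueError("reference_counts must be positive")


@dataclass(frozen=True)
class ProjectionImage:
    """A noisy photon-count image together with its noiseless mean and truth."""

    pixels: np.ndarray
    mean_field: np.ndarray
    aperture: ApertureModel
    lesion_present: bool
    lesion_center: Optional[tuple[int, int]]
    rng_seed: int

    def __post_init__(self) -> None:
        if self.pixels.shape != self.mean_field.shape:
            raise ValueError("pixels and mean_field must share a shape")


@dataclass
class Dataset:
    """An ordered collection of projection images with a master seed."""

    images: list[ProjectionImage]
    prevalence: float
    seed: int
    config: PhantomConfig = field(default_factory=PhantomConfig)
    aperture: ApertureModel = field(default_factory=lambda: ApertureModel(1.0))

    def __len__(self) -> int:
        return len(self.images)


def _gaussian_blob_sum(
    size: int, rows: np.ndarray, cols: np.ndarray, amplitude: float, fwhm: float
) -> np.ndarray:
    """Sum of identical isotropic Gaussians at (rows[i], cols[i]), rendered on
    a size x size grid.  Separable per blob: outer product of 1D profiles."""
    if rows.size == 0:
        return np.zeros((size, size))
    sigma = fwhm_to_sigma(fwhm)
    ax = np.arange(size, dtype=float)
    # (n_blobs, size) 1D profiles along each axis
    pr = np.exp(-((ax[None, :] - rows[:, None]) ** 2) / (2.0 * sigma**2))
    pc = np.exp(-((ax[None, :] - cols[:, None]) ** 2) / (2.0 * sigma**2))
    return amplitude * np.einsum("nr,nc->rc", pr, pc)


def sample_lumpy_background(config: PhantomConfig, seed: int) -> Phantom:
    """Draw one lesion-absent lumpy-background phantom.

    The number of lumps is Poisson(``lump_count_mean``); each lump is an
    isotropic Gaussian of FWHM ``lump_fwhm_px`` at a uniform random continuous
    position, added to ``dc_offset``.  Deterministic given (config, seed).
    """
    rng = default_rng(SeedSequence(seed))
    n_lumps = rng.poisson(config.lump_count_mean)
    size = config.image_size
    rows = rng.uniform(0.0, size, size=n_lumps)
    cols = rng.uniform(0.0, size, size=n_lumps)
    intensity = config.dc_offset + _gaussian_blob_sum(
        size, rows, cols, config.lump_amplitude, config.lump_fwhm_px
    )
    return Phantom(intensity=intensity, lesion_present=False, lesion_center=None, config=config)


def insert_lesion(
    phantom: Phantom, center: tuple[int, int], config: Optional[PhantomConfig] = None
) -> Phantom:
    """Return a new phantom with a Gaussian lesion added at ``center`` (row, col)."""
    cfg = config or phantom.config
    size = cfg.image_size
    m = cfg.lesion_margin_px
    r, c = int(center[0]), int(center[1])
    if not (m <= r < size - m and m <= c < size - m):
        raise ValueError(
            f"lesion center {center} violates the {m}-px margin on a {size}-px image"
        )
    lesion = _gaussian_blob_sum(
        size, np.array([float(r)]), np.array([float(c)]), cfg.lesion_amplitude, cfg.lesion_fwhm_px
    )
    return Phantom(
        intensity=phantom.intensity + lesion,
        lesion_present=True,
        lesion_center=(r, c),
        config=cfg,
    )


def _aperture_kernel_rfft(size: int, fwhm_px: float) -> np.ndarray:
    """rfft2 of the unit-integral periodic Gaussian aperture kernel."""
    ax = np.arange(size, dtype=float)
    # distance to the origin on a periodic axis
    d = np.minimum(ax, size - ax)
    sigma = fwhm_to_sigma(fwhm_px)
    prof = np.exp(-(d**2) / (2.0 * sigma**2))
    kernel = np.outer(prof, prof)
    kernel /= kernel.sum()
    return np.fft.rfft2(kernel)


def project_pinhole(phantom: Phantom, aperture: ApertureModel) -> np.ndarray:
    """Image a phantom through the Gaussian pinhole: periodic convolution with
    a unit-integral Gaussian of FWHM = relative_diameter * lesion_fwhm_px, then
    rescaling so the total equals reference_counts * relative_diameter**2
    (throughput proportional to aperture area).  Returns the mean count field.
    """
    size = phantom.config.image_size
    fwhm = aperture.relative_diameter * phantom.config.lesion_fwhm_px
    kf = _aperture_kernel_rfft(size, fwhm)
    blurred = np.fft.irfft2(np.fft.rfft2(phantom.intensity) * kf, s=(size, size))
    blurred = np.maximum(blurred, 0.0)  # clip tiny negative FFT ringing
    total = blurred.sum()
    if total <= 0:
        raise ValueError("phantom has zero total intensity; cannot impose count scale")
    target = aperture.reference_counts * aperture.relative_diameter**2
    return blurred * (target / total)


def apply_quantum_noise(
    mean_field: np.ndarray,
    seed: int,
    aperture: Optional[ApertureModel] = None,
    lesion_present: bool = False,
    lesion_center: Optional[tuple[int, int]] = None,
) -> ProjectionImage:
    """Sample an independent Poisson count at each pixel of ``mean_field``."""
    if np.any(mean_field < 0):
        raise ValueError("mean_field must be nonnegative for Poisson sampling")
    rng = default_rng(SeedSequence(seed))
    pixels = rng.poisson(mean_field).astype(np.int64)
    return ProjectionImage(
        pixels=pixels,
        mean_field=np.asarray(mean_field, dtype=float),
        aperture=aperture if aperture is not None else ApertureModel(1.0),
        lesion_present=lesion_present,
        lesion_center=lesion_center,
        rng_seed=int(seed),
    )


def _child_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed: SeedSequence entropy mixed with a spawn key.

    Any image in a dataset is reproducible in isolation from (master seed, key).
    """
    return int(SeedSequence(entropy=master_seed, spawn_key=key).generate_state(1)[0])


def generate_dataset(
    config: PhantomConfig,
    aperture: ApertureModel,
    n_pairs: int,
    seed: int,
    paired_backgrounds: bool = True,
) -> Dataset:
    """Generate ``n_pairs`` lesion-present and ``n_pairs`` lesion-absent images.

    Lesion centers are uniform over the margin-respecting interior.  With
    ``paired_backgrounds`` (default) the i-th present and absent images share
    the identical lumpy background (signal-known-statistically paired design),
    which halves the background contribution to Monte-Carlo variance; noise
    realizations always differ.  Present images come first, then absent.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be nonnegative")
    size, m = config.image_size, config.lesion_margin_px
    center_rng = default_rng(SeedSequence(entropy=seed, spawn_key=(0xC,)))
    present: list[ProjectionImage] = []
    absent: list[ProjectionImage] = []
    for i in range(n_pairs):
        bg = sample_lumpy_background(config, _child_seed(seed, 1, i))
        if paired_backgrounds:
            bg_absent = bg
        else:
            bg_absent = sample_lumpy_background(config, _child_seed(seed, 2, i))
        r, c = center_rng.integers(m, size - m, size=2)
        lesioned = insert_lesion(bg, (int(r), int(c)), config)
        mean_p = project_pinhole(lesioned, aperture)
        mean_a = project_pinhole(bg_absent, aperture)
        sp = _child_seed(seed, 3, i)
        sa = _child_seed(seed, 4, i)
        present.append(
            apply_quantum_noise(mean_p, sp, aperture, True, (int(r), int(c)))
        )
        absent.append(apply_quantum_noise(mean_a, sa, aperture, False, None))
    images = present + absent
    prevalence = 0.5 if n_pairs else 0.0
    return Dataset(images=images, prevalence=prevalence, seed=int(seed), config=config, aperture=aperture)
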