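"""2D Gabor filter banks and feature-map computation.

A Gabor kernel is a Gaussian envelope modulated by an oriented cosine carrier:

    G(x, y) = exp(-4 ln2 * ((x-x0)^2 + (y-y0)^2) / Ws^2)
              * cos(2 pi fc * ((x-x0) cos(theta) + (y-y0) sin(theta)) + phi)

where ``Ws`` is the envelope full width at half maximum, ``fc`` the carrier
frequency in cycles per pixel, ``theta`` the carrier orientation and ``phi``
its phase.  Such kernels model the receptive fields of simple cells in primary
visual cortex and are the standard front end of anthropomorphic model
observers.  Coordinates map to arrays as x = axis 0 (row), y = axis 1 (col),
so theta = 0 modulates along the row axis.

Feature maps are periodic cross-correlations of an image with each kernel;
the raw signed response is kept (no magnitude), since the observer's
thresholding acts as a signed lower bound on feature values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GaborParams",
    "GaborKernel",
    "FilterBank",
    "FeatureMapStack",
    "make_gabor_kernel",
    "build_filter_bank",
    "default_filter_bank",
    "apply_filter_bank",
    "features_at_location",
]


@dataclass(frozen=True)
class GaborParams:
    """Parameters of one Gabor kernel (see module docstring for the formula)."""

    ws: float
    fc: float
    theta: float
    phi: float
    center: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.ws <= 0:
            raise ValueError("ws (envelope FWHM) must be positive")
        if self.fc < 0:
            raise ValueError("fc (carrier frequency) must be nonnegative")
        if not 0.0 <= self.theta < np.pi:
            raise ValueError("theta must lie in [0, pi); theta and theta+pi are redundant")
        if not 0.0 <= self.phi < 2.0 * np.pi:
            raise ValueError("phi must lie in [0, 2*pi)")


@dataclass(frozen=True)
class GaborKernel:
    params: GaborParams
    support_px: int
    weights: np.ndarray


@dataclass(frozen=True)
class FilterBank:
    """Ordered Gabor kernels generated from a Cartesian parameter grid."""

    kernels: tuple[GaborKernel, ...]
    grid_spec: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.kernels)


@dataclass(frozen=True)
class FeatureMapStack:
    """One response map per kernel, each the same shape as the source image."""

    maps: np.ndarray  # (n_kernels, H, W)
    source: str = ""

    def __len__(self) -> int:
        return self.maps.shape[0]


def make_gabor_kernel(params: GaborParams, support_px: int) -> GaborKernel:
    """Evaluate the Gabor function on an odd square grid of side ``support_px``.

    The default center is the grid midpoint ((support-1)/2, (support-1)/2).
    """
    if support_px < 3 or support_px % 2 == 0:
        raise ValueError(f"support_px must be odd and >= 3, got {support_px}")
    c = (support_px - 1) / 2.0
    x0, y0 = params.center if params.center is not None else (c, c)
    x = np.arange(support_px, dtype=float)[:, None] - x0  # rows
    y = np.arange(support_px, dtype=float)[None, :] - y0  # cols
    envelope = np.exp(-4.0 * np.log(2.0) * (x**2 + y**2) / params.ws**2)
    carrier = np.cos(
        2.0 * np.pi * params.fc * (x * np.cos(params.theta) + y * np.sin(params.theta))
        + params.phi
    )
    return GaborKernel(params=params, support_px=support_px, weights=envelope * carrier)


def _default_support(ws: float) -> int:
    """Smallest odd integer >= 4*ws (envelope < 1.6% of peak at truncation)."""
    s = int(np.ceil(4.0 * ws))
    if s % 2 == 0:
        s += 1
    return max(s, 3)


def build_filter_bank(
    ws_list: Sequence[float],
    fc_list: Sequence[float],
    theta_list: Sequence[float],
    phi_list: Sequence[float],
    support_px: Optional[int] = None,
) -> FilterBank:
    """Cartesian-product bank with deterministic ordering (ws outer, phi inner).

    ``support_px`` fixes one support for all kernels; by default each kernel
    gets the smallest odd support >= 4*ws.
    """
    for name, lst in (("ws", ws_list), ("fc", fc_list), ("theta", theta_list), ("phi", phi_list)):
        if len(lst) == 0:
            raise ValueError(f"{name}_list must be nonempty")
    combos = list(itertools.product(ws_list, fc_list, theta_list, phi_list))
    if len(set(combos)) != len(combos):
        raise ValueError("duplicate parameter tuples in the grid")
    kernels = []
    for ws, fc, theta, phi in combos:
        sup = support_px if support_px is not None else _default_support(ws)
        kernels.append(make_gabor_kernel(GaborParams(ws, fc, theta, phi), sup))
    grid = {
        "ws": list(map(float, ws_list)),
        "fc": list(map(float, fc_list)),
        "theta": list(map(float, theta_list)),
        "phi": list(map(float, phi_list)),
        "support_px": support_px,
    }
    return FilterBank(kernels=tuple(kernels), grid_spec=grid)


def default_filter_bank() -> FilterBank:
    """The 48-kernel default bank: 2 envelope widths x 3 frequencies x 4
    orientations x 2 phases, spanning lesion-scale structure for a ~9 px FWHM
    target (frequencies 1/32, 1/16 and 1/8 cycles/pixel)."""
    return build_filter_bank(
        ws_list=[8.0, 16.0],
        fc_list=[1.0 / 32.0, 1.0 / 16.0, 1.0 / 8.0],
        theta_list=[0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        phi_list=[0.0, np.pi / 2],
    )


def _embedded_kernel_rfft(kernel: GaborKernel, shape: tuple[int, int]) -> np.ndarray:
    """rfft2 of the kernel zero-padded to ``shape`` with its center at (0, 0)."""
    H, W = shape
    s = kernel.support_px
    if s > H or s > W:
        raise ValueError(f"kernel support {s} exceeds image shape {shape}")
    emb = np.zeros(shape)
    emb[:s, :s] = kernel.weights
    c = (s - 1) // 2
    emb = np.roll(emb, (-c, -c), axis=(0, 1))
    return np.fft.rfft2(emb)


class BankCorrelator:
    """Precomputed transform-domain correlator for one bank and image shape.

    Caches each kernel's padded spectrum so that filtering a stream of
    same-sized images costs one forward FFT per image plus one inverse FFT per
    requested kernel.
    """

    def __init__(self, bank: FilterBank, shape: tuple[int, int]):
        self.bank = bank
        self.shape = tuple(shape)
        self._kf = [np.conj(_embedded_kernel_rfft(k, self.shape)) for k in bank.kernels]

    def maps(self, image: np.ndarray, indices: Optional[Sequence[int]] = None) -> np.ndarray:
        """Correlation maps for the selected kernels; shape (len(indices), H, W)."""
        if image.shape != self.shape:
            raise ValueError(f"image shape {image.shape} != correlator shape {self.shape}")
        idx = range(len(self.bank)) if indices is None else indices
        imf = np.fft.rfft2(image)
        return np.stack([np.fft.irfft2(imf * self._kf[i], s=self.shape) for i in idx])


def apply_filter_bank(image: np.ndarray, bank: FilterBank) -> FeatureMapStack:
    """Periodic cross-correlation of ``image`` with every kernel in the bank.

    Each output map has the image's shape; map value at pixel p is the inner
    product of the kernel with the (periodically wrapped) image patch centered
    at p.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    maps = BankCorrelator(bank, image.shape).maps(image)
    return FeatureMapStack(maps=maps)


def features_at_location(
    stack: FeatureMapStack, location: tuple[int, int], feature_indices: Sequence[int]
) -> np.ndarray:
    """Feature vector: the selected maps' values at ``location`` (row, col)."""
    r, c = location
    _, H, W = stack.maps.shape
    if not (0 <= r < H and 0 <= c < W):
        raise ValueError(f"location {location} outside image of shape {(H, W)}")
    idx = np.asarray(feature_indices, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= len(stack)):
        raise ValueError("feature index out of range")
    return stack.maps[idx, r, c]
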