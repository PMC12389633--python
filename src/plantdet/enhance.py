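"""Image sharpening and enhancement operators.

The primary operator is unsharp masking: the image minus its Gaussian
blur is the detail layer, which is added back with intensity ``k``
(default 1.5), i.e. ``sharp = (1 + k) * I - k * B``.  Four comparison
enhancers (Laplacian, Sobel, high-boost, HSV value equalization) share
the same shape/clipping contract.  All spatial filtering uses reflect
borders; sharpening is applied independently per RGB channel.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

__all__ = [
    "SharpenParams", "EnhanceMethod", "gaussian_kernel", "gaussian_blur",
    "unsharp_mask", "apply_enhancement",
]

# 4-neighbour Laplacian and the Sobel pair, fixed comparator kernels
LAPLACIAN_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64)
SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
SOBEL_Y = SOBEL_X.T
HIGH_BOOST_A = 2.0


@dataclass(frozen=True)
class SharpenParams:
    """Unsharp-mask parameters: intensity ``k`` and Gaussian support."""

    k: float = 1.5
    sigma: float = 2.0
    kernel_size: int = 13

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ValueError(
                f"kernel_size must be odd and >= 3, got {self.kernel_size}")


class EnhanceMethod(str, Enum):
    UNSHARP_MASK = "unsharp_mask"
    LAPLACE = "laplace"
    SOBEL = "sobel"
    HIGH_BOOST = "high_boost"
    HSV_VALUE = "hsv_value"


def gaussian_kernel(sigma: float, kernel_size: int) -> np.ndarray:
    """Normalized 2-D Gaussian kernel of odd side ``kernel_size``."""
    half = kernel_size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    k2 = np.outer(g1, g1)
    return k2 / k2.sum()


def _as_float(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim not in (2, 3):
        raise ValueError(f"expected HxW or HxWxC image, got shape {img.shape}")
    return img.astype(np.float64)


def _finalize(out: np.ndarray, like: np.ndarray) -> np.ndarray:
    out = np.clip(out, 0.0, 255.0)
    if np.issubdtype(np.asarray(like).dtype, np.integer):
        return np.rint(out).astype(np.asarray(like).dtype)
    return out


def _filter_channels(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Correlate each channel with a (symmetric) kernel, reflect border."""
    f = _as_float(img)
    if f.ndim == 2:
        return ndimage.correlate(f, kernel, mode="reflect")
    out = np.empty_like(f)
    for c in range(f.shape[2]):
        out[:, :, c] = ndimage.correlate(f[:, :, c], kernel, mode="reflect")
    return out


def gaussian_blur(img: np.ndarray, params: SharpenParams = SharpenParams()) -> np.ndarray:
    """Low-frequency component: Gaussian-filtered image, same shape."""
    if np.asarray(img).size == 0:
        raise ValueError("empty image")
    kernel = gaussian_kernel(params.sigma, params.kernel_size)
    return _finalize(_filter_channels(img, kernel), img)


def unsharp_mask(img: np.ndarray, params: SharpenParams = SharpenParams(),
                 clip: bool = True) -> np.ndarray:
    """Sharpen: ``(1 + k) * I - k * blur(I)``, clipped to [0, 255].

    With ``clip=False`` the raw float linear combination is returned
    (useful for verifying the closed form exactly).
    """
    f = _as_float(img)
    kernel = gaussian_kernel(params.sigma, params.kernel_size)
    blurred = _filter_channels(f, kernel)
    sharp = f + params.k * (f - blurred)  # == (1 + k) * I - k * B
    if not clip:
        return sharp
    return _finalize(sharp, img)


def _laplace_sharpen(img: np.ndarray) -> np.ndarray:
    return _finalize(_as_float(img) - _filter_channels(img, LAPLACIAN_KERNEL), img)


def _sobel_sharpen(img: np.ndarray) -> np.ndarray:
    gx = _filter_channels(img, SOBEL_X)
    gy = _filter_channels(img, SOBEL_Y)
    return _finalize(_as_float(img) + np.hypot(gx, gy), img)


def _high_boost(img: np.ndarray, params: SharpenParams) -> np.ndarray:
    kernel = gaussian_kernel(params.sigma, params.kernel_size)
    blurred = _filter_channels(img, kernel)
    return _finalize(HIGH_BOOST_A * _as_float(img) - blurred, img)


def _hsv_value_equalize(img: np.ndarray) -> np.ndarray:
    from skimage import color, exposure

    f = _as_float(img)
    if f.ndim != 3 or f.shape[2] != 3:
        raise ValueError("hsv_value enhancement requires an RGB image")
    hsv = color.rgb2hsv(f / 255.0)
    hsv[:, :, 2] = exposure.equalize_hist(hsv[:, :, 2])
    rgb = color.hsv2rgb(hsv) * 255.0
    return _finalize(rgb, img)


def apply_enhancement(img: np.ndarray, method: EnhanceMethod | str,
                      params: SharpenParams = SharpenParams()) -> np.ndarray:
    """Dispatch to the enhancer named by ``method``; shape is preserved."""
    try:
        method = EnhanceMethod(method)
    except ValueError:
        raise ValueError(
            f"unknown enhancement method {method!r}; expected one of "
            f"{[m.value for m in EnhanceMethod]}") from None
    if method is EnhanceMethod.UNSHARP_MASK:
        return unsharp_mask(img, params)
    if method is EnhanceMethod.LAPLACE:
        return _laplace_sharpen(img)
    if method is EnhanceMethod.SOBEL:
        return _sobel_sharpen(img)
    if method is EnhanceMethod.HIGH_BOOST:
        return _high_boost(img, params)
    return _hsv_value_equalize(img)
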