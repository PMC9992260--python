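"""Centred Fourier operators and coil algebra for multi-coil MRI.

Conventions
-----------
* Arrays are complex and laid out ``[..., coils, h, w]`` (coil axis third
  from the end where present); the phase-encoding direction is the **last**
  axis.
* ``fft2c``/``ifft2c`` are centred (DC at the array centre) and orthonormal,
  implemented as shift → transform → shift, so Parseval holds exactly and
  undersampling masks with a fully sampled centre act on the middle of the
  array.
* Coil sensitivities are normalised to pixelwise unit energy,
  ``sum_i conj(S_i) S_i = 1``, which makes coil expansion followed by coil
  reduction the identity on single complex images.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "fft2c",
    "ifft2c",
    "coil_reduce",
    "coil_expand",
    "rss",
    "normalize_sensitivities",
    "crop_quadratic",
    "complex_to_channels",
    "channels_to_complex",
]


def _check_2d(x: np.ndarray, name: str) -> None:
    if x.ndim < 2:
        raise ValueError(f"{name} needs at least 2 trailing spatial dims, got shape {x.shape}")


def fft2c(image: np.ndarray) -> np.ndarray:
    """Centred orthonormal 2-D FFT over the last two axes."""
    _check_2d(image, "image")
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(image, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(kspace: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    _check_2d(kspace, "kspace")
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(kspace, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def coil_reduce(ku: np.ndarray, sens: np.ndarray) -> np.ndarray:
    """Fold multi-coil k-space to a single complex image.

    Computes ``sum_i ifft2c(ku_i) * conj(S_i)`` over the coil axis (third
    from the end).  Linear in ``ku``.
    """
    if ku.shape[-3] != sens.shape[-3]:
        raise ValueError(
            f"coil count mismatch: kspace has {ku.shape[-3]}, "
            f"sensitivities have {sens.shape[-3]}"
        )
    return (ifft2c(ku) * np.conj(sens)).sum(axis=-3)


def coil_expand(image: np.ndarray, sens: np.ndarray) -> np.ndarray:
    """Project a single complex image onto each coil: coil i is ``image * S_i``."""
    if image.shape[-2:] != sens.shape[-2:]:
        raise ValueError(
            f"spatial shape mismatch: image {image.shape[-2:]} vs "
            f"sensitivities {sens.shape[-2:]}"
        )
    return image[..., np.newaxis, :, :] * sens


def rss(coil_images: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares magnitude over the coil axis."""
    if coil_images.ndim < 3 or coil_images.shape[-3] < 1:
        raise ValueError(f"expected [..., c, h, w] with c >= 1, got {coil_images.shape}")
    return np.sqrt((np.abs(coil_images) ** 2).sum(axis=-3))


def normalize_sensitivities(raw: np.ndarray, eps: float = 1e-12,
                            return_valid: bool = False):
    """Scale coil maps to pixelwise unit total energy.

    Divides by ``sqrt(sum_i |S_i|^2 + eps)``; the relative phase and
    magnitude ratio between coils at each pixel is preserved.  Pixels with
    (near) zero total energy come out (near) zero rather than NaN; with
    ``return_valid=True`` a boolean map of pixels with energy above ``eps``
    is returned alongside.
    """
    if not np.all(np.isfinite(raw)):
        raise ValueError("sensitivity maps must be finite")
    energy = (np.abs(raw) ** 2).sum(axis=-3, keepdims=True)
    sens = raw / np.sqrt(energy + eps)
    if return_valid:
        return sens, (energy[..., 0, :, :] > eps)
    return sens


def crop_quadratic(image: np.ndarray, target: int) -> np.ndarray:
    """Centred square crop of side ``target`` on the last two dims.

    Start offsets follow ``floor((dim - target) / 2)``.
    """
    h, w = image.shape[-2:]
    if target > h or target > w:
        raise ValueError(f"crop target {target} exceeds image dims {h}×{w}")
    top = (h - target) // 2
    left = (w - target) // 2
    return image[..., top:top + target, left:left + target]


def complex_to_channels(x: np.ndarray) -> np.ndarray:
    """Complex ``[..., h, w]`` → real ``[..., 2, h, w]`` (real, imaginary)."""
    return np.stack([x.real, x.imag], axis=-3).astype(np.float32)


def channels_to_complex(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`complex_to_channels`; channel 0 real, channel 1 imag."""
    if x.shape[-3] != 2:
        raise ValueError(f"expected a (real, imaginary) pair axis, got {x.shape}")
    return x[..., 0, :, :] + 1j * x[..., 1, :, :]
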