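"""Reconstruction quality metrics and the SSIM + L1 training loss.

SSIM uses an 11×11 Gaussian window (σ = 1.5, truncated at radius 5) with
K1 = 0.01, K2 = 0.03 and population (non-sample) covariance normalisation,
computed over the interior where the window fits entirely; ``data_range``
is conventionally the maximum of the reference volume.  NMSE and PSNR are
computed per volume.  The training loss is the equally weighted sum of
(1 − SSIM) and the mean absolute error, so its minimum is 0 at equality.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import correlate1d

from . import nn
from .nn import Tensor

__all__ = [
    "ssim",
    "nmse",
    "psnr",
    "training_loss",
    "ssim_tensor",
    "PSNR_CAP",
]

PSNR_CAP = 100.0  # dB sentinel for exact matches

_K1 = 0.01
_K2 = 0.03
_SIGMA = 1.5
_TRUNCATE = 3.5


def _gaussian_kernel1d(dtype=np.float64) -> np.ndarray:
    radius = int(_TRUNCATE * _SIGMA + 0.5)
    x = np.arange(-radius, radius + 1, dtype=dtype)
    k = np.exp(-0.5 * (x / _SIGMA) ** 2)
    return k / k.sum()


def _filter_valid(img: np.ndarray) -> np.ndarray:
    """Separable Gaussian filtering, cropped to the fully valid interior."""
    k = _gaussian_kernel1d(img.dtype if img.dtype.kind == "f" else np.float64)
    r = (k.size - 1) // 2
    out = correlate1d(correlate1d(img, k, axis=0), k, axis=1)
    return out[r:-r, r:-r]


def ssim(x: np.ndarray, y: np.ndarray, data_range: float) -> float:
    """Gaussian-weighted structural similarity of two magnitude images."""
    x = np.asarray(x, np.float64)
    y = np.asarray(y, np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if data_range <= 0:
        raise ValueError(f"data_range must be positive, got {data_range}")
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    ux = _filter_valid(x)
    uy = _filter_valid(y)
    uxx = _filter_valid(x * x)
    uyy = _filter_valid(y * y)
    uxy = _filter_valid(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cxy = uxy - ux * uy
    s = ((2 * ux * uy + c1) * (2 * cxy + c2)) / (
        (ux * ux + uy * uy + c1) * (vx + vy + c2)
    )
    return float(s.mean())


def nmse(pred: np.ndarray, ref: np.ndarray) -> float:
    """Squared error normalised by the reference energy."""
    pred = np.asarray(pred, np.float64)
    ref = np.asarray(ref, np.float64)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    denom = float((ref ** 2).sum())
    if denom == 0.0:
        raise ValueError("reference is identically zero")
    return float(((pred - ref) ** 2).sum() / denom)


def psnr(pred: np.ndarray, ref: np.ndarray, data_range: float) -> float:
    """Peak signal-to-noise ratio in dB, capped for exact matches."""
    pred = np.asarray(pred, np.float64)
    ref = np.asarray(ref, np.float64)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    mse = float(((pred - ref) ** 2).mean())
    if mse == 0.0:
        return PSNR_CAP
    return min(PSNR_CAP, 20.0 * np.log10(data_range) - 10.0 * np.log10(mse))


# -- differentiable versions ----------------------------------------------

def _gauss_conv(x: Tensor, kernel: Tensor) -> Tensor:
    return nn.conv2d(x, kernel, padding=0)


def ssim_tensor(x: Tensor, y: Tensor | np.ndarray, data_range: float) -> Tensor:
    """Differentiable Gaussian-windowed SSIM on [h, w] tensors."""
    if not isinstance(y, Tensor):
        y = Tensor(np.asarray(y, dtype=x.dtype))
    k1 = _gaussian_kernel1d(np.dtype(x.dtype))
    k2d = np.outer(k1, k1).reshape(1, 1, k1.size, k1.size)
    kernel = Tensor(k2d.astype(x.dtype))
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    h, w = x.shape[-2], x.shape[-1]
    x4 = x.reshape(1, 1, h, w)
    y4 = y.reshape(1, 1, h, w)
    ux = _gauss_conv(x4, kernel)
    uy = _gauss_conv(y4, kernel)
    vx = _gauss_conv(x4 * x4, kernel) - ux * ux
    vy = _gauss_conv(y4 * y4, kernel) - uy * uy
    cxy = _gauss_conv(x4 * y4, kernel) - ux * uy
    num = (ux * uy * 2.0 + c1) * (cxy * 2.0 + c2)
    den = (ux * ux + uy * uy + c1) * (vx + vy + c2)
    return (num / den).mean()


def training_loss(pred: Tensor, ref: np.ndarray | Tensor,
                  data_range: float) -> Tensor:
    """(1 − SSIM) + mean |pred − ref|, equally weighted."""
    ref_t = ref if isinstance(ref, Tensor) else Tensor(np.asarray(ref, dtype=pred.dtype))
    l1 = (pred - ref_t).abs().mean()
    return (1.0 - ssim_tensor(pred, ref_t, data_range)) + l1
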