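"""Structural similarity (SSIM) with an analytic gradient.

Single implementation used both as an image-quality metric and as the
training loss (``1 - mean SSIM``).  Local statistics are computed with a
Gaussian window (default 11x11, sigma 1.5, the classic choice), 'valid'
windows only, dynamic range 1.0 and the standard stabilizing constants
C1 = (0.01 L)^2, C2 = (0.03 L)^2.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

__all__ = ["gaussian_window", "ssim", "ssim_map", "ssim_and_grad"]


def gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    if size < 3 or size % 2 == 0:
        raise ValueError("window size must be odd and >= 3")
    r = np.arange(size) - size // 2
    g = np.exp(-(r**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _conv_valid(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    return fftconvolve(x, k, mode="valid")


def _conv_valid_adjoint(g: np.ndarray, k: np.ndarray) -> np.ndarray:
    # Adjoint of 'valid' convolution with a symmetric kernel: 'full' convolution.
    return fftconvolve(g, k[::-1, ::-1], mode="full")


def _stats(x, y, window):
    mu_x = _conv_valid(x, window)
    mu_y = _conv_valid(y, window)
    exx = _conv_valid(x * x, window)
    eyy = _conv_valid(y * y, window)
    exy = _conv_valid(x * y, window)
    var_x = exx - mu_x**2
    var_y = eyy - mu_y**2
    cov = exy - mu_x * mu_y
    return mu_x, mu_y, var_x, var_y, cov


def ssim_map(
    x: np.ndarray,
    y: np.ndarray,
    window_size: int = 11,
    sigma: float = 1.5,
    data_range: float = 1.0,
) -> np.ndarray:
    """Local SSIM map over all 'valid' window positions of two 2D images."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 2:
        raise ValueError("ssim_map expects 2D images")
    if min(x.shape) < window_size:
        raise ValueError("image smaller than SSIM window")
    w = gaussian_window(window_size, sigma)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_x, mu_y, var_x, var_y, cov = _stats(x, y, w)
    a1 = 2 * mu_x * mu_y + c1
    a2 = 2 * cov + c2
    b1 = mu_x**2 + mu_y**2 + c1
    b2 = var_x + var_y + c2
    return (a1 * a2) / (b1 * b2)


def ssim(x, y, window_size: int = 11, sigma: float = 1.5, data_range: float = 1.0) -> float:
    """Mean SSIM of two 2D images (or mean over leading axes of a stack)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim > 2:
        return float(
            np.mean([
                ssim(a, b, window_size, sigma, data_range)
                for a, b in zip(x.reshape(-1, *x.shape[-2:]), y.reshape(-1, *y.shape[-2:]))
            ])
        )
    return float(np.mean(ssim_map(x, y, window_size, sigma, data_range)))


def ssim_and_grad(
    x: np.ndarray,
    y: np.ndarray,
    window_size: int = 11,
    sigma: float = 1.5,
    data_range: float = 1.0,
):
    """Mean SSIM and its gradient with respect to ``x``.

    Returns ``(mssim, grad)`` where ``grad[i, j] = d mssim / d x[i, j]``,
    obtained by chaining the window convolutions backwards.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("ssim_and_grad expects two equal-shape 2D images")
    w = gaussian_window(window_size, sigma)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_x, mu_y, var_x, var_y, cov = _stats(x, y, w)
    a1 = 2 * mu_x * mu_y + c1
    a2 = 2 * cov + c2
    b1 = mu_x**2 + mu_y**2 + c1
    b2 = var_x + var_y + c2
    s = (a1 * a2) / (b1 * b2)
    mssim = float(np.mean(s))

    # d(mean S)/dS = 1/n per window; then S = (a1 a2)/(b1 b2).
    n = s.size
    g_s = np.full_like(s, 1.0 / n)
    g_a1 = g_s * a2 / (b1 * b2)
    g_a2 = g_s * a1 / (b1 * b2)
    g_b1 = -g_s * s / b1
    g_b2 = -g_s * s / b2
    # a1 = 2 mu_x mu_y + c1 ; b1 = mu_x^2 + mu_y^2 + c1
    g_mu_x = 2 * mu_y * g_a1 + 2 * mu_x * g_b1
    # a2 = 2 cov + c2 ; b2 = var_x + var_y + c2
    g_cov = 2 * g_a2
    g_var_x = g_b2
    # var_x = exx - mu_x^2 ; cov = exy - mu_x mu_y
    g_exx = g_var_x
    g_exy = g_cov
    g_mu_x = g_mu_x - 2 * mu_x * g_var_x - mu_y * g_cov
    # Back through the convolutions: mu_x = w*x, exx = w*(x^2), exy = w*(x y).
    grad = (
        _conv_valid_adjoint(g_mu_x, w)
        + 2 * x * _conv_valid_adjoint(g_exx, w)
        + y * _conv_valid_adjoint(g_exy, w)
    )
    return mssim, grad
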