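"""Kaiser-Bessel gridding primitives.

Non-Cartesian k-space samples are related to a DC-centered oversampled
Cartesian grid by a separable Kaiser-Bessel interpolation kernel:

* ``kb_spread``   : samples -> grid (the gridding / adjoint operation)
* ``kb_interpolate``: grid -> samples (the forward interpolation)

These two are exact matrix transposes of one another.  On top of them,
``nufft_forward`` / ``nufft_adjoint`` implement type-2 / type-1 non-uniform
Fourier transforms for images of size N^3 with oversampling ``os``:

    S(k) = sum_n f(n) exp(-2*pi*i k.n / N),   n in [-N/2, N/2)^3,
    k in cycles/FOV; the oversampled-grid coordinate is u = os * k.

Kernel shape parameter beta follows the standard width/oversampling-optimal
(Beatty) formula; the image-domain apodization of the kernel is divided out
analytically.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "kb_beta",
    "kb_kernel",
    "kb_apodization",
    "kb_spread",
    "kb_interpolate",
    "nufft_forward",
    "nufft_adjoint",
    "GriddingConfig",
]

from dataclasses import dataclass


@dataclass(frozen=True)
class GriddingConfig:
    """Gridding parameters: oversampling ratio, kernel width (grid cells)."""

    oversampling: float = 2.0
    kernel_width: int = 4
    kernel_beta: float | None = None

    def __post_init__(self):
        if self.oversampling < 1:
            raise ValueError("oversampling must be >= 1")
        if self.kernel_width < 2:
            raise ValueError("kernel_width must be >= 2")

    @property
    def beta(self) -> float:
        if self.kernel_beta is not None:
            return self.kernel_beta
        return kb_beta(self.kernel_width, self.oversampling)


def kb_beta(width: int, oversampling: float) -> float:
    """Optimal Kaiser-Bessel shape parameter for given width/oversampling."""
    os = oversampling
    return math.pi * math.sqrt((width / os) ** 2 * (os - 0.5) ** 2 - 0.8)


def kb_kernel(kappa, width: int, beta: float):
    """Kernel value at offset ``kappa`` (grid cells); normalized to unit area
    in the sense integral C = sinh(beta)/beta, matching ``kb_apodization``."""
    kappa = np.asarray(kappa, dtype=float)
    t = 1.0 - (2.0 * kappa / width) ** 2
    inside = t > 0
    out = np.zeros_like(kappa)
    out[inside] = np.i0(beta * np.sqrt(t[inside])) / width
    return out


def kb_apodization(x, width: int, beta: float):
    """Image-domain response c(x) of the kernel; x in cycles per grid cell.

    c(x) = sin(sqrt((pi W x)^2 - beta^2)) / sqrt((pi W x)^2 - beta^2),
    evaluated with complex square roots so the sinh branch is handled.
    """
    x = np.asarray(x, dtype=float)
    z = np.sqrt((np.pi * width * x) ** 2 - beta ** 2 + 0j)
    out = np.real(np.sinc(z / np.pi))  # sin(z)/z with the z->0 limit
    return out


def _neighbor_indices_weights(u, grid_size: int, width: int, beta: float):
    """Per-axis neighbor grid indices (mod grid_size) and kernel weights.

    u : (n,) continuous grid coordinates with DC at index grid_size/2.
    Returns (idx, w) each of shape (n, width).
    """
    u = np.asarray(u, dtype=float)
    base = np.floor(u).astype(np.int64) - width // 2 + 1
    offs = np.arange(width)
    m = base[:, None] + offs[None, :]
    w = kb_kernel(m - u[:, None], width, beta)
    return np.mod(m, grid_size), w


def _axis_terms(coords, grid_size: int, cfg: GriddingConfig):
    """Neighbor indices/weights per axis for (n, 3) oversampled coordinates."""
    half = grid_size / 2
    if np.any(np.abs(coords) > half):
        raise ValueError("sample outside the oversampled grid bounds")
    u = coords + half  # array coordinates, DC at index grid_size/2
    terms = []
    for ax in range(3):
        terms.append(_neighbor_indices_weights(u[:, ax], grid_size, cfg.kernel_width, cfg.beta))
    return terms


def kb_spread(values, coords, grid_size: int, cfg: GriddingConfig) -> np.ndarray:
    """Grid (spread) complex samples onto a grid_size^3 DC-centered grid.

    coords : (n, 3) oversampled-grid k-coordinates u = os * k, DC at 0.
    Exact adjoint of ``kb_interpolate``.
    """
    values = np.asarray(values).ravel()
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    (ix, wx), (iy, wy), (iz, wz) = _axis_terms(coords, grid_size, cfg)
    W = cfg.kernel_width
    M = grid_size
    flat_re = np.zeros(M ** 3)
    flat_im = np.zeros(M ** 3)
    vre, vim = values.real, values.imag
    for a in range(W):
        ia = ix[:, a] * (M * M)
        for b in range(W):
            iab = ia + iy[:, b] * M
            wab = wx[:, a] * wy[:, b]
            for c in range(W):
                idx = iab + iz[:, c]
                w = wab * wz[:, c]
                flat_re += np.bincount(idx, weights=vre * w, minlength=M ** 3)
                flat_im += np.bincount(idx, weights=vim * w, minlength=M ** 3)
    return (flat_re + 1j * flat_im).reshape(M, M, M)


def kb_interpolate(grid: np.ndarray, coords, cfg: GriddingConfig) -> np.ndarray:
    """Interpolate a grid_size^3 DC-centered grid at (n, 3) coordinates."""
    M = grid.shape[0]
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    (ix, wx), (iy, wy), (iz, wz) = _axis_terms(coords, M, cfg)
    W = cfg.kernel_width
    flat = grid.ravel()
    out = np.zeros(coords.shape[0], dtype=complex)
    for a in range(W):
        ia = ix[:, a] * (M * M)
        for b in range(W):
            iab = ia + iy[:, b] * M
            wab = wx[:, a] * wy[:, b]
            for c in range(W):
                out += flat[iab + iz[:, c]] * (wab * wz[:, c])
    return out


def _apodization_3d(n: int, grid_size: int, cfg: GriddingConfig) -> np.ndarray:
    """Separable c(x) over the central n^3 image region of an M^3 grid."""
    idx = np.arange(n) - n // 2
    c1 = kb_apodization(idx / grid_size, cfg.kernel_width, cfg.beta)
    return c1[:, None, None] * c1[None, :, None] * c1[None, None, :]


def nufft_forward(image: np.ndarray, k_coords, cfg: GriddingConfig | None = None) -> np.ndarray:
    """Type-2 NUFFT: evaluate the DFT of an N^3 image at (n, 3) k-coordinates
    (cycles/FOV).  Image voxel n runs over [-N/2, N/2)^3 (array index n+N/2)."""
    cfg = cfg or GriddingConfig()
    N = image.shape[0]
    M = int(round(cfg.oversampling * N))
    padded = np.zeros((M, M, M), dtype=complex)
    lo = M // 2 - N // 2
    padded[lo:lo + N, lo:lo + N, lo:lo + N] = image / _apodization_3d(N, M, cfg)
    F = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(padded)))
    u = np.asarray(k_coords, dtype=float).reshape(-1, 3) * (M / N)
    return kb_interpolate(F, u, cfg)


def nufft_adjoint(values, k_coords, n: int, cfg: GriddingConfig | None = None,
                  deapodize: bool = True) -> np.ndarray:
    """Type-1 NUFFT (adjoint): sum_j v_j exp(+2*pi*i k_j.n / N) on an N^3 grid.

    Implements gridding -> centered inverse FFT -> deapodization -> crop.
    Density compensation of ``values`` is the caller's responsibility.
    """
    cfg = cfg or GriddingConfig()
    M = int(round(cfg.oversampling * n))
    u = np.asarray(k_coords, dtype=float).reshape(-1, 3) * (M / n)
    G = kb_spread(values, u, M, cfg)
    g = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(G))) * (M ** 3)
    lo = M // 2 - n // 2
    g = g[lo:lo + n, lo:lo + n, lo:lo + n]
    if deapodize:
        g = g / _apodization_3d(n, M, cfg)
    return g
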