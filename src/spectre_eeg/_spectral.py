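"""Pseudo-spectral primitives on periodic grids.

All spatial derivatives in the package go through this module: fields are
transformed with the FFT, multiplied by (i k) factors, and transformed back.
The grid is treated as periodic in every axis; `spacing` is the physical size
of one voxel per axis, so wavenumbers are angular (2*pi*fftfreq/spacing).
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft


def wavenumbers(shape, spacing):
    """Angular wavenumber arrays, one broadcastable array per axis."""
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (len(shape),))
    ks = []
    for ax, (n, d) in enumerate(zip(shape, spacing)):
        k = 2.0 * np.pi * np.fft.fftfreq(n, d=d)
        sh = [1] * len(shape)
        sh[ax] = n
        ks.append(k.reshape(sh))
    return ks


def k_squared(shape, spacing):
    """|k|^2 on the full grid (broadcast sum of per-axis squares)."""
    ks = wavenumbers(shape, spacing)
    k2 = np.zeros(shape, dtype=float)
    for k in ks:
        k2 = k2 + k**2
    return k2


def gradient(f, spacing):
    """Spectral gradient: list of d(f)/dx_i arrays (complex preserved)."""
    f = np.asarray(f)
    ks = wavenumbers(f.shape, spacing)
    fh = sfft.fftn(f)
    out = []
    for k in ks:
        g = sfft.ifftn(1j * k * fh)
        out.append(g if np.iscomplexobj(f) else g.real)
    return out


def laplacian(f, spacing):
    f = np.asarray(f)
    k2 = k_squared(f.shape, spacing)
    g = sfft.ifftn(-k2 * sfft.fftn(f))
    return g if np.iscomplexobj(f) else g.real


def invert_laplacian(f, spacing):
    """Solve lap(phi) = f on the periodic grid.

    The DC (k=0) mode is set to zero: the potential is defined only up to a
    constant, and the compatibility condition requires the source mean to be
    dropped.  Total (never-failing) operation.
    """
    f = np.asarray(f)
    k2 = k_squared(f.shape, spacing)
    fh = sfft.fftn(f)
    with np.errstate(divide="ignore", invalid="ignore"):
        ph = fh / (-k2)
    ph[(0,) * f.ndim] = 0.0
    g = sfft.ifftn(ph)
    return g if np.iscomplexobj(f) else g.real


def hessian_apply(f, spacing):
    """All second derivatives d2 f / dx_i dx_j as a dict {(i, j): array}, i<=j."""
    f = np.asarray(f)
    ks = wavenumbers(f.shape, spacing)
    fh = sfft.fftn(f)
    out = {}
    for i in range(f.ndim):
        for j in range(i, f.ndim):
            g = sfft.ifftn(-(ks[i] * ks[j]) * fh)
            out[(i, j)] = g if np.iscomplexobj(f) else g.real
    return out


def cosine_taper(shape, width):
    """Separable raised-cosine window: 1 in the interior, ->0 over `width`
    voxels at each edge of each axis.  Used to apodize coefficient fields so
    the periodic wrap-around of the FFT does not couple opposite faces."""
    w = np.ones(shape, dtype=float)
    for ax, n in enumerate(shape):
        prof = np.ones(n)
        m = int(min(width, n // 2))
        if m > 0:
            ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(m) + 0.5) / m))
            prof[:m] = ramp
            prof[-m:] = ramp[::-1]
        sh = [1] * len(shape)
        sh[ax] = n
        w = w * prof.reshape(sh)
    return w
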