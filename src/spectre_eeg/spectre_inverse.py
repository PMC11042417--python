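"""Frequency-domain iterative pseudo-spectral EEG inversion.

Transforming the wave equation to the frequency domain gives an operator
equation  L phi_w = R phi_w  with L the Laplacian and R a first/second-order
operator weighted by the tissue-property gradients:

    R = (sbar + i w eps) / (sbar^2 + w^2 eps^2) *
        [ i w (d_i eps) d_i  -  (d_i Sigma_ij) d_j  -  (Sigma_ij - sbar d_ij) d_i d_j ]

where Sigma_ij = sigma_ij/eps0 (1/s), eps is the relative-permittivity
field, sbar = Tr Sigma / 3, and w is the angular frequency.  The three
bracketed terms are sourced respectively by permittivity gradients (the
WM/GM interface), conductivity gradients (the GM/CSF boundary), and
conductivity anisotropy.  The solution is accumulated iteratively:

    phi^(k) = L^-1 R phi^(k-1),      phi_w ~ alpha * sum_k phi^(k)

seeded from the electrode data and scaled at the end by a complex
least-squares fit to the measured coefficients.  All spatial derivatives are
pseudo-spectral on the periodic grid; the overall scale and phase of the
reconstruction are fixed entirely by the sensor fit, so the result is
invariant to any global constant in the property nondimensionalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from . import _spectral
from .forward_sim import EEGRecording
from .tissue_model import PropertyFields, TissueGrid
from .wetcow_dynamics import WaveField

logger = logging.getLogger(__name__)

_FWHM_TO_SIGMA = 1.0 / 2.3548200450309493


class InverseError(ValueError):
    pass


class DivergenceError(RuntimeError):
    """The operator iteration is growing without bound."""


@dataclass
class BandSpec:
    """Frequency band [f_lo, f_hi) in Hz; the DC bin is always excluded."""

    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not (0 <= self.f_lo < self.f_hi):
            raise InverseError("need 0 <= f_lo < f_hi")


@dataclass
class ReconstructionConfig:
    K: int = 10  # iteration count
    tol: float = 1e-6  # relative-change early stop on the accumulant
    seed_splat_fwhm: float = 3.0  # voxels
    divergence_ratio: float = 1e6

    def __post_init__(self):
        if self.K < 0:
            raise InverseError("K must be >= 0")
        if self.tol <= 0:
            raise InverseError("tol must be > 0")


@dataclass
class SpectralPotential:
    """Complex volumetric potential per retained frequency bin."""

    bins_hz: np.ndarray
    phi: np.ndarray  # (n_bins, *grid), complex
    grid: TissueGrid
    residual_history: Optional[List[np.ndarray]] = None

    def __post_init__(self):
        self.bins_hz = np.asarray(self.bins_hz, dtype=float)
        self.phi = np.asarray(self.phi)
        if self.phi.shape[0] != len(self.bins_hz):
            raise InverseError("one volume per frequency bin required")
        if not np.all(np.isfinite(self.phi.real)):
            raise InverseError("non-finite spectral potential")


def band_transform(rec: EEGRecording, band: BandSpec):
    """Per-channel DFT coefficients for the bins inside the band.

    A plain (rectangular-window) DFT scaled by 2/N, so a unit sinusoid
    aligned with a bin yields a unit-magnitude coefficient.  Off-bin
    components leak as usual for an unwindowed transform; recordings are
    assumed long enough that band edges contain at least one bin.

    Returns
    -------
    freqs : (n_bins,) Hz
    coeffs : (n_channels, n_bins) complex
    """
    if band.f_hi > rec.fs / 2:
        raise InverseError("band exceeds Nyquist")
    min_dur = 2.0 / (band.f_hi - band.f_lo)
    if rec.duration < min_dur:
        raise InverseError(
            f"recording of {rec.duration:.3g} s too short to resolve a "
            f"{band.f_lo}-{band.f_hi} Hz band (need > {min_dur:.3g} s)"
        )
    n = rec.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.fs)
    sel = (freqs >= band.f_lo) & (freqs < band.f_hi) & (freqs > 0)
    if not np.any(sel):
        raise InverseError("band contains no DFT bins")
    coeffs = np.fft.rfft(rec.data, axis=1)[:, sel] * (2.0 / n)
    return freqs[sel], coeffs


def invert_laplacian(f: np.ndarray, spacing=1.0) -> np.ndarray:
    """Periodic pseudo-spectral inverse Laplacian (DC mode gauged to zero)."""
    return _spectral.invert_laplacian(f, spacing)


def _trilinear(volume: np.ndarray, vox: np.ndarray) -> np.ndarray:
    """Trilinear gather of a (possibly complex) volume at fractional voxels."""
    shape = np.asarray(volume.shape)
    base = np.floor(np.clip(vox, 0, shape - 1 - 1e-9)).astype(int)
    frac = vox - base
    out = np.zeros(len(vox), dtype=volume.dtype)
    for corner in range(8):
        off = np.array([(corner >> a) & 1 for a in range(3)])
        w = np.prod(np.where(off, frac, 1.0 - frac), axis=1)
        idx = np.minimum(base + off, shape - 1)
        out += w * volume[idx[:, 0], idx[:, 1], idx[:, 2]]
    return out


def _splat(coeffs: np.ndarray, vox: np.ndarray, shape, fwhm: float) -> np.ndarray:
    """Scatter complex channel coefficients as Gaussian blobs at electrode
    voxels (trilinear scatter followed by one Gaussian filter pass)."""
    vol = np.zeros(shape, dtype=complex)
    base = np.floor(vox).astype(int)
    frac = vox - base
    shape_arr = np.asarray(shape)
    for corner in range(8):
        off = np.array([(corner >> a) & 1 for a in range(3)])
        w = np.prod(np.where(off, frac, 1.0 - frac), axis=1)
        idx = np.minimum(base + off, shape_arr - 1)
        np.add.at(vol, (idx[:, 0], idx[:, 1], idx[:, 2]), w * coeffs)
    sig = fwhm * _FWHM_TO_SIGMA
    return ndimage.gaussian_filter(vol.real, sig, mode="wrap") + 1j * ndimage.gaussian_filter(
        vol.imag, sig, mode="wrap"
    )


def _div_sigma_eps0(fields: PropertyFields) -> np.ndarray:
    """d_i (Sigma_ij * eps_rel): divergence of the eps0-scaled conductivity,
    cached on the PropertyFields instance."""
    cache = getattr(fields, "_inverse_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(fields, "_inverse_cache", cache)
    if "div_sig" not in cache:
        spacing = fields.spacing_m
        sig_t = fields.Sigma * fields.eps_rel[..., None, None]
        div = np.empty(fields.grid.shape + (3,))
        for j in range(3):
            acc = np.zeros(fields.grid.shape)
            for i in range(3):
                acc += _spectral.gradient(sig_t[..., i, j], spacing)[i]
            div[..., j] = acc
        cache["div_sig"] = div
        cache["grad_eps"] = _spectral.gradient(fields.eps_rel, spacing)
        cache["sbar"] = (
            np.trace(sig_t, axis1=-2, axis2=-1) / 3.0
        )
    return cache["div_sig"]


def apply_R(phi: np.ndarray, fields: PropertyFields, omega: float) -> np.ndarray:
    """Apply the frequency-domain tissue operator R to a potential volume.

    omega is angular (rad/s).  For homogeneous isotropic fields all three
    terms vanish identically.
    """
    phi = np.asarray(phi, dtype=complex)
    if phi.shape != fields.grid.shape:
        raise InverseError("phi and property fields must share the grid")
    div_sig = _div_sigma_eps0(fields)
    cache = fields._inverse_cache
    grad_eps = cache["grad_eps"]
    sbar = cache["sbar"]
    eps = fields.eps_rel
    denom = sbar**2 + omega**2 * eps**2
    if np.any(denom == 0):
        raise InverseError(
            "singular prefactor: omega = 0 with zero conductivity present"
        )
    P = (sbar + 1j * omega * eps) / denom

    spacing = fields.spacing_m
    gphi = _spectral.gradient(phi, spacing)

    bracket = np.zeros(phi.shape, dtype=complex)
    for i in range(3):
        bracket += 1j * omega * grad_eps[i] * gphi[i]
        bracket -= div_sig[..., i] * gphi[i]
    if not fields.isotropic:
        sig_t = fields.Sigma * eps[..., None, None]
        hess = _spectral.hessian_apply(phi, spacing)
        for i in range(3):
            for j in range(3):
                dev = sig_t[..., i, j] - (sbar if i == j else 0.0)
                h = hess[(i, j) if i <= j else (j, i)]
                bracket -= dev * h
    return P * bracket


def reconstruct_band(
    rec: EEGRecording,
    grid: TissueGrid,
    fields: PropertyFields,
    band: BandSpec,
    cfg: Optional[ReconstructionConfig] = None,
) -> SpectralPotential:
    """Reconstruct the complex volumetric potential for every bin in a band.

    Per bin: (1) the channels' complex DFT coefficients are splatted as
    Gaussians at their electrode voxels and the Laplacian is inverted to
    give the seed phi^(0); (2) the operator iteration phi^(k) = L^-1 R
    phi^(k-1) is accumulated for up to K steps (early stop when the
    accumulant's relative change drops below tol, hard error if it grows by
    more than the divergence ratio); (3) a single complex scalar alpha is
    fit by least squares so that alpha*phi~ matches the measured
    coefficients at the electrodes.
    """
    cfg = cfg or ReconstructionConfig()
    freqs, coeffs = band_transform(rec, band)
    vox = grid.world_to_voxel(rec.sensors.positions)
    shape_arr = np.asarray(grid.shape)
    if np.any(vox < 0) or np.any(vox > shape_arr - 1):
        raise InverseError("electrodes fall outside the labeled grid")
    spacing = fields.spacing_m

    out = np.empty((len(freqs), *grid.shape), dtype=complex)
    history: List[np.ndarray] = []
    for b, f_hz in enumerate(freqs):
        omega = 2.0 * np.pi * f_hz
        d = coeffs[:, b]
        seed = _splat(d, vox, grid.shape, cfg.seed_splat_fwhm)
        phi = _spectral.invert_laplacian(seed, spacing)
        accum = phi.copy()
        seed_norm = np.linalg.norm(phi)
        residuals = [_sensor_residual(accum, vox, d)]
        if seed_norm > 0:
            for k in range(1, cfg.K + 1):
                phi = _spectral.invert_laplacian(
                    apply_R(phi, fields, omega), spacing
                )
                accum += phi
                residuals.append(_sensor_residual(accum, vox, d))
                rel = np.linalg.norm(phi) / max(np.linalg.norm(accum), 1e-300)
                if np.linalg.norm(accum) > cfg.divergence_ratio * seed_norm:
                    raise DivergenceError(
                        f"accumulant grew beyond {cfg.divergence_ratio:g}x the "
                        "seed norm; reduce K or smooth the property fields"
                    )
                if rel < cfg.tol:
                    break
        alpha = _fit_alpha(accum, vox, d)
        logger.info(
            "bin %.3g Hz: %d iterations, residuals %s",
            f_hz,
            len(residuals) - 1,
            np.array2string(np.asarray(residuals), precision=3),
        )
        history.append(np.asarray(residuals))
        out[b] = alpha * accum
    return SpectralPotential(
        bins_hz=freqs, phi=out, grid=grid, residual_history=history
    )


def _fit_alpha(accum: np.ndarray, vox: np.ndarray, d: np.ndarray) -> complex:
    s = _trilinear(accum, vox)
    denom = np.vdot(s, s).real
    if denom == 0:
        return 0.0 + 0.0j
    return np.vdot(s, d) / denom


def _sensor_residual(accum: np.ndarray, vox: np.ndarray, d: np.ndarray) -> float:
    s = _trilinear(accum, vox)
    alpha = _fit_alpha(accum, vox, d)
    return float(np.sum(np.abs(alpha * s - d) ** 2))


def to_time_domain(
    sp: SpectralPotential, fs: float, n_samples: int
) -> WaveField:
    """Convert a spectral potential to a real 4D time-domain field.

    Each bin contributes Re[phi_b(x) exp(i 2 pi f_b t)] — the inverse DFT of
    a Hermitian-symmetrized spectrum under the 2/N coefficient convention,
    so the output is real by construction.
    """
    for f in sp.bins_hz:
        if f >= fs / 2:
            raise InverseError(f"bin {f} Hz at or above Nyquist for fs={fs}")
    t = np.arange(n_samples) / fs
    out = np.zeros(sp.grid.shape + (n_samples,), dtype=float)
    for f_hz, vol in zip(sp.bins_hz, sp.phi):
        phase = np.exp(2j * np.pi * f_hz * t)  # (n_samples,)
        out += np.real(vol[..., None] * phase[None, None, None, :])
    return WaveField(
        phi=out,
        dt=1.0 / fs,
        spacing=sp.grid.voxel_size * 1e-3,
        affine=sp.grid.affine,
    )


def band_power_map(sp: SpectralPotential) -> np.ndarray:
    """Per-voxel band power: sum over bins of |phi_w|^2.

    Equals twice the time-domain variance of :func:`to_time_domain` output
    when the bins are orthogonal on the sample comb (Parseval).
    """
    return np.sum(np.abs(sp.phi) ** 2, axis=0)
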