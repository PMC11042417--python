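"""Brain-wave dynamics: dispersion analytics, boundary-layer modes, and
direct time-domain simulation of the damped wave equation.

The model: retaining the displacement current in Maxwell's equations turns
the potential equation into

    d/dt lap(phi) = -div( Sigma grad(phi) )

with Sigma = sigma_ij/eps the scaled conductivity tensor (1/s).  Plane-wave
analysis phi ~ exp[i(k.x - Omega t)] gives the complex dispersion relation
whose real part (oscillation) scales as 1/|k| — the opposite of an EM wave —
and whose imaginary part is the tissue damping rate:

    gamma = (k.Sigma.k)/|k|^2        omega = -(div Sigma . k)/|k|^2

Sign convention used throughout this module: the temporal factor is
exp(-i omega t) * exp(-gamma t), and results are packaged as
Omega = omega + i*gamma with gamma > 0 meaning decay.  (An equivalent
ansatz with the conjugate sign flips Im[Omega]; magnitudes are what the
physics fixes.)

In a thin boundary layer where conductivity falls off across the fiber
direction, the leading-order equations split into a damped oscillator along
the fibers and an undamped transverse wave equation — the weakly evanescent
transverse cortical waves that survive the bulk damping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import fft as sfft
from scipy import signal as ssignal

from . import _spectral
from .tissue_model import PropertyFields

#: speed of light in vacuum, m/s (the worked-example convention uses 3e8)
C_LIGHT = 3.0e8

#: RK4 real-axis absolute-stability boundary is ~2.785; keep a margin
RK4_STABILITY_LIMIT = 2.5


class DynamicsError(ValueError):
    pass


class StabilityError(RuntimeError):
    """Time step too large for the stiffest damping rate on the grid."""


@dataclass
class DispersionResult:
    """Complex frequency split into oscillation and decay parts (1/s)."""

    omega: float
    gamma: float

    @property
    def Omega(self) -> complex:
        return complex(self.omega, self.gamma)


@dataclass
class BoundaryLayerParams:
    """Coefficients of the idealized thin-layer model.

    a is the conductivity profile value at the boundary, b its cross-layer
    derivative there; both are treated as free constants of the 1D model
    (the theory evaluates them at the layer and carries their units
    implicitly).  epsilon_aniso is the small cross-fiber coupling parameter;
    it tags the ordering of the two branches and does not enter the
    leading-order spectra.
    """

    a: float
    b: float
    epsilon_aniso: float = 0.0
    x0: float = 0.0


@dataclass
class WaveField:
    """A potential field over time: shape (*spatial, n_times)."""

    phi: np.ndarray
    dt: float
    spacing: np.ndarray  # physical voxel size per axis (same units as 1/k)
    affine: Optional[np.ndarray] = None

    def __post_init__(self):
        self.phi = np.asarray(self.phi)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (self.phi.ndim - 1,)
        ).copy()
        if not np.all(np.isfinite(self.phi.real)):
            raise DynamicsError("wave field contains non-finite values")

    @property
    def n_times(self) -> int:
        return self.phi.shape[-1]

    @property
    def spatial_shape(self) -> Tuple[int, ...]:
        return self.phi.shape[:-1]


# ---------------------------------------------------------------------------
# analytics
# ---------------------------------------------------------------------------

def dispersion_relation(k, Sigma_local, div_Sigma) -> DispersionResult:
    """Evaluate the inhomogeneous-medium dispersion relation at wavevector k.

    Parameters are the local scaled-conductivity tensor (1/s) and its
    divergence d_i Sigma_ij (1/(s*length)); k in 1/length.
    """
    k = np.asarray(k, dtype=float)
    k2 = float(k @ k)
    if k2 == 0:
        raise DynamicsError("dispersion relation undefined at k = 0")
    Sigma_local = np.asarray(Sigma_local, dtype=float)
    div_Sigma = np.asarray(div_Sigma, dtype=float)
    gamma = float(k @ Sigma_local @ k) / k2
    omega = -float(div_Sigma @ k) / k2
    return DispersionResult(omega=omega, gamma=gamma)


def em_wavelength(freq: float, eps_rel: float) -> Tuple[float, float]:
    """Electromagnetic phase velocity and wavelength in a dielectric.

    v = c/sqrt(eps_rel), lambda = v/freq.  At 10 Hz and eps_rel = 100 the
    wavelength is 3000 km — the textbook argument for why EM propagation
    effects (not time dependence!) are negligible in the head.
    """
    if freq <= 0:
        raise DynamicsError("frequency must be positive")
    if eps_rel < 1:
        raise DynamicsError("relative permittivity must be >= 1")
    v = C_LIGHT / np.sqrt(eps_rel)
    return float(v), float(v / freq)


def persistence_ratio(k, Sigma_local, div_Sigma) -> float:
    """Damping-to-oscillation ratio gamma/|omega| at wavevector k.

    Small values (~0.02-0.04 for the longest waves at tissue interfaces)
    mean the wave persists for many cycles.
    """
    d = dispersion_relation(k, Sigma_local, div_Sigma)
    if d.omega == 0:
        raise DynamicsError("persistence ratio undefined where omega = 0")
    return abs(d.gamma / d.omega)


def boundary_layer_spectrum(
    params: BoundaryLayerParams, k: float, branch: str
) -> DispersionResult:
    """Plane-wave spectrum of the thin-layer equations.

    With the ansatz phi ~ exp[i(k x - Omega t)]:

    - ``parallel`` (along-fiber damped oscillator, dphi/dt = -a d2phi - b dphi):
      Omega = b*k + i*a*k^2.  The amplitude evolves as exp(Im[Omega] t), so
      a < 0 decays at rate |a|*k^2.
    - ``transverse`` (cross-fiber wave equation, d/dt d2phi = -b dphi):
      Omega = -b/k, exactly real — no damping term exists, the mode only
      oscillates.  Note the 1/k dependence again.
    """
    if k == 0:
        raise DynamicsError("boundary-layer spectrum undefined at k = 0")
    if branch == "transverse":
        return DispersionResult(omega=-params.b / k, gamma=0.0)
    if branch == "parallel":
        return DispersionResult(omega=params.b * k, gamma=params.a * k**2)
    raise DynamicsError(f"unknown branch {branch!r} (parallel|transverse)")


# ---------------------------------------------------------------------------
# time-domain simulation
# ---------------------------------------------------------------------------

def _as_sigma_field(fields, spacing):
    """Accept PropertyFields or a raw Sigma array (scalar or tensor field)."""
    if isinstance(fields, PropertyFields):
        if fields.isotropic:
            sig = fields.scaled_scalar
        else:
            sig = fields.Sigma
        return sig, fields.spacing_m
    sig = np.asarray(fields, dtype=float)
    if spacing is None:
        spacing = 1.0
    return sig, np.asarray(spacing, dtype=float)


def simulate_wave_field(
    fields: Union[PropertyFields, np.ndarray],
    phi0: np.ndarray,
    dt: float,
    n_steps: int,
    *,
    spacing=None,
    forcing: Optional[Callable[[float], np.ndarray]] = None,
    forcing_is_spectral: bool = False,
    store_every: int = 1,
    apodize_width: int = 3,
) -> WaveField:
    """Integrate d/dt lap(phi) = -div(Sigma grad phi) [+ F] on a periodic grid.

    The evolved state is u = lap(phi) in spectral space; phi is recovered by
    spectral Laplacian inversion at every Runge-Kutta stage.  Classic RK4
    with fixed dt; the guard dt * max(Sigma) <= 2.5 rejects steps outside
    the RK4 stability region of the stiffest (purely damped) mode.

    Parameters
    ----------
    fields : PropertyFields or ndarray
        Scaled conductivity: a PropertyFields, a scalar field (isotropic),
        or a (*grid, d, d) tensor field.  Any dimensionality 1-3.
    phi0 : ndarray
        Initial potential (zero-mean; the k=0 mode is projected out).
    forcing : callable t -> ndarray, optional
        Additive drive on du/dt.  If ``forcing_is_spectral`` the callable
        must return the transform of the drive (cheap for precomputed
        splats): scipy.fft.rfftn for a real phi0, scipy.fft.fftn otherwise.
    store_every : int
        Keep every n-th step (plus the initial condition).
    apodize_width : int
        Cosine-taper width (voxels) applied to Sigma at the box edges to
        suppress periodic wrap-around; 0 disables.
    """
    sigma, spacing = _as_sigma_field(fields, spacing)
    phi0 = np.asarray(phi0)
    ndim = phi0.ndim
    shape = phi0.shape
    tensor = sigma.ndim == ndim + 2
    if not tensor and sigma.shape != shape and sigma.size != 1:
        raise DynamicsError("Sigma field shape does not match phi0")
    if dt <= 0 or n_steps < 1:
        raise DynamicsError("need dt > 0 and n_steps >= 1")

    sigma = np.broadcast_to(sigma, shape + ((ndim, ndim) if tensor else ())).copy()
    if apodize_width > 0:
        taper = _spectral.cosine_taper(shape, apodize_width)
        sigma = sigma * (taper[..., None, None] if tensor else taper)

    rate_max = float(
        np.max(np.linalg.eigvalsh(sigma)) if tensor else np.max(sigma)
    )
    if dt * rate_max > RK4_STABILITY_LIMIT:
        raise StabilityError(
            f"dt*max(Sigma) = {dt * rate_max:.3g} exceeds the RK4 stability "
            f"bound {RK4_STABILITY_LIMIT}; reduce dt below "
            f"{RK4_STABILITY_LIMIT / rate_max:.3g}"
        )

    complex_field = np.iscomplexobj(phi0)
    # real fields use the half-spectrum (rfftn) transforms: ~2x faster and
    # the gradient/flux products stay in real arithmetic
    if complex_field:
        fwd = sfft.fftn
        inv = sfft.ifftn
        ks = _spectral.wavenumbers(shape, spacing)
    else:
        fwd = sfft.rfftn
        inv = lambda a: sfft.irfftn(a, s=shape)  # noqa: E731
        ks = _spectral.wavenumbers(shape, spacing)
        last = 2.0 * np.pi * np.fft.rfftfreq(shape[-1], d=np.broadcast_to(
            np.asarray(spacing, float), (ndim,))[-1])
        sh = [1] * ndim
        sh[-1] = last.size
        ks[-1] = last.reshape(sh)
    ik = [1j * k for k in ks]
    k2 = sum(k**2 for k in ks)
    inv_k2 = np.where(k2 > 0, -1.0 / np.where(k2 > 0, k2, 1.0), 0.0)

    def rhs(uh, t):
        ph = uh * inv_k2
        grads = [inv(ik[i] * ph) for i in range(ndim)]
        if tensor:
            div = None
            for i in range(ndim):
                Ji = sigma[..., i, 0] * grads[0]
                for j in range(1, ndim):
                    Ji += sigma[..., i, j] * grads[j]
                term = ik[i] * fwd(Ji)
                div = term if div is None else div + term
        else:
            div = ik[0] * fwd(sigma * grads[0])
            for i in range(1, ndim):
                div += ik[i] * fwd(sigma * grads[i])
        out = -div
        if forcing is not None:
            f = forcing(t)
            out = out + (f if forcing_is_spectral else fwd(np.asarray(f)))
        return out

    uh = -k2 * fwd(phi0)
    uh[(0,) * ndim] = 0.0

    n_stored = n_steps // store_every + 1
    out = np.empty(
        shape + (n_stored,), dtype=complex if complex_field else float
    )

    def snapshot(uh, col):
        ph = inv(uh * inv_k2)
        out[..., col] = ph

    snapshot(uh, 0)
    col = 1
    t = 0.0
    sixth = dt / 6.0
    half = 0.5 * dt
    for step in range(1, n_steps + 1):
        k1 = rhs(uh, t)
        k2_ = rhs(uh + half * k1, t + half)
        k3 = rhs(uh + half * k2_, t + half)
        k4 = rhs(uh + dt * k3, t + dt)
        uh = uh + sixth * (k1 + 2 * k2_ + 2 * k3 + k4)
        t += dt
        if step % store_every == 0:
            if not np.all(
                np.isfinite(uh.reshape(-1)[:: max(1, uh.size // 64)].real)
            ):
                raise StabilityError(
                    f"simulation overflowed at step {step}: dt*max(Sigma) = "
                    f"{dt * rate_max:.3g} (stability bound {RK4_STABILITY_LIMIT})"
                )
            snapshot(uh, col)
            col += 1

    if not np.all(np.isfinite(out.real)):
        raise StabilityError(
            f"simulation produced non-finite values: dt*max(Sigma) = "
            f"{dt * rate_max:.3g} (stability bound {RK4_STABILITY_LIMIT})"
        )
    return WaveField(phi=out[..., :col], dt=dt * store_every, spacing=spacing)


def simulate_boundary_layer(
    params: BoundaryLayerParams,
    branch: str,
    phi0: np.ndarray,
    dx: float,
    dt: float,
    n_steps: int,
    store_every: int = 1,
) -> WaveField:
    """1D spectral integration of the thin-layer equations.

    parallel:    dphi/dt = -a d2phi/dx2 - b dphi/dx
                 (per mode: dphi_k/dt = (a k^2 - i b k) phi_k)
    transverse:  d/dt d2phi/dx2 = -b dphi/dx
                 (per mode: dphi_k/dt = +i (b/k) phi_k  — pure rotation,
                 energy-conserving; the k=0 mode is held at zero)

    RK4 on the exact per-mode ODE; both branches are diagonal in k, so this
    is an independent numerical check on :func:`boundary_layer_spectrum`.
    """
    phi0 = np.asarray(phi0, dtype=complex)
    if phi0.ndim != 1:
        raise DynamicsError("boundary-layer simulation is 1D")
    n = phi0.size
    k = 2.0 * np.pi * np.fft.fftfreq(n, d=dx)
    if branch == "parallel":
        lam = params.a * k**2 - 1j * params.b * k
    elif branch == "transverse":
        lam = np.zeros(n, dtype=complex)
        nz = k != 0
        lam[nz] = 1j * params.b / k[nz]
    else:
        raise DynamicsError(f"unknown branch {branch!r}")

    ph = np.fft.fft(phi0)
    if branch == "transverse":
        ph[0] = 0.0
    # RK4 growth factor for the diagonal system
    z = lam * dt
    growth = 1.0 + z + z**2 / 2.0 + z**3 / 6.0 + z**4 / 24.0

    n_stored = n_steps // store_every + 1
    out = np.empty((n, n_stored), dtype=complex)
    out[:, 0] = phi0
    col = 1
    for step in range(1, n_steps + 1):
        ph = ph * growth
        if step % store_every == 0:
            out[:, col] = np.fft.ifft(ph)
            col += 1
    return WaveField(phi=out[:, :col], dt=dt * store_every, spacing=dx)


# ---------------------------------------------------------------------------
# wave-loop detection
# ---------------------------------------------------------------------------

@dataclass
class WaveLoop:
    """A closed phase streamline in a plane: centroid in (row, col) voxel
    coordinates of the plane, path length in voxels, and the polyline."""

    centroid: np.ndarray
    length: float
    points: np.ndarray


def _instantaneous_phase(plane_t: np.ndarray) -> np.ndarray:
    """Per-pixel temporal analytic-signal phase at the middle time sample."""
    analytic = ssignal.hilbert(plane_t, axis=-1)
    mid = plane_t.shape[-1] // 2
    return np.angle(analytic[..., mid])


def _phase_gradient(phase: np.ndarray) -> np.ndarray:
    """Wrap-safe central-difference gradient of a phase map (2D)."""
    e = np.exp(1j * phase)
    g = np.empty(phase.shape + (2,))
    for ax in range(2):
        fwd = np.roll(e, -1, axis=ax)
        bwd = np.roll(e, 1, axis=ax)
        d = np.angle(fwd * np.conj(bwd)) / 2.0
        # one-sided at the (non-periodic) borders
        sl_lo = [slice(None)] * 2
        sl_lo[ax] = 0
        sl_hi = [slice(None)] * 2
        sl_hi[ax] = -1
        d[tuple(sl_lo)] = np.angle(np.take(e, 1, axis=ax) * np.conj(np.take(e, 0, axis=ax)))
        d[tuple(sl_hi)] = np.angle(
            np.take(e, -1, axis=ax) * np.conj(np.take(e, -2, axis=ax))
        )
        g[..., ax] = d
    return g


def detect_wave_loops(
    field: WaveField,
    plane: Tuple[int, int],
    closure_tol: float = 2.0,
    seed_stride: int = 4,
    step_size: float = 0.5,
) -> List[WaveLoop]:
    """Find closed phase streamlines (rotating-wave cores) in a plane.

    The instantaneous phase is taken per voxel from the temporal analytic
    signal; streamlines follow the in-plane phase gradient (bilinear
    interpolation, midpoint integration, 0.5-voxel steps).  A streamline
    that returns within ``closure_tol`` voxels of its start before the step
    cap (10x the plane perimeter) is reported as a loop; loops are
    deduplicated by centroid distance.  The plane is treated as bounded:
    trajectories leaving it terminate, so traveling plane waves yield no
    loops.
    """
    if field.n_times < 8:
        raise DynamicsError("need at least 8 time samples for analytic phase")
    axis, index = plane
    sl = [slice(None)] * (field.phi.ndim - 1)
    sl[axis] = index
    plane_t = np.real(field.phi[tuple(sl) + (slice(None),)])
    if np.ptp(plane_t) == 0 or np.allclose(np.std(plane_t, axis=-1), 0):
        raise DynamicsError("field is constant in time; phase undefined")

    phase = _instantaneous_phase(plane_t)
    grad = _phase_gradient(phase)
    ny, nx = phase.shape
    perimeter = 2.0 * (nx + ny)
    max_steps = int(10 * perimeter / step_size)

    def interp_dir(p):
        i, j = p
        if not (0 <= i <= ny - 1 and 0 <= j <= nx - 1):
            return None
        i0, j0 = int(np.floor(min(i, ny - 2))), int(np.floor(min(j, nx - 2)))
        di, dj = i - i0, j - j0
        v = (
            grad[i0, j0] * (1 - di) * (1 - dj)
            + grad[i0 + 1, j0] * di * (1 - dj)
            + grad[i0, j0 + 1] * (1 - di) * dj
            + grad[i0 + 1, j0 + 1] * di * dj
        )
        n = np.hypot(v[0], v[1])
        if n < 1e-12:
            return None
        return v / n

    loops: List[WaveLoop] = []
    for si in range(seed_stride // 2, ny, seed_stride):
        for sj in range(seed_stride // 2, nx, seed_stride):
            p = np.array([si, sj], dtype=float)
            start = p.copy()
            pts = [p.copy()]
            traveled = 0.0
            for _ in range(max_steps):
                d = interp_dir(p)
                if d is None:
                    break
                mid = p + 0.5 * step_size * d
                d2 = interp_dir(mid)
                if d2 is None:
                    break
                p = p + step_size * d2
                traveled += step_size
                pts.append(p.copy())
                if traveled > 4 * closure_tol and np.linalg.norm(p - start) < closure_tol:
                    arr = np.asarray(pts)
                    loops.append(
                        WaveLoop(
                            centroid=arr.mean(axis=0), length=traveled, points=arr
                        )
                    )
                    break

    # deduplicate by centroid proximity, keeping the shortest (tightest) loop
    loops.sort(key=lambda l: l.length)
    kept: List[WaveLoop] = []
    for lp in loops:
        if all(np.linalg.norm(lp.centroid - q.centroid) > 3.0 for q in kept):
            kept.append(lp)
    return kept
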