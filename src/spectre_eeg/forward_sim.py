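"""Synthetic EEG generation: electrode placement, sensor sampling, and
driven forward studies.

This is the fixture factory for the inverse problem: a phantom head plus a
set of oscillatory volumetric sources produces both the ground-truth wave
field and the surface recording a real EEG system would have seen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import fft as sfft
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from . import _spectral
from .tissue_model import (
    BACKGROUND,
    GM,
    SCALP,
    WM,
    PropertyFields,
    TissueGrid,
)
from .wetcow_dynamics import DynamicsError, WaveField, simulate_wave_field


class ForwardSimError(ValueError):
    pass


@dataclass
class SensorArray:
    """Named electrodes at world-mm positions, with a reference scheme."""

    names: List[str]
    positions: np.ndarray  # (n, 3) world mm
    reference: str = "average"  # "average", "none", or a channel name

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if len(self.names) != len(self.positions):
            raise ForwardSimError("names/positions length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ForwardSimError("duplicate channel names")
        # positions may be all-NaN (recording loaded without an electrode
        # table); distinctness is only checked for known coordinates
        if len(self.positions) > 1 and np.all(np.isfinite(self.positions)):
            d = np.linalg.norm(
                self.positions[:, None] - self.positions[None, :], axis=-1
            )
            np.fill_diagonal(d, np.inf)
            if d.min() == 0:
                raise ForwardSimError("electrode positions must be distinct")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class EEGRecording:
    """Multichannel recording: data (channels x samples) at rate fs."""

    data: np.ndarray
    fs: float
    sensors: SensorArray

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.fs <= 0:
            raise ForwardSimError("fs must be positive")
        if self.data.shape[0] != len(self.sensors):
            raise ForwardSimError("data rows must match sensor count")
        if not np.all(np.isfinite(self.data)):
            raise ForwardSimError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _scalp_surface_voxels(grid: TissueGrid) -> np.ndarray:
    """Voxel indices of scalp voxels adjacent to background (outer surface)."""
    scalp = grid.labels == SCALP
    if not scalp.any():
        raise ForwardSimError("grid has no scalp voxels")
    bg = grid.labels == BACKGROUND
    # a scalp voxel touching background across any face is on the surface
    neigh_bg = ndimage.binary_dilation(
        bg, structure=ndimage.generate_binary_structure(3, 1)
    )
    surface = scalp & neigh_bg
    if not surface.any():  # head fills the box: fall back to all scalp
        surface = scalp
    return np.argwhere(surface)


def place_electrodes(grid: TissueGrid, n: int, seed: int = 0) -> SensorArray:
    """Quasi-uniform montage by farthest-point sampling on the scalp surface.

    The first electrode is a seeded random surface voxel; each subsequent
    one maximizes the minimum distance to those already chosen.
    Deterministic for a fixed seed.
    """
    if n < 4:
        raise ForwardSimError("need at least 4 electrodes")
    surf = _scalp_surface_voxels(grid)
    if n > len(surf):
        raise ForwardSimError(
            f"requested {n} electrodes but scalp surface has {len(surf)} voxels"
        )
    rng = np.random.default_rng(seed)
    pts_mm = grid.voxel_to_world(surf)
    chosen = [int(rng.integers(len(surf)))]
    dmin = np.linalg.norm(pts_mm - pts_mm[chosen[0]], axis=1)
    for _ in range(1, n):
        nxt = int(np.argmax(dmin))
        chosen.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(pts_mm - pts_mm[nxt], axis=1))
    names = [f"E{i + 1:03d}" for i in range(n)]
    return SensorArray(names=names, positions=pts_mm[chosen], reference="average")


def _interpolator(field: WaveField, grid: TissueGrid):
    axes = [np.arange(s) for s in field.spatial_shape]
    return RegularGridInterpolator(
        axes, field.phi, method="linear", bounds_error=True
    )


def apply_reference(data: np.ndarray, sensors: SensorArray) -> np.ndarray:
    """Subtract the reference: channel mean per sample, a named channel, or
    nothing."""
    ref = sensors.reference
    if ref == "average":
        return data - data.mean(axis=0, keepdims=True)
    if ref in (None, "none"):
        return data
    if ref in sensors.names:
        return data - data[sensors.names.index(ref)][None, :]
    raise ForwardSimError(f"unknown reference {ref!r}")


def sample_sensors(
    field: WaveField,
    sensors: SensorArray,
    grid: TissueGrid,
    snr_db: Optional[float] = None,
    seed: int = 0,
) -> EEGRecording:
    """Trilinear-interpolate the field at electrode positions per sample.

    The sensor reference is applied after interpolation (average reference
    subtracts the per-sample channel mean).  If ``snr_db`` is given, white
    Gaussian noise is added per channel at that empirical SNR.
    """
    vox = grid.world_to_voxel(sensors.positions)
    shape = np.asarray(field.spatial_shape)
    if np.any(vox < 0) or np.any(vox > shape - 1):
        raise ForwardSimError("electrode position outside the field volume")
    interp = _interpolator(field, grid)
    data = np.real(interp(vox))  # (n_sensors, n_times)
    data = apply_reference(data, sensors)
    if snr_db is not None:
        rng = np.random.default_rng(seed)
        p_sig = np.mean(data**2, axis=1, keepdims=True)
        p_noise = p_sig / (10.0 ** (snr_db / 10.0))
        data = data + rng.standard_normal(data.shape) * np.sqrt(p_noise)
    fs = 1.0 / field.dt
    return EEGRecording(data=data, fs=fs, sensors=sensors)


@dataclass
class OscillatorySource:
    """A Gaussian-blob drive at a fixed frequency: center (world mm),
    frequency (Hz), amplitude (arbitrary), blob FWHM in voxels."""

    center_mm: Sequence[float]
    freq_hz: float
    amplitude: float = 1.0
    fwhm_vox: float = 3.0
    phase: float = 0.0


def synthesize_study(
    grid: TissueGrid,
    fields: PropertyFields,
    sources: Sequence[Union[OscillatorySource, Tuple]],
    duration: float,
    fs: float,
    sensors: SensorArray,
    seed: int = 0,
    sim_dt: Optional[float] = None,
    snr_db: Optional[float] = None,
) -> Tuple[WaveField, EEGRecording]:
    """Run a driven forward simulation and sample the electrodes.

    Sources are oscillatory additive forcings on u = lap(phi) — localized
    Gaussian splats at stated frequencies.  (This is fixture machinery: a
    drive is needed to produce a nontrivial recording; it makes no claim
    about the physiological source term, which is outside the model.)
    Returns the ground-truth wave field (sampled at fs) together with the
    sensor recording, both covering round(duration*fs) samples.
    """
    srcs = [
        s if isinstance(s, OscillatorySource) else OscillatorySource(*s)
        for s in sources
    ]
    if not srcs:
        raise ForwardSimError("need at least one source")
    for s in srcs:
        if s.freq_hz >= fs / 2:
            raise ForwardSimError(
                f"source at {s.freq_hz} Hz aliases at fs = {fs} Hz"
            )
        vox = grid.world_to_voxel(np.asarray(s.center_mm))[0]
        iv = tuple(np.round(vox).astype(int))
        if not all(0 <= iv[a] < grid.shape[a] for a in range(3)):
            raise ForwardSimError("source center outside the volume")
        if grid.labels[iv] not in (GM, WM):
            raise ForwardSimError(
                f"source center must lie in brain tissue (label at {iv} is "
                f"{int(grid.labels[iv])})"
            )

    n_samples = int(round(duration * fs))
    if sim_dt is None:
        # resolve both the fastest source and the stiffest damping rate
        dt_guard = 2.0 / max(fields.max_rate, 1e-12)
        sim_dt = min(1.0 / fs, dt_guard)
    store_every = max(1, int(np.ceil(1.0 / (fs * sim_dt) - 1e-9)))
    sim_dt = 1.0 / (fs * store_every)  # commensurate with the sampling comb
    n_steps = n_samples * store_every

    shape = grid.shape
    # precompute spectral splats once; the forcing is then a cheap
    # per-stage linear combination
    splats = []
    for s in srcs:
        vol = np.zeros(shape)
        vox = grid.world_to_voxel(np.asarray(s.center_mm))[0]
        iv = tuple(np.round(vox).astype(int))
        vol[iv] = s.amplitude
        sig = s.fwhm_vox / 2.3548200450309493
        vol = ndimage.gaussian_filter(vol, sig, mode="wrap")
        # half-spectrum transform: the simulator integrates real fields
        splats.append(sfft.rfftn(vol))

    w = [2.0 * np.pi * s.freq_hz for s in srcs]
    ph = [s.phase for s in srcs]

    def forcing(t):
        acc = splats[0] * np.cos(w[0] * t + ph[0])
        for m in range(1, len(splats)):
            acc = acc + splats[m] * np.cos(w[m] * t + ph[m])
        return acc

    phi0 = np.zeros(shape)
    field = simulate_wave_field(
        fields,
        phi0,
        sim_dt,
        n_steps,
        forcing=forcing,
        forcing_is_spectral=True,
        store_every=store_every,
    )
    # drop the initial condition so that exactly n_samples frames remain
    field = WaveField(
        phi=field.phi[..., 1 : n_samples + 1],
        dt=field.dt,
        spacing=field.spacing,
        affine=grid.affine,
    )
    rec = sample_sensors(field, sensors, grid, snr_db=snr_db, seed=seed)
    return field, rec
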