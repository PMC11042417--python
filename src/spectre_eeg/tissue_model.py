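"""Head models: segmented tissue grids and voxelwise bioelectric properties.

The electric-field wave equation solved elsewhere in this package is
parameterized entirely by two scalar fields — conductivity sigma (S/m) and
relative permittivity eps_rel — and by the scaled conductivity tensor
Sigma = sigma_ij / (eps_rel * eps0) with units of 1/s, whose magnitude is the
local wave damping rate.  This module builds those fields from a labeled
segmentation, and generates synthetic multi-shell head phantoms so that the
whole pipeline can be exercised without any acquired data.

Label coding (fixed): 0=background, 1=scalp, 2=skull, 3=CSF, 4=gray matter,
5=white matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from . import _spectral

#: vacuum permittivity, F/m
EPS0 = 8.854187817e-12

BACKGROUND, SCALP, SKULL, CSF, GM, WM = range(6)
LABEL_NAMES = {
    BACKGROUND: "background",
    SCALP: "scalp",
    SKULL: "skull",
    CSF: "csf",
    GM: "gm",
    WM: "wm",
}

#: MNI template grid shapes by isotropic resolution (mm)
MNI_SHAPES: Dict[int, Tuple[int, int, int]] = {
    2: (91, 109, 91),
    1: (182, 218, 182),
}


class TissueModelError(ValueError):
    """Raised for invalid grids, labels, or property tables."""


@dataclass
class TissueGrid:
    """A segmented label volume with voxel geometry.

    Parameters
    ----------
    labels : int ndarray, shape (nx, ny, nz)
        Tissue label per voxel, values in {0..5}.
    voxel_size : 3 floats
        Voxel edge length per axis, mm.
    affine : (4, 4) ndarray
        Voxel-index -> world-mm map (NIfTI convention).
    """

    labels: np.ndarray
    voxel_size: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise TissueModelError("labels must be a 3D volume")
        if self.labels.min() < 0 or self.labels.max() > WM:
            bad = sorted(set(np.unique(self.labels)) - set(LABEL_NAMES))
            raise TissueModelError(f"unknown tissue labels present: {bad}")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise TissueModelError("affine is singular")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.labels.shape))

    def world_to_voxel(self, xyz_mm: np.ndarray) -> np.ndarray:
        """Map world-mm coordinates (n, 3) to fractional voxel indices."""
        xyz_mm = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        hom = np.c_[xyz_mm, np.ones(len(xyz_mm))]
        return (hom @ inv.T)[:, :3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (hom @ self.affine.T)[:, :3]


def mni_grid(resolution_mm: int = 2) -> TissueGrid:
    """An empty grid with the MNI template dimensions at 1 or 2 mm.

    Useful for bookkeeping (voxel counts, affines) and as a canvas for
    template-space property maps; all labels are background.
    """
    if resolution_mm not in MNI_SHAPES:
        raise TissueModelError(
            f"no MNI template shape at {resolution_mm} mm (have {sorted(MNI_SHAPES)})"
        )
    shape = MNI_SHAPES[resolution_mm]
    r = float(resolution_mm)
    affine = np.diag([r, r, r, 1.0])
    # standard MNI origin: AC at world (0,0,0)
    affine[:3, 3] = (-90.0, -126.0, -72.0)
    return TissueGrid(np.zeros(shape, dtype=np.int16), (r, r, r), affine)


@dataclass
class TissueProperties:
    """Bioelectric properties of one tissue class."""

    sigma: float  # conductivity, S/m
    eps_rel: float  # relative permittivity (dimensionless)
    anisotropy_ratio: float = 1.0  # transverse/longitudinal, in (0, 1]

    def __post_init__(self):
        if self.sigma < 0:
            raise TissueModelError("sigma must be >= 0")
        if self.eps_rel <= 0:
            raise TissueModelError("eps_rel must be > 0")
        if not (0.0 < self.anisotropy_ratio <= 1.0):
            raise TissueModelError("anisotropy_ratio must be in (0, 1]")


@dataclass
class TissuePropertyTable:
    """Per-label bioelectric property assignments.

    Gray and white matter use measured low-frequency averages; scalp, skull
    and CSF conductivities are literature-typical placeholders with the same
    permittivity placeholder, and belong in the run configuration rather
    than in code.  Background is vacuum-like with a tiny conductivity floor
    so spectral operators stay finite.
    """

    entries: Dict[int, TissueProperties] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "TissuePropertyTable":
        return cls(
            {
                BACKGROUND: TissueProperties(1e-6, 1e7),
                SCALP: TissueProperties(0.43, 1e7),
                SKULL: TissueProperties(0.01, 1e7),
                CSF: TissueProperties(1.79, 1e7),
                GM: TissueProperties(2.75e-2, 4.07e7),
                WM: TissueProperties(2.77e-2, 2.76e7),
            }
        )

    def __getitem__(self, label: int) -> TissueProperties:
        return self.entries[label]

    def damping_rates(self) -> Dict[int, float]:
        """Isotropic damping rate sigma/(eps_rel*eps0) per label, 1/s."""
        return {
            lab: isotropic_damping_rate(p.sigma, p.eps_rel)
            for lab, p in self.entries.items()
        }


def isotropic_damping_rate(sigma: float, eps_rel: float) -> float:
    """Wave decay rate gamma = sigma / (eps_rel * eps0), in 1/s.

    For a homogeneous isotropic medium the dispersion relation gives a decay
    rate independent of wavevector, equal to the scaled conductivity.  With
    measured gray/white-matter values this lands in the 75-115 1/s range —
    strong damping, which is why only the transverse boundary-layer modes
    survive long enough to observe.
    """
    if eps_rel <= 0:
        raise TissueModelError("eps_rel must be > 0")
    return float(sigma) / (float(eps_rel) * EPS0)


@dataclass
class PropertyFields:
    """Voxelwise property fields on a tissue grid.

    Attributes
    ----------
    sigma : ndarray
        Conductivity, S/m.
    eps_rel : ndarray
        Relative permittivity (dimensionless).
    Sigma : ndarray, shape (*grid, 3, 3)
        Scaled conductivity tensor sigma_ij/(eps_rel*eps0), units 1/s.
    grad_Sigma : ndarray, shape (*grid, 3)
        Spectrally computed divergence d_i Sigma_ij, units 1/(s*m).
    fiber_dir : ndarray or None
        Unit vectors for anisotropy, shape (*grid, 3).
    """

    grid: TissueGrid
    sigma: np.ndarray
    eps_rel: np.ndarray
    Sigma: np.ndarray
    grad_Sigma: np.ndarray
    fiber_dir: Optional[np.ndarray] = None
    isotropic: bool = True

    @property
    def spacing_m(self) -> np.ndarray:
        """Voxel spacing in meters (spectral operators are SI)."""
        return self.voxel_size_mm * 1e-3

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return self.grid.voxel_size

    @property
    def scaled_scalar(self) -> np.ndarray:
        """Isotropic part of the scaled tensor, Tr(Sigma)/3 (1/s)."""
        return np.trace(self.Sigma, axis1=-2, axis2=-1) / 3.0

    @property
    def max_rate(self) -> float:
        """Largest eigenvalue of Sigma over the volume (for dt guards)."""
        if self.isotropic:
            return float(np.max(self.scaled_scalar))
        return float(np.max(np.linalg.eigvalsh(self.Sigma)))


def build_property_fields(
    grid: TissueGrid,
    table: Optional[TissuePropertyTable] = None,
    smooth_width: float = None,
    fiber_dir: Optional[np.ndarray] = None,
) -> PropertyFields:
    """Assign sigma/eps_rel by label, smooth, and build the scaled tensor.

    Parameters
    ----------
    smooth_width : float, mm
        Standard deviation of the Gaussian applied to the scalar property
        maps before tensor construction.  Spectral differentiation of
        discontinuous coefficients rings, so some smoothing is required;
        the default is one voxel.  Scalars are smoothed first and the tensor
        is assembled from the smoothed scalars.
    fiber_dir : optional (*grid, 3) array
        Unit fiber directions.  When given, labels with anisotropy_ratio < 1
        get a transversely-isotropic tensor
        v v^T * S_par + (I - v v^T) * S_perp with S_perp/S_par equal to the
        ratio and the trace matching the isotropic construction.
    """
    table = table or TissuePropertyTable.default()
    if smooth_width is None:
        smooth_width = float(np.min(grid.voxel_size))
    if smooth_width < 0:
        raise TissueModelError("smooth_width must be >= 0")
    extent = np.min(np.asarray(grid.shape) * grid.voxel_size)
    if smooth_width > extent / 2:
        raise TissueModelError(
            f"smooth_width {smooth_width} mm exceeds half the domain extent"
        )

    present = np.unique(grid.labels)
    missing = [int(l) for l in present if int(l) not in table.entries]
    if missing:
        raise TissueModelError(f"labels without table entries: {missing}")

    sigma = np.zeros(grid.shape, dtype=float)
    eps = np.zeros(grid.shape, dtype=float)
    ratio = np.ones(grid.shape, dtype=float)
    for lab in present:
        m = grid.labels == lab
        p = table[int(lab)]
        sigma[m] = p.sigma
        eps[m] = p.eps_rel
        ratio[m] = p.anisotropy_ratio

    if smooth_width > 0:
        sig_vox = smooth_width / grid.voxel_size  # per-axis sigma in voxels
        sigma = ndimage.gaussian_filter(sigma, sig_vox, mode="wrap")
        eps = ndimage.gaussian_filter(eps, sig_vox, mode="wrap")
        ratio = ndimage.gaussian_filter(ratio, sig_vox, mode="wrap")

    s_iso = sigma / (eps * EPS0)  # 1/s
    eye = np.eye(3)
    aniso = fiber_dir is not None and np.any(ratio < 1.0 - 1e-12)
    if aniso:
        v = np.asarray(fiber_dir, dtype=float)
        if v.shape != grid.shape + (3,):
            raise TissueModelError("fiber_dir must have shape (*grid, 3)")
        norm = np.linalg.norm(v, axis=-1, keepdims=True)
        v = np.where(norm > 0, v / np.maximum(norm, 1e-30), 0.0)
        vvt = v[..., :, None] * v[..., None, :]
        # trace-preserving split: S_par + 2*S_perp = 3*s_iso
        s_par = 3.0 * s_iso / (1.0 + 2.0 * ratio)
        s_perp = ratio * s_par
        Sigma = (
            vvt * s_par[..., None, None]
            + (eye - vvt) * s_perp[..., None, None]
        )
        # voxels without a fiber direction stay isotropic
        flat = norm[..., 0] <= 0
        Sigma[flat] = eye * s_iso[flat][..., None, None]
    else:
        Sigma = eye * s_iso[..., None, None]

    spacing_m = grid.voxel_size * 1e-3
    grad = np.empty(grid.shape + (3,), dtype=float)
    for j in range(3):
        # d_i Sigma_ij summed over i
        acc = np.zeros(grid.shape)
        for i in range(3):
            comp = Sigma[..., i, j]
            acc += _spectral.gradient(comp, spacing_m)[i]
        grad[..., j] = acc

    return PropertyFields(
        grid=grid,
        sigma=sigma,
        eps_rel=eps,
        Sigma=Sigma,
        grad_Sigma=grad,
        fiber_dir=fiber_dir if aniso else None,
        isotropic=not aniso,
    )


# ---------------------------------------------------------------------------
# synthetic phantom
# ---------------------------------------------------------------------------

#: shell outer radii as fractions of the half-extent, outermost first
_SHELL_FRACTIONS = {
    SCALP: 0.92,
    SKULL: 0.80,
    CSF: 0.70,
    GM: 0.62,
    WM: 0.38,
}


def make_phantom_head(
    shape=(48, 48, 48),
    voxel_size=2.0,
    fold_amplitude: float = 0.1,
    seed: int = 0,
) -> TissueGrid:
    """Concentric-ellipsoid head phantom: scalp > skull > CSF > GM > WM.

    The gray/white interface may be perturbed by a smooth sinusoidal radial
    modulation (``fold_amplitude`` as a fraction of the interface radius)
    emulating cortical folding; phases are drawn deterministically from
    ``seed``.  The world origin sits at the volume center.
    """
    shape = tuple(int(n) for n in np.broadcast_to(shape, (3,)))
    if min(shape) < 16:
        raise TissueModelError("phantom shape must be >= 16 per axis")
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
    rng = np.random.default_rng(seed)

    half = (np.asarray(shape) - 1) / 2.0
    idx = np.indices(shape).astype(float)
    # normalized ellipsoidal radius: 1.0 at the box inscribed ellipsoid
    rho = np.sqrt(sum(((idx[a] - half[a]) / half[a]) ** 2 for a in range(3)))

    theta = np.arccos(np.clip((idx[2] - half[2]) / np.maximum(rho * half[2], 1e-9), -1, 1))
    phi_ang = np.arctan2(idx[1] - half[1], idx[0] - half[0])
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    fold = np.sin(6 * theta + p1) * np.cos(5 * phi_ang + p2)

    labels = np.zeros(shape, dtype=np.int16)
    labels[rho <= _SHELL_FRACTIONS[SCALP]] = SCALP
    labels[rho <= _SHELL_FRACTIONS[SKULL]] = SKULL
    labels[rho <= _SHELL_FRACTIONS[CSF]] = CSF
    labels[rho <= _SHELL_FRACTIONS[GM]] = GM
    r_wm = _SHELL_FRACTIONS[WM] * (1.0 + fold_amplitude * fold)
    labels[(rho <= r_wm) & (labels == GM)] = WM

    for lab in (SCALP, SKULL, CSF, GM, WM):
        if not np.any(labels == lab):
            raise TissueModelError(
                f"degenerate phantom: no {LABEL_NAMES[lab]} voxels at shape {shape}"
            )

    affine = np.diag(list(voxel_size) + [1.0])
    affine[:3, 3] = -half * voxel_size
    return TissueGrid(labels, voxel_size, affine)


def brain_mask(grid: TissueGrid) -> np.ndarray:
    """Boolean mask of brain voxels (gray + white matter)."""
    return (grid.labels == GM) | (grid.labels == WM)
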