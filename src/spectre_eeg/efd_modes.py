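"""Spatiotemporal mode decomposition and comparison statistics.

A simplified entropy-spectrum-pathways construction: the coupling between
masked voxels is their absolute temporal Pearson correlation (nonnegative,
as a path-entropy weight must be); its eigendecomposition supplies
orthonormal spatial modes, the squared leading eigenvector gives the
equilibrium (long-time) distribution mu*, and projecting the data onto the
top-n modes yields time courses and per-mode power maps.  This is a
documented simplification of the full field-theoretic decomposition — it
keeps the operational ingredients (space-time correlations, mu*, summed
power modes) while remaining a plain symmetric eigenproblem.

Also here: the map-comparison statistics used to score reconstructions —
thresholded map correlation, slice-wise correlation profiles, ROI power
tables, and Fisher's z transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .wetcow_dynamics import WaveField

logger = logging.getLogger(__name__)


class ModeError(ValueError):
    pass


@dataclass
class CouplingMatrix:
    """Pairwise |Pearson| coupling over a (possibly subsampled) voxel mask."""

    Q: np.ndarray  # (n, n), symmetric, diag 1, entries in [0, 1]
    voxels: np.ndarray  # (n, 3) voxel indices into the field grid

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        self.voxels = np.atleast_2d(np.asarray(self.voxels))
        if self.Q.shape[0] != self.Q.shape[1]:
            raise ModeError("Q must be square")
        if len(self.voxels) != self.Q.shape[0]:
            raise ModeError("one voxel per Q row required")


@dataclass
class EFDModeSet:
    """Eigenmodes of the coupling matrix applied to a data field."""

    eigvals: np.ndarray  # descending
    eigmaps: np.ndarray  # (n_voxels, n_modes), orthonormal columns
    timecourses: np.ndarray  # (n_modes, n_times)
    mu_star: np.ndarray  # (n_voxels,), >= 0, sums to 1
    voxels: np.ndarray  # (n_voxels, 3)
    grid_shape: Tuple[int, int, int]

    @property
    def n_modes(self) -> int:
        return self.eigmaps.shape[1]

    def mode_power_map(self, k: int) -> np.ndarray:
        """Power map of mode k: psi_k^2 * var(tau_k), as a volume."""
        var = float(np.var(self.timecourses[k]))
        vol = np.zeros(self.grid_shape)
        vol[tuple(self.voxels.T)] = self.eigmaps[:, k] ** 2 * var
        return vol

    def summed_power_map(self, weighting: str = "eigval") -> np.ndarray:
        """Sum of per-mode power maps.

        ``eigval`` weights each mode by its coupling eigenvalue (the display
        quantity); ``unit`` weights are the energy-conserving choice — over
        a complete mode set the unit-weighted total equals the variance of
        the masked data.
        """
        if weighting == "eigval":
            w = self.eigvals[: self.n_modes]
        elif weighting == "unit":
            w = np.ones(self.n_modes)
        else:
            raise ModeError("weighting must be 'eigval' or 'unit'")
        vols = np.zeros(self.grid_shape)
        var = np.var(self.timecourses, axis=1)
        vals = (self.eigmaps**2 * (w * var)[None, :]).sum(axis=1)
        vols[tuple(self.voxels.T)] = vals
        return vols

    def total_power(self) -> float:
        """Unit-weighted power summed over modes and voxels."""
        return float(np.sum(np.var(self.timecourses, axis=1)))


def _masked_courses(field: WaveField, voxels: np.ndarray) -> np.ndarray:
    X = np.real(field.phi[tuple(voxels.T)])  # (n_vox, n_times)
    return X - X.mean(axis=1, keepdims=True)


def build_coupling_matrix(
    field: WaveField,
    mask: np.ndarray,
    max_voxels: int = 2000,
    seed: int = 0,
) -> CouplingMatrix:
    """Absolute Pearson correlation between masked voxel time courses.

    If the mask exceeds ``max_voxels``, a deterministic stratified subsample
    is drawn: the mask (in C order, which is spatially coherent) is split
    into ``max_voxels`` contiguous strata and a seeded random member is
    taken from each.  Constant time courses are dropped with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field.spatial_shape:
        raise ModeError("mask shape must match the field grid")
    if field.n_times < 8:
        raise ModeError("need at least 8 time points")
    voxels = np.argwhere(mask)
    if len(voxels) < 2:
        raise ModeError("need at least 2 masked voxels")
    if len(voxels) > max_voxels:
        rng = np.random.default_rng(seed)
        edges = np.linspace(0, len(voxels), max_voxels + 1).astype(int)
        pick = np.array(
            [rng.integers(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]
        )
        voxels = voxels[pick]

    X = _masked_courses(field, voxels)
    sd = X.std(axis=1)
    keep = sd > 0
    if not np.all(keep):
        logger.warning(
            "dropping %d constant time course(s) from the coupling matrix",
            int(np.sum(~keep)),
        )
        voxels, X = voxels[keep], X[keep]
        if len(voxels) < 2:
            raise ModeError("fewer than 2 non-constant masked voxels")
    Q = np.abs(np.corrcoef(X))
    np.fill_diagonal(Q, 1.0)
    return CouplingMatrix(Q=Q, voxels=voxels)


def esp_equilibrium(coupling: CouplingMatrix):
    """Eigendecomposition of the coupling and the equilibrium distribution.

    Returns eigenvalues (descending), eigenvectors (columns, matching
    order), and mu* — the squared leading eigenvector normalized to sum 1.
    When the leading eigenvalue is degenerate, mu* is the (basis-invariant)
    diagonal of the projector onto the leading eigenspace, normalized; for
    Q = I this gives the uniform distribution, and exchangeable voxels
    always receive equal weight.
    """
    Q = coupling.Q
    if not np.all(np.isfinite(Q)):
        raise ModeError("coupling matrix contains non-finite entries")
    vals, vecs = sla.eigh(Q)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    lead = np.isclose(vals, vals[0], rtol=1e-10, atol=1e-12)
    mu = np.sum(vecs[:, lead] ** 2, axis=1)
    mu = mu / mu.sum()
    return vals, vecs, mu


def extract_modes(
    field: WaveField, coupling: CouplingMatrix, n: int = 10
) -> EFDModeSet:
    """Project the field onto the top-n coupling eigenmodes.

    tau_k(t) = sum_i psi^(k)_i X_i(t) over the coupling's voxels (demeaned
    time courses).  With n equal to the mask size the orthonormal basis is
    complete and the projection reconstructs X exactly.
    """
    n_vox = coupling.Q.shape[0]
    if not (1 <= n <= n_vox):
        raise ModeError(f"n must be in [1, {n_vox}]")
    vals, vecs, mu = esp_equilibrium(coupling)
    # |corr| is symmetric but not necessarily PSD; rank counts magnitudes
    rank = int(np.sum(np.abs(vals) > 1e-12 * abs(vals[0])))
    if n > rank:
        raise ModeError(f"n={n} exceeds the coupling rank {rank}")
    X = _masked_courses(field, coupling.voxels)
    psi = vecs[:, :n]
    tau = psi.T @ X
    return EFDModeSet(
        eigvals=vals[:n],
        eigmaps=psi,
        timecourses=tau,
        mu_star=mu,
        voxels=coupling.voxels,
        grid_shape=field.spatial_shape,
    )


def contrast_power(map_a: np.ndarray, map_b: np.ndarray) -> np.ndarray:
    """Signed condition difference A - B, voxelwise."""
    map_a, map_b = np.asarray(map_a), np.asarray(map_b)
    if map_a.shape != map_b.shape:
        raise ModeError("contrast maps must share a grid")
    return map_a - map_b


def roi_power_table(
    power_map: np.ndarray,
    atlas: np.ndarray,
    labels: Optional[Sequence[int]] = None,
    names: Optional[dict] = None,
) -> pd.DataFrame:
    """Mean power per nonzero atlas region, sorted descending.

    Regions with no voxels (possible when an explicit label list is given)
    are flagged with count 0 and NaN mean.
    """
    power_map, atlas = np.asarray(power_map), np.asarray(atlas)
    if power_map.shape != atlas.shape:
        raise ModeError("power map and atlas must share a grid")
    if labels is None:
        labels = [int(l) for l in np.unique(atlas) if l != 0]
    rows = []
    for lab in labels:
        m = atlas == lab
        cnt = int(m.sum())
        mean = float(power_map[m].mean()) if cnt else float("nan")
        rows.append(
            {
                "region": names.get(lab, lab) if names else lab,
                "label": lab,
                "mean_power": mean,
                "n_voxels": cnt,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        "mean_power", ascending=False, na_position="last"
    ).reset_index(drop=True)


def map_correlation(
    map_a: np.ndarray,
    map_b: np.ndarray,
    roi: Optional[np.ndarray] = None,
    threshold: float = 0.1,
) -> float:
    """Pearson r over voxels where both |A| and |B| exceed the threshold.

    Correlating only supra-threshold voxels inside the ROI focuses the
    comparison on jointly 'activated' tissue rather than empty background.
    """
    map_a, map_b = np.asarray(map_a, float), np.asarray(map_b, float)
    if map_a.shape != map_b.shape:
        raise ModeError("maps must share a grid")
    m = (np.abs(map_a) > threshold) & (np.abs(map_b) > threshold)
    if roi is not None:
        m &= np.asarray(roi, dtype=bool)
    if m.sum() < 3:
        raise ModeError(
            f"only {int(m.sum())} voxels survive the joint threshold (need >= 3)"
        )
    return float(np.corrcoef(map_a[m], map_b[m])[0, 1])


def slicewise_correlation(
    map_a: np.ndarray, map_b: np.ndarray, axis: int = 2
) -> np.ndarray:
    """Pearson r within each slice along ``axis``; NaN where undefined
    (constant or empty slices)."""
    map_a, map_b = np.asarray(map_a, float), np.asarray(map_b, float)
    if map_a.shape != map_b.shape:
        raise ModeError("maps must share a grid")
    n = map_a.shape[axis]
    out = np.full(n, np.nan)
    for i in range(n):
        a = np.take(map_a, i, axis=axis).ravel()
        b = np.take(map_b, i, axis=axis).ravel()
        if a.size < 2 or a.std() == 0 or b.std() == 0:
            continue
        out[i] = np.corrcoef(a, b)[0, 1]
    return out


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform z = arctanh(r)."""
    r = float(r)
    if abs(r) >= 1:
        raise ModeError("|r| must be < 1")
    return float(np.arctanh(r))
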