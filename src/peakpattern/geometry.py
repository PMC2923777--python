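"""Regional "statistical volume" (resel) estimation.

Under non-stationary smoothness the null distribution of peaks is uniform
per *resel* (resolution element), not per voxel.  The resels-per-voxel
(RPV) image is estimated from the spatial derivatives of standardized GLM
residuals; summing it over the voxels of a region gives the region's resel
count ``|A_j|``, and the normalised counts ``a_j = |A_j| / sum|A|`` define
the null multinomial pattern over any partition of the search volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: (4 ln 2)^(-3/2), the 3D conversion from gradient-covariance determinant
#: to resel density.
_RESEL_SCALE_3D = (4.0 * np.log(2.0)) ** (-1.5)

MIN_REGION_RESELS = 1e-6


@dataclass(frozen=True)
class VolumeGrid:
    """Sampling grid shared by all volumes of one analysis.

    Parameters
    ----------
    shape : tuple of int
        Lattice dimensions in voxels.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    affine : (4, 4) ndarray
        Voxel-to-world map (NIfTI convention).
    mask : ndarray of bool
        Analysis mask; volumes are only interpreted inside it.
    """

    shape: tuple
    voxel_size: tuple
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {shape}")
        vs = tuple(float(v) for v in self.voxel_size)
        object.__setattr__(self, "voxel_size", vs)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be strictly positive, got {vs}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", affine)
        mask = np.asarray(self.mask)
        if mask.shape != shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match grid shape {shape}"
            )
        object.__setattr__(self, "mask", mask.astype(bool))

    @classmethod
    def from_mask(cls, mask, voxel_size=(1.0, 1.0, 1.0), affine=None):
        mask = np.asarray(mask)
        if affine is None:
            affine = np.diag(list(voxel_size) + [1.0])
        return cls(shape=mask.shape, voxel_size=voxel_size, affine=affine,
                   mask=mask)

    @classmethod
    def full(cls, shape, voxel_size=(1.0, 1.0, 1.0)):
        """Grid whose mask is the whole lattice (as in simulations)."""
        return cls.from_mask(np.ones(shape, dtype=bool), voxel_size)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def check_volume(self, vol, name="volume"):
        vol = np.asarray(vol)
        if vol.shape != self.shape:
            raise ValueError(
                f"{name} shape {vol.shape} does not match grid {self.shape}"
            )
        return vol


@dataclass(frozen=True)
class RPVImage:
    """Resels-per-voxel image on a grid; zero outside the mask."""

    grid: VolumeGrid
    rpv: np.ndarray

    def __post_init__(self):
        rpv = np.asarray(self.rpv, dtype=float)
        self.grid.check_volume(rpv, "rpv")
        if np.any(rpv < 0):
            raise ValueError("rpv must be non-negative everywhere")
        rpv = np.where(self.grid.mask, rpv, 0.0)
        total = rpv.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("total resel count must be finite and positive")
        object.__setattr__(self, "rpv", rpv)

    @property
    def total_resels(self) -> float:
        return float(self.rpv.sum())


@dataclass(frozen=True)
class RegionPartition:
    """A labelled partition of the search volume with resel measures.

    ``labels`` assigns 0 to voxels outside the partition and 1..n to the
    regions; ``resels[j-1]`` is |A_j| and ``rel_volume`` the normalised
    a_j = |A_j| / sum|A| defining the null multinomial pattern.
    """

    grid: VolumeGrid
    labels: np.ndarray
    region_names: tuple
    resels: np.ndarray
    rel_volume: np.ndarray = field(default=None)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        self.grid.check_volume(labels, "labels")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise ValueError("labels must be integer-valued")
            labels = np.round(labels).astype(np.int32)
        if labels.min() < 0:
            raise ValueError("labels must be >= 0 (0 = outside partition)")
        object.__setattr__(self, "labels", labels)
        resels = np.asarray(self.resels, dtype=float)
        names = tuple(str(s) for s in self.region_names)
        if len(names) != resels.size:
            raise ValueError("region_names and resels length mismatch")
        if np.any(resels < 0):
            raise ValueError("resel counts must be non-negative")
        object.__setattr__(self, "resels", resels)
        object.__setattr__(self, "region_names", names)
        rv = self.rel_volume
        if rv is None:
            rv = resels / resels.sum()
        rv = np.asarray(rv, dtype=float)
        if abs(rv.sum() - 1.0) > 1e-12:
            raise ValueError("rel_volume must sum to 1 within 1e-12")
        object.__setattr__(self, "rel_volume", rv)

    @property
    def n_regions(self) -> int:
        return len(self.region_names)


def _forward_diff(u, mask, axis):
    """Forward difference of standardized residuals along one axis.

    Returns (derivatives, valid) where ``valid[v]`` is True when both v and
    its +1 neighbour on ``axis`` lie in the mask; derivatives are zero where
    invalid.
    """
    d = np.zeros_like(u)
    sl_lo = [slice(None)] * u.ndim
    sl_hi = [slice(None)] * u.ndim
    ax = axis + 1  # axis 0 indexes volumes
    sl_lo[ax] = slice(None, -1)
    sl_hi[ax] = slice(1, None)
    d[tuple(sl_lo)] = u[tuple(sl_hi)] - u[tuple(sl_lo)]

    valid = np.zeros(mask.shape, dtype=bool)
    m_lo = [slice(None)] * mask.ndim
    m_hi = [slice(None)] * mask.ndim
    m_lo[axis] = slice(None, -1)
    m_hi[axis] = slice(1, None)
    valid[tuple(m_lo)] = mask[tuple(m_lo)] & mask[tuple(m_hi)]
    d[:, ~valid] = 0.0
    return d, valid


def estimate_rpv(residuals, grid: VolumeGrid, df: int) -> RPVImage:
    """Estimate the resels-per-voxel image from a residual series.

    At each in-mask voxel the residual time-course is standardized to unit
    sum of squares, per-axis spatial gradients are formed by forward
    differences (a voxel contributes to an axis only when its +1 neighbour
    is in-mask), and the 3x3 gradient covariance ``Lambda`` is accumulated
    across volumes.  The resel density is ``(4 ln 2)^(-3/2) |Lambda|^(1/2)``.
    Voxels where ``Lambda`` is not computable (all-zero residuals, or no
    in-mask neighbour on any axis) receive the mask-mean density; missing
    individual axes are imputed entry-wise from the mask mean of the
    corresponding covariance term.

    Parameters
    ----------
    residuals : (n_volumes, nx, ny, nz) array_like
        Standardizable residual volumes (>= 4) sharing ``grid``.
    grid : VolumeGrid
    df : int
        Residual degrees of freedom of the GLM the residuals came from
        (validation/metadata; the density formula itself is df-free).
    """
    res = np.asarray(residuals, dtype=np.float64)
    if res.ndim != 4:
        raise ValueError("residuals must be a 4D array (volumes first)")
    if res.shape[0] < 4:
        raise ValueError("need at least 4 residual volumes")
    if res.shape[1:] != grid.shape:
        raise ValueError("residual volumes do not match the grid shape")
    if df < 1:
        raise ValueError("df must be >= 1")

    mask = grid.mask
    ss = np.sqrt(np.einsum("t...,t...->...", res, res))
    standardizable = mask & (ss > 0)
    u = np.zeros_like(res)
    np.divide(res, ss, out=u, where=standardizable)

    # gradient covariance entries over valid voxels, entry-wise imputation
    derivs, valids = [], []
    for ax in range(3):
        d, v = _forward_diff(u, standardizable, ax)
        derivs.append(d)
        valids.append(v)

    lam = np.zeros(grid.shape + (3, 3))
    any_valid = np.zeros(grid.shape, dtype=bool)
    for a in range(3):
        any_valid |= valids[a]
    for a in range(3):
        for b in range(a, 3):
            entry = np.einsum("t...,t...->...", derivs[a], derivs[b])
            ok = valids[a] & valids[b]
            if ok.any():
                fill = entry[ok].mean()
            else:
                fill = 0.0
            entry = np.where(ok, entry, fill)
            lam[..., a, b] = entry
            lam[..., b, a] = entry

    det = np.linalg.det(lam[mask])
    det = np.clip(det, 0.0, None)
    rpv_flat = _RESEL_SCALE_3D * np.sqrt(det)

    computable = (standardizable & any_valid)[mask]
    if computable.any():
        mean_rpv = rpv_flat[computable].mean()
    else:
        raise ValueError("no voxel allows resel estimation")
    rpv_flat[~computable] = mean_rpv
    n_imputed = int((~computable).sum())
    if n_imputed:
        logger.info("imputed mask-mean rpv at %d voxels", n_imputed)

    rpv = np.zeros(grid.shape)
    rpv[mask] = rpv_flat
    return RPVImage(grid=grid, rpv=rpv)


def region_resels(rpv: RPVImage, labels, region_names=None,
                  min_resels: float = MIN_REGION_RESELS) -> RegionPartition:
    """Sum the RPV image over each labelled region.

    Regions are listed in ascending label order; ``|A_j|`` is the sum of
    resel density over voxels carrying label j, and relative statistical
    volumes are the normalised sums.  A region whose resel mass falls below
    ``min_resels`` makes the null pattern degenerate and raises.
    """
    grid = rpv.grid
    labels = np.asarray(labels)
    grid.check_volume(labels, "labels")
    labels = labels.astype(np.int64)
    n = int(labels.max())
    if n < 1:
        raise ValueError("labels contain no regions (max label < 1)")
    if region_names is None:
        region_names = [f"region_{j}" for j in range(1, n + 1)]
    if len(region_names) != n:
        raise ValueError(f"expected {n} region names, got {len(region_names)}")

    sums = np.bincount(labels.ravel(), weights=rpv.rpv.ravel(),
                       minlength=n + 1)[1:]
    low = np.nonzero(sums < min_resels)[0]
    if low.size:
        bad = ", ".join(str(region_names[j]) for j in low)
        raise ValueError(
            f"region(s) {bad} have < {min_resels} resels; merge them with a "
            "neighbour or exclude them (the null pattern is degenerate at "
            "a_j = 0)"
        )
    return RegionPartition(grid=grid, labels=labels,
                           region_names=region_names, resels=sums)


def isotropic_rel_volume(labels, grid: VolumeGrid = None,
                         region_names=None) -> RegionPartition:
    """Partition with relative volumes proportional to voxel counts.

    Shortcut for stationary (isotropic-smoothness) maps, where resel counts
    are proportional to physical volume; ``resels`` holds raw voxel counts,
    which is adequate for every relative quantity downstream.
    """
    labels = np.asarray(labels)
    if grid is None:
        grid = VolumeGrid.full(labels.shape)
    grid.check_volume(labels, "labels")
    labels = labels.astype(np.int64)
    n = int(labels.max())
    if n < 1:
        raise ValueError("labels contain no regions")
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    if np.any(counts == 0):
        empty = np.nonzero(counts == 0)[0] + 1
        raise ValueError(f"empty region label(s): {empty.tolist()}")
    if region_names is None:
        region_names = [f"region_{j}" for j in range(1, n + 1)]
    return RegionPartition(grid=grid, labels=labels,
                           region_names=region_names,
                           resels=counts.astype(float))
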