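"""Detection and regional counting of supra-threshold local maxima.

An "event" is a local maximum of the statistic image lying above a height
threshold; only the locations of events enter the pattern model, never
their heights or extents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import VolumeGrid, RegionPartition
from .multinomial import EventCounts

logger = logging.getLogger(__name__)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    raise ValueError(f"connectivity must be 18 or 26, got {connectivity}")


@dataclass(frozen=True)
class PeakConfig:
    """Event definition: height threshold and neighbourhood.

    ``one_per_excursion`` switches from counting every supra-threshold
    local maximum to counting one event per supra-threshold connected
    component (its global maximum), the convention recommended at low
    thresholds where a single blob can carry several nearby maxima.
    """

    threshold: float = 3.0
    connectivity: int = 26
    one_per_excursion: bool = False

    def __post_init__(self):
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        _structure(self.connectivity)


@dataclass(frozen=True)
class EventSet:
    """Detected peaks: integer voxel coordinates and statistic heights."""

    coords: np.ndarray          # (n_peaks, 3) int
    heights: np.ndarray         # (n_peaks,)
    grid: VolumeGrid

    def __post_init__(self):
        coords = np.atleast_2d(np.asarray(self.coords, dtype=np.int64))
        if coords.size == 0:
            coords = coords.reshape(0, 3)
        heights = np.asarray(self.heights, dtype=float).ravel()
        if coords.shape[0] != heights.size:
            raise ValueError("coords/heights length mismatch")
        if coords.shape[0] and len(np.unique(coords, axis=0)) != coords.shape[0]:
            raise ValueError("peak coordinates must be unique")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "heights", heights)

    def __len__(self):
        return self.coords.shape[0]


def find_peaks(spm, grid: VolumeGrid, cfg: PeakConfig = PeakConfig()) -> EventSet:
    """Find supra-threshold local maxima of a statistic volume.

    A voxel is a peak when it is in-mask, exceeds the threshold and is
    strictly greater than every in-mask neighbour (out-of-mask neighbours
    count as -inf).  Connected plateaus of exactly equal value that
    dominate all their neighbours yield a single peak at the
    lexicographically smallest coordinate.  With ``one_per_excursion`` only
    the global maximum of each supra-threshold connected component is kept.
    """
    spm = np.asarray(grid.check_volume(spm, "spm"), dtype=float)
    mask = grid.mask
    if not np.all(np.isfinite(spm[mask])):
        raise ValueError("non-finite statistic values inside the mask")

    struct = _structure(cfg.connectivity)
    t = cfg.threshold

    work = np.where(mask, spm, -np.inf)
    # candidates: >= every neighbour (maximum_filter includes the centre)
    neigh_max = ndimage.maximum_filter(
        work, footprint=struct & ~_centre(), mode="constant", cval=-np.inf
    )
    cand = mask & (spm > t) & (work >= neigh_max)

    strict = cand & (work > neigh_max)
    plateau_cand = cand & ~strict

    coords = [np.argwhere(strict)]
    if plateau_cand.any():
        coords.append(_plateau_peaks(work, plateau_cand, struct))
    coords = np.concatenate(coords, axis=0) if coords else np.zeros((0, 3), int)

    if cfg.one_per_excursion and coords.shape[0]:
        coords = _one_per_excursion(work, mask, t, struct, coords)

    coords = coords[np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))]
    heights = spm[tuple(coords.T)] if coords.shape[0] else np.zeros(0)
    return EventSet(coords=coords, heights=heights, grid=grid)


def _centre():
    c = np.zeros((3, 3, 3), dtype=bool)
    c[1, 1, 1] = True
    return c


def _plateau_peaks(work, plateau_cand, struct):
    """Resolve equal-valued plateaus: one peak per dominating plateau.

    Connected components of equal-valued candidate voxels are accepted when
    every voxel adjacent to (but outside) the component is strictly lower,
    and represented by their lexicographically smallest coordinate.
    """
    out = []
    lab, n = ndimage.label(plateau_cand, structure=struct)
    for comp in ndimage.find_objects(lab):
        sub = lab[comp]
        for cid in np.unique(sub[sub > 0]):
            vox = np.argwhere(lab == cid)
            vals = work[tuple(vox.T)]
            # a labelled component may join touching plateaus of different
            # heights; split by value
            for v in np.unique(vals):
                members = vox[vals == v]
                if _dominates(work, members, v, struct):
                    order = np.lexsort(
                        (members[:, 2], members[:, 1], members[:, 0]))
                    out.append(members[order[0]])
    if not out:
        return np.zeros((0, 3), dtype=np.int64)
    return np.asarray(out, dtype=np.int64)


def _dominates(work, members, value, struct) -> bool:
    offsets = np.argwhere(struct) - 1
    offsets = offsets[np.any(offsets != 0, axis=1)]
    member_set = {tuple(m) for m in map(tuple, members)}
    shape = work.shape
    has_outside = False
    for m in members:
        for off in offsets:
            nb = m + off
            if np.any(nb < 0) or np.any(nb >= shape):
                continue
            if tuple(nb) in member_set:
                continue
            v = work[tuple(nb)]
            if v >= value:
                return False
            if np.isfinite(v):
                has_outside = True
    # a multi-voxel constant region with nothing in-mask around it (e.g. a
    # constant field over the whole mask) is not a local maximum
    return has_outside


def _one_per_excursion(work, mask, t, struct, coords):
    excur = mask & (work > t)
    lab, n_comp = ndimage.label(excur, structure=struct)
    keep = []
    comp_of = lab[tuple(coords.T)]
    for cid in range(1, n_comp + 1):
        members = coords[comp_of == cid]
        if members.shape[0] == 0:
            continue
        vals = work[tuple(members.T)]
        best = vals == vals.max()
        members = members[best]
        order = np.lexsort((members[:, 2], members[:, 1], members[:, 0]))
        keep.append(members[order[0]])
    return np.asarray(keep, dtype=np.int64) if keep else np.zeros((0, 3), int)


def count_events(events: EventSet, partition: RegionPartition,
                 subject_id=None) -> EventCounts:
    """Count events per region of a partition.

    Peaks on label 0 (outside the partition) are excluded with a warning;
    include an explicit rest-of-volume region in the partition when they
    should be modelled.
    """
    if events.grid.shape != partition.grid.shape:
        raise ValueError("events and partition are on different grids")
    n = partition.n_regions
    if len(events) == 0:
        return EventCounts(d=np.zeros(n, dtype=np.int64), subject_id=subject_id)
    labels = partition.labels[tuple(events.coords.T)]
    outside = int((labels == 0).sum())
    if outside:
        logger.warning(
            "%d peak(s) fall outside the partition (label 0) and are "
            "excluded from the counts", outside)
    d = np.bincount(labels[labels > 0], minlength=n + 1)[1:]
    return EventCounts(d=d, subject_id=subject_id)
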