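"""File formats: NIfTI volumes, TSV tables, YAML configuration, JSON reports.

Conventions: NIfTI-1 for volumes (statistic maps, masks, label atlases,
RPV images, residual series), TSV for tabular exchange (region tables,
event tables, counts tables), JSON for inference reports.  Region order in
every output follows the atlas label order.  Reports embed SHA-256
checksums of the inputs they were computed from.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
import nibabel as nib
import yaml

from .geometry import VolumeGrid, RegionPartition
from .multinomial import EventCounts, NullPattern
from .peaks import EventSet
from .rfx import SubjectCounts


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_volume(path, mask=None):
    """Read a 3D (or 4D series) NIfTI volume.

    Returns (data, grid).  For 4D inputs the data is returned with the
    series axis first, ready for residual-based resel estimation.  The
    grid mask defaults to everywhere-true unless ``mask`` is supplied.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim == 4:
        data = np.moveaxis(data, -1, 0)
        shape = data.shape[1:]
    elif data.ndim == 3:
        shape = data.shape
    else:
        raise ValueError(f"{path}: expected a 3D or 4D NIfTI, got "
                         f"{data.ndim}D")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    grid = VolumeGrid(shape=shape, voxel_size=voxel_size,
                      affine=img.affine, mask=mask)
    return data, grid


def read_mask(path):
    """Read a binary analysis mask; values other than {0, 1} are an error."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: mask must be 3D")
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError(f"{path}: mask must contain only 0/1 values, "
                         f"found {uniq[:5]}")
    return data.astype(bool), img.affine


def write_volume(data, grid: VolumeGrid, path):
    data = np.asarray(data)
    if data.ndim == 4:  # series axis first internally, last on disk
        data = np.moveaxis(data, 0, -1)
    nib.save(nib.Nifti1Image(data.astype(np.float32), grid.affine), str(path))


def check_same_grid(grid_a: VolumeGrid, grid_b: VolumeGrid,
                    name_a="first input", name_b="second input"):
    if grid_a.shape != grid_b.shape or \
            not np.allclose(grid_a.affine, grid_b.affine):
        raise ValueError(
            f"{name_a} and {name_b} differ in shape or affine: "
            f"{grid_a.shape} vs {grid_b.shape}")


def write_region_table(partition: RegionPartition, path):
    """TSV: region, n_voxels, resels, rel_volume (atlas label order)."""
    n_vox = np.bincount(partition.labels.ravel(),
                        minlength=partition.n_regions + 1)[1:]
    df = pd.DataFrame({
        "region": list(partition.region_names),
        "n_voxels": n_vox,
        "resels": partition.resels,
        "rel_volume": partition.rel_volume,
    })
    df.to_csv(path, sep="\t", index=False)


def write_events_table(events: EventSet, path, labels=None,
                       region_names=None):
    """TSV event table: x, y, z, height, region."""
    regions = [""] * len(events)
    if labels is not None and len(events):
        lab = labels[tuple(events.coords.T)]
        if region_names is not None:
            regions = [region_names[v - 1] if v > 0 else "<outside>"
                       for v in lab]
        else:
            regions = lab.tolist()
    df = pd.DataFrame({
        "x": events.coords[:, 0], "y": events.coords[:, 1],
        "z": events.coords[:, 2], "height": events.heights,
        "region": regions,
    })
    df.to_csv(path, sep="\t", index=False)


def read_counts_table(path):
    """Read a regional counts table.

    TSV with header ``region<TAB>resels<TAB><subject>...``: one row per
    region, a positive resel column, and one non-negative integer count
    column per subject.  Returns (SubjectCounts, NullPattern) with the
    null pattern computed from the resel column.
    """
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "region" or cols[1] not in (
            "resels", "rel_volume"):
        raise ValueError(
            f"{path}: expected columns 'region', 'resels' (or "
            f"'rel_volume'), then one count column per subject; got {cols}")
    regions = df["region"].astype(str).tolist()
    if len(set(regions)) != len(regions):
        dupes = {r for r in regions if regions.count(r) > 1}
        raise ValueError(f"{path}: duplicate region name(s): {sorted(dupes)}")
    resels = df[cols[1]].to_numpy(dtype=float)
    for i, v in enumerate(resels):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(
                f"{path}: row {i + 2}: non-positive or missing "
                f"{cols[1]} value {v!r}")
    a = NullPattern(resels / resels.sum())

    subj_cols = cols[2:]
    count_mat = np.empty((len(subj_cols), len(regions)), dtype=np.int64)
    for s, col in enumerate(subj_cols):
        for i, v in enumerate(df[col]):
            try:
                fv = float(v)
            except (TypeError, ValueError):
                fv = np.nan
            if not np.isfinite(fv) or fv < 0 or fv != int(fv):
                raise ValueError(
                    f"{path}: row {i + 2}, column {col!r}: counts must be "
                    f"non-negative integers, got {v!r}")
            count_mat[s, i] = int(fv)
    subject_resels = np.tile(resels, (len(subj_cols), 1))
    data = SubjectCounts(
        counts=tuple(EventCounts(row, subject_id=col)
                     for row, col in zip(count_mat, subj_cols)),
        nulls=(a,), resels=subject_resels)
    return data, a, regions


def write_counts_table(path, regions, resels, count_matrix,
                       subject_ids=None):
    count_matrix = np.atleast_2d(np.asarray(count_matrix))
    if subject_ids is None:
        subject_ids = [f"subject_{i + 1}" for i in range(count_matrix.shape[0])]
    df = pd.DataFrame({"region": list(regions), "resels": np.asarray(resels)})
    for sid, row in zip(subject_ids, count_matrix):
        df[str(sid)] = row
    df.to_csv(path, sep="\t", index=False)


def write_report(report: dict, path, inputs=None):
    """Write a JSON report, embedding SHA-256 checksums of its inputs."""
    out = dict(report)
    if inputs:
        out["input_checksums"] = {str(p): sha256_of(p) for p in inputs}
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=False)
        fh.write("\n")


def load_yaml_config(path, dataclass_type):
    """Load a YAML mapping into a (frozen) dataclass; unknown keys are
    rejected with the offending names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    known = {f.name for f in dc_fields(dataclass_type)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown configuration key(s): {unknown}")
    for key in ("shape", "fwhm_range", "n_partition_regions"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return dataclass_type(**raw)
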