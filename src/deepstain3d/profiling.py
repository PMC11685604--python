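"""Per-cell multiplexed feature extraction and spatial dispersion statistics.

Downstream of segmentation, each cell is profiled by the mean and the
population SD of every marker channel over its voxels (the within-cell SD
separates strictly nuclear or cytoplasmic markers from uniformly expressed
ones at equal mean), by its mean distance to the nearest vessel, and by its
mean value of the fiber distance-transform field (proximity to e.g.
neuropeptide-positive fibers).  k-nearest-neighbor dispersion statistics
(mean, SD, coefficient of variation of each cell's mean distance to its k
nearest same-group neighbors, k = 30 by default) quantify spatial clustering
per cell group.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import cKDTree

from .grid import LabelVolume, MaskVolume, VolumeGrid, distance_transform

__all__ = ["extract_cell_features", "fiber_proximity", "knn_dispersion"]

NORMALIZATIONS = ("none", "percentile", "zscore")


def _normalize_channel(data: np.ndarray, incell: np.ndarray, mode: str) -> np.ndarray:
    """Per-channel intensity normalization based on in-cell voxel statistics."""
    if mode == "none":
        return data
    vals = data[incell]
    if mode == "percentile":
        lo, hi = np.percentile(vals, [0.1, 99.9])
        if hi <= lo:
            return np.zeros_like(data)
        return np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    if mode == "zscore":
        sd = vals.std()
        if sd == 0:
            return np.zeros_like(data)
        return (data - vals.mean()) / sd
    raise ValueError(f"normalization must be one of {NORMALIZATIONS}, got {mode!r}")


def extract_cell_features(
    labels: LabelVolume,
    channels: Sequence[VolumeGrid],
    vessel_mask: Optional[MaskVolume] = None,
    normalization: str = "percentile",
    min_size: int = 10,
    channel_names: Optional[Sequence[str]] = None,
    vessel_distance_at: str = "cell-mean",
) -> pd.DataFrame:
    """Per-cell marker means/SDs and distance to the nearest vessel.

    Returns one row per label of at least ``min_size`` voxels with columns
    ``label``, ``n_voxels``, ``cz/cy/cx`` (centroid, µm), ``mean_<ch>`` and
    ``sd_<ch>`` per channel (population SD over the label's voxels after the
    chosen per-channel normalization) and, when a vessel mask is given,
    ``vessel_distance`` (µm) — the mean of the vessel distance field over the
    cell's voxels, or its value at the centroid voxel when
    ``vessel_distance_at='centroid'``.
    """
    if len(channels) < 1:
        raise ValueError("need at least one channel")
    for ch in channels:
        if ch.shape != labels.shape:
            raise ValueError("channel and label shapes differ")
    if vessel_mask is not None and vessel_mask.shape != labels.shape:
        raise ValueError("vessel mask shape differs from labels")
    if vessel_distance_at not in ("cell-mean", "centroid"):
        raise ValueError("vessel_distance_at must be 'cell-mean' or 'centroid'")

    ids = labels.labels
    counts = ndi.sum_labels(np.ones(labels.shape), labels.data, ids) if ids.size else np.array([])
    keep = counts >= min_size
    ids = ids[keep]
    names = list(channel_names) if channel_names is not None else [f"ch{i}" for i in range(len(channels))]
    if len(names) != len(channels):
        raise ValueError("channel_names length mismatch")

    out = pd.DataFrame({"label": ids.astype(int), "n_voxels": counts[keep].astype(int)})
    if ids.size:
        spc = np.asarray(labels.spacing)
        cents = np.asarray(ndi.center_of_mass(np.ones(labels.shape), labels.data, ids)) * spc
        out[["cz", "cy", "cx"]] = cents
    else:
        out[["cz", "cy", "cx"]] = np.empty((0, 3))

    incell = labels.data > 0
    for name, ch in zip(names, channels):
        data = _normalize_channel(np.asarray(ch.data, dtype=float), incell, normalization)
        if ids.size:
            out[f"mean_{name}"] = ndi.mean(data, labels.data, ids)
            out[f"sd_{name}"] = np.sqrt(ndi.variance(data, labels.data, ids))
        else:
            out[f"mean_{name}"] = out[f"sd_{name}"] = np.array([])

    if vessel_mask is not None and ids.size:
        vdist = distance_transform(vessel_mask).data
        if vessel_distance_at == "cell-mean":
            out["vessel_distance"] = ndi.mean(vdist, labels.data, ids)
        else:
            idx = np.rint(np.asarray(out[["cz", "cy", "cx"]]) / np.asarray(labels.spacing)).astype(int)
            idx = np.clip(idx, 0, np.asarray(labels.shape) - 1)
            out["vessel_distance"] = vdist[idx[:, 0], idx[:, 1], idx[:, 2]]
    return out


def fiber_proximity(labels: LabelVolume, fiber_mask: MaskVolume) -> pd.Series:
    """Per-cell mean of the fiber distance-transform field (µm).

    A cell fully overlapping the fiber mask scores 0; values grow with the
    cell's distance from the nearest fiber.
    """
    if not fiber_mask.data.any():
        raise ValueError("fiber mask is empty")
    if fiber_mask.shape != labels.shape:
        raise ValueError("fiber mask shape differs from labels")
    ids = labels.labels
    field = distance_transform(fiber_mask).data
    vals = ndi.mean(field, labels.data, ids) if ids.size else np.array([])
    return pd.Series(vals, index=pd.Index(ids.astype(int), name="label"), name="fiber_distance")


def knn_dispersion(
    points: np.ndarray,
    group_labels: Sequence,
    k: int = 30,
    eval_subset: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Spatial dispersion of each cell group via k-NN distances.

    For every member the mean Euclidean distance to its ``k`` nearest
    same-group neighbors is computed; per group these member values are
    aggregated to mean, population SD and coefficient of variation CV =
    SD/mean (NaN when the mean is 0).

    ``eval_subset`` (boolean mask over points) applies guard-zone edge
    correction: all same-group members remain neighbor candidates, but only
    the selected members enter the aggregates — use it to exclude members
    near the observation-window boundary whose neighborhoods are truncated.

    Raises when any group has ≤ k members (naming the group).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be an (n, d) array")
    groups = np.asarray(group_labels)
    if len(groups) != len(pts):
        raise ValueError("group_labels length mismatch")
    if eval_subset is None:
        eval_subset = np.ones(len(pts), dtype=bool)
    eval_subset = np.asarray(eval_subset, dtype=bool)

    rows = []
    for g in pd.unique(groups):
        sel = groups == g
        n = int(sel.sum())
        if n <= k:
            raise ValueError(f"group {g!r} has {n} members; needs more than k={k}")
        gp = pts[sel]
        tree = cKDTree(gp)
        dists, _ = tree.query(gp, k=k + 1)  # first neighbor is the point itself
        member_means = dists[:, 1:].mean(axis=1)
        member_means = member_means[eval_subset[sel]]
        if member_means.size == 0:
            raise ValueError(f"group {g!r} has no members in eval_subset")
        mean = float(member_means.mean())
        sd = float(member_means.std())
        rows.append(
            {
                "group": g,
                "n": int(member_means.size),
                "k": k,
                "mean": mean,
                "sd": sd,
                "cv": sd / mean if mean > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")
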