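"""Spatial statistics on ROI centroids in atlas-like coordinates.

Centroid clouds are rasterised onto an isometric voxel grid (10 um edges by
default) and compared by Pearson correlation of the linearised volumes:
cluster-cluster spatial correlograms, marker-cluster co-localisation
screens (a marker is a candidate label for a cluster when their volumes
correlate above 0.15), per-region density heatmaps against binary region
masks, and two-regressor HSV tuning maps where saturation encodes the
stronger correlation and hue the preference between the two regressors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "VoxelDensityMap",
    "voxelize_centroids",
    "spatial_correlogram",
    "marker_cluster_correlation",
    "hsv_tuning_map",
    "region_density_heatmap",
]


@dataclass(frozen=True)
class VoxelDensityMap:
    """3-D centroid count grid with its voxel size and placement."""

    counts: np.ndarray          # (nx, ny, nz) counts
    edge_um: float
    origin: Tuple[float, float, float]
    n_clipped: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def voxelize_centroids(centroids: np.ndarray, edge: float = 10.0,
                       extent: Tuple[Tuple[float, float], ...] | None = None
                       ) -> VoxelDensityMap:
    """Count centroids in half-open isometric voxel bins ``[lo, hi)``.

    ``extent`` is ((x0, x1), (y0, y1), (z0, z1)); by default it is derived
    from the data, snapped outward to voxel-edge multiples.  Centroids
    outside the extent are not counted; their number is reported in
    ``n_clipped``.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("centroids must be (n, 3)")
    if edge <= 0:
        raise ValueError("edge must be > 0")
    if extent is None:
        lo = np.floor(pts.min(axis=0) / edge) * edge
        hi = np.floor(pts.max(axis=0) / edge + 1) * edge
    else:
        lo = np.array([e[0] for e in extent], dtype=float)
        hi = np.array([e[1] for e in extent], dtype=float)
    shape = np.maximum(np.round((hi - lo) / edge).astype(int), 1)
    idx = np.floor((pts - lo) / edge).astype(int)
    inside = np.all((pts >= lo) & (idx < shape), axis=1)
    counts = np.zeros(shape, dtype=int)
    np.add.at(counts, tuple(idx[inside].T), 1)
    return VoxelDensityMap(counts=counts, edge_um=edge,
                           origin=tuple(lo),
                           n_clipped=int((~inside).sum()))


def _linearized(maps: Sequence[VoxelDensityMap | np.ndarray]) -> np.ndarray:
    arrs = [m.counts if isinstance(m, VoxelDensityMap) else np.asarray(m)
            for m in maps]
    shape = arrs[0].shape
    for a in arrs:
        if a.shape != shape:
            raise ValueError("maps must share one voxel grid")
    return np.array([a.ravel().astype(float) for a in arrs])


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson matrix with zero-variance rows mapped to 0."""
    def z(x):
        sd = x.std(axis=1)
        zero = sd == 0
        out = (x - x.mean(axis=1, keepdims=True)) \
            / np.where(zero, 1.0, sd)[:, None]
        out[zero] = 0.0
        return out, zero
    za, ea = z(a)
    zb, eb = z(b)
    if ea.any() or eb.any():
        warnings.warn("all-zero (or constant) volumes; their correlations "
                      "are 0", stacklevel=3)
    return za @ zb.T / a.shape[1]


def spatial_correlogram(maps: Sequence[VoxelDensityMap | np.ndarray],
                        names: Sequence[str] | None = None):
    """Cluster-cluster Pearson matrix over linearised voxel counts, with a
    complete-linkage correlation-distance leaf order."""
    x = _linearized(maps)
    corr = _pearson_rows(x, x)
    np.fill_diagonal(corr, 1.0)
    dist = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    link = hierarchy.linkage(dist, method="complete")
    order = hierarchy.leaves_list(link)
    if names is None:
        names = [f"cluster{i + 1}" for i in range(len(maps))]
    return pd.DataFrame(corr, index=names, columns=names), order, link


def marker_cluster_correlation(marker_volumes: Sequence[np.ndarray],
                               cluster_maps: Sequence[VoxelDensityMap
                                                      | np.ndarray],
                               select_thresh: float = 0.15,
                               marker_names: Sequence[str] | None = None,
                               cluster_names: Sequence[str] | None = None):
    """Marker x cluster co-localisation screen.

    Volumes must live on the cluster voxel grid.  A marker is selected when
    its best cluster correlation is strictly above ``select_thresh``.
    Returns (corr table, selected boolean Series, row-z-scored table of the
    selected markers in complete-linkage order).
    """
    mk = _linearized(marker_volumes)
    cl = _linearized(cluster_maps)
    if mk.shape[1] != cl.shape[1]:
        raise ValueError("marker volumes and cluster maps on different grids")
    corr = _pearson_rows(mk, cl)
    if marker_names is None:
        marker_names = [f"marker{i + 1}" for i in range(len(mk))]
    if cluster_names is None:
        cluster_names = [f"cluster{i + 1}" for i in range(len(cl))]
    table = pd.DataFrame(corr, index=marker_names, columns=cluster_names)
    selected = table.max(axis=1) > select_thresh
    sel = table.loc[selected]
    if len(sel) >= 2:
        sd = sel.to_numpy().std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        zrows = (sel.to_numpy() - sel.to_numpy().mean(axis=1,
                                                      keepdims=True)) / sd
        dist = hierarchy.distance.pdist(zrows, metric="correlation")
        order = hierarchy.leaves_list(hierarchy.linkage(dist,
                                                        method="complete"))
        zmap = pd.DataFrame(zrows[order], index=sel.index[order],
                            columns=sel.columns)
    else:
        zmap = sel
    return table, selected, zmap


def hsv_tuning_map(corr_a: np.ndarray, corr_b: np.ndarray,
                   centroids: np.ndarray, edge: float = 10.0,
                   hue_a: float = 0.9, hue_b: float = 0.35):
    """Two-regressor tuning colours and a maximum-intensity projection.

    Saturation is the larger of the two correlations (negative values clip
    to 0); hue interpolates linearly between the anchor hues by the relative
    preference ``corr_a / (corr_a + corr_b)``.  ROIs with no positive
    correlation render unsaturated.  Returns (per-ROI hsv (n, 3) with
    value=1, RGB projection image over x-y).
    """
    a = np.clip(np.asarray(corr_a, dtype=float), 0.0, 1.0)
    b = np.clip(np.asarray(corr_b, dtype=float), 0.0, 1.0)
    sat = np.maximum(a, b)
    total = a + b
    pref_a = np.divide(a, total, out=np.full_like(a, 0.5),
                       where=total > 0)
    hue = hue_a * pref_a + hue_b * (1.0 - pref_a)
    hue[total == 0] = 0.0
    sat = np.where(total == 0, 0.0, sat)
    hsv = np.stack([hue, sat, np.ones_like(hue)], axis=1)

    pts = np.asarray(centroids, dtype=float)
    lo = pts.min(axis=0)
    ij = np.floor((pts[:, :2] - lo[:2]) / edge).astype(int)
    shape = ij.max(axis=0) + 1
    img_sat = np.zeros(shape)
    img_hue = np.zeros(shape)
    for (i, j), h, s in zip(ij, hue, sat):
        if s > img_sat[i, j]:
            img_sat[i, j] = s
            img_hue[i, j] = h
    from matplotlib.colors import hsv_to_rgb
    rgb = hsv_to_rgb(np.stack([img_hue, img_sat,
                               (img_sat > 0).astype(float)], axis=-1))
    return hsv, rgb


def region_density_heatmap(cluster_labels: np.ndarray,
                           centroids: np.ndarray,
                           masks: Dict[str, np.ndarray],
                           edge: float = 10.0,
                           origin: Sequence[float] = (0.0, 0.0, 0.0),
                           normalize: bool = True) -> pd.DataFrame:
    """Cluster x region density: ROIs of the cluster inside the region per
    region voxel.  Rows optionally normalised to sum 1 per cluster; empty
    region masks yield NaN with a warning."""
    labels = np.asarray(cluster_labels)
    pts = np.asarray(centroids, dtype=float)
    origin = np.asarray(origin, dtype=float)
    clusters = sorted(set(labels) - {-1})
    region_names = list(masks)
    out = np.zeros((len(clusters), len(region_names)))
    vox = np.floor((pts - origin) / edge).astype(int)
    for j, rname in enumerate(region_names):
        mask = np.asarray(masks[rname], dtype=bool)
        nvox = mask.sum()
        if nvox == 0:
            warnings.warn(f"region {rname!r} has an empty mask",
                          stacklevel=2)
            out[:, j] = np.nan
            continue
        inside = np.all((vox >= 0) & (vox < mask.shape), axis=1)
        in_region = np.zeros(len(pts), dtype=bool)
        in_region[inside] = mask[tuple(vox[inside].T)]
        for i, k in enumerate(clusters):
            out[i, j] = (in_region & (labels == k)).sum() / nvox
    if normalize:
        with np.errstate(invalid="ignore"):
            rows = np.nansum(out, axis=1, keepdims=True)
            rows[rows == 0] = 1.0
            out = out / rows
    return pd.DataFrame(out, index=clusters, columns=region_names)
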