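"""Recursive octree and supervoxel decomposition of strain heterogeneity.

Both methods start from a single region of interest (ROI) covering the whole
lung mask and recursively subdivide any ROI whose masked-voxel standard
deviation of the analysed field (mean-normalized strain range) is at or
above a threshold, until every leaf is either homogeneous (std below
threshold) or smaller than a minimum fraction of the mask.  Octree
subdivision bisects the ROI bounding box into eight octants; supervoxel
subdivision splits the ROI in two by a weighted k-means over intensity and
spatial position.  Patchiness is summarised by the mean ROI volume as a
fraction of the lung mask (larger = more spatially homogeneous).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_STD_THRESHOLD = 0.3
DEFAULT_MIN_FRACTION = 0.002


def mean_normalize(field: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Field divided by its mask mean (the decomposition input)."""
    m = float(np.mean(field[mask]))
    if m == 0:
        raise ValueError("cannot mean-normalize a zero-mean field")
    return field / m


@dataclass
class Decomposition:
    """ROI label volume plus per-ROI census."""

    labels: np.ndarray  # int volume, -1 outside mask, ROI ids 0..n-1
    sizes: np.ndarray  # masked voxels per ROI
    stds: np.ndarray  # population std of the field per ROI
    method: str
    mask_size: int

    @property
    def n_rois(self) -> int:
        return len(self.sizes)

    @property
    def mean_roi_fraction(self) -> float:
        """Mean ROI volume as a fraction of the lung mask (V_ROI-bar)."""
        return float(np.mean(self.sizes)) / self.mask_size


def cluster_stats(decomp: Decomposition):
    """Mean ROI fraction and a per-ROI census table."""
    census = pd.DataFrame(
        {
            "roi": np.arange(decomp.n_rois),
            "voxels": decomp.sizes,
            "fraction": decomp.sizes / decomp.mask_size,
            "std": decomp.stds,
        }
    )
    return decomp.mean_roi_fraction, census


def _pop_std(values: np.ndarray) -> float:
    return float(np.std(values)) if values.size else 0.0


def octree_decompose(
    field: np.ndarray,
    mask: np.ndarray,
    std_threshold: float = DEFAULT_STD_THRESHOLD,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> Decomposition:
    """Recursive eight-way subdivision of the mask bounding region.

    An ROI splits when its masked std is >= ``std_threshold`` AND its masked
    size is >= ``min_fraction`` of the mask; octants come from bisecting each
    axis of the ROI's own bounding box (floor split for odd extents); empty
    octants are discarded.
    """
    if not np.any(mask):
        raise ValueError("empty mask")
    field = np.asarray(field, dtype=float)
    total = int(mask.sum())
    min_size = min_fraction * total

    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    labels = np.full(mask.shape, -1, dtype=int)
    sizes: list[int] = []
    stds: list[float] = []
    stack = [tuple((int(a), int(b)) for a, b in zip(lo, hi))]
    while stack:
        box = stack.pop()
        sl = tuple(slice(a, b) for a, b in box)
        sub_mask = mask[sl]
        size = int(sub_mask.sum())
        if size == 0:
            continue
        vals = field[sl][sub_mask]
        std = _pop_std(vals)
        splittable = any(b - a > 1 for a, b in box)
        if std >= std_threshold and size >= min_size and splittable:
            mids = [a + (b - a) // 2 if b - a > 1 else b for a, b in box]
            for octant in np.ndindex(2, 2, 2):
                child = []
                degenerate = False
                for (a, b), m, half in zip(box, mids, octant):
                    lo_c, hi_c = (a, m) if half == 0 else (m, b)
                    if hi_c <= lo_c:
                        degenerate = True
                        break
                    child.append((lo_c, hi_c))
                if not degenerate:
                    stack.append(tuple(child))
        else:
            roi = len(sizes)
            view = labels[sl]
            view[sub_mask] = roi
            sizes.append(size)
            stds.append(std)
    return Decomposition(
        labels=labels,
        sizes=np.asarray(sizes),
        stds=np.asarray(stds),
        method="octree",
        mask_size=total,
    )


def _two_means(features: np.ndarray, max_iter: int = 50):
    """Deterministic 2-means: farthest-pair initialization, Lloyd updates.

    Returns a boolean assignment (True = cluster 1) or None when the split
    degenerates (identical features or an empty cluster).
    """
    center = features.mean(axis=0)
    d0 = np.einsum("ij,ij->i", features - center, features - center)
    p = int(np.argmax(d0))
    dp = np.einsum("ij,ij->i", features - features[p], features - features[p])
    q = int(np.argmax(dp))
    if dp[q] == 0:
        return None  # all features identical
    c0, c1 = features[p].copy(), features[q].copy()
    assign = np.zeros(len(features), dtype=bool)
    for _ in range(max_iter):
        dist0 = np.einsum("ij,ij->i", features - c0, features - c0)
        dist1 = np.einsum("ij,ij->i", features - c1, features - c1)
        new_assign = dist1 < dist0  # ties go to cluster 0
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        if not assign.any() or assign.all():
            return None
        c0 = features[~assign].mean(axis=0)
        c1 = features[assign].mean(axis=0)
    return assign


def supervoxel_decompose(
    field: np.ndarray,
    mask: np.ndarray,
    std_threshold: float = DEFAULT_STD_THRESHOLD,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    proximity_weight: float = 1.0,
    max_iter: int = 50,
) -> Decomposition:
    """Recursive binary supervoxel split by weighted 2-means clustering.

    Feature vectors combine the z-scored field value with spatial position
    scaled by the ROI bounding-box diagonal and ``proximity_weight``
    (default 1: equal balance; larger values favour compact ROIs).  Stop
    rules match the octree.  The clustering is deterministic (farthest-pair
    initialization, fixed iteration cap); a degenerate ROI (identical
    features) is treated as below threshold.
    """
    if not np.any(mask):
        raise ValueError("empty mask")
    field = np.asarray(field, dtype=float)
    total = int(mask.sum())
    min_size = min_fraction * total

    coords = np.argwhere(mask).astype(float)
    values = field[mask]
    labels = np.full(mask.shape, -1, dtype=int)
    sizes: list[int] = []
    stds: list[float] = []
    stack = [np.arange(len(values))]
    while stack:
        roi = stack.pop()
        vals = values[roi]
        std = _pop_std(vals)
        assign = None
        if std >= std_threshold and roi.size >= min_size and roi.size >= 2:
            pos = coords[roi]
            span = pos.max(axis=0) - pos.min(axis=0)
            diag = float(np.linalg.norm(span))
            v_std = np.std(vals)
            z = (vals - vals.mean()) / v_std if v_std > 0 else np.zeros_like(vals)
            spatial = (
                proximity_weight * (pos - pos.mean(axis=0)) / diag
                if diag > 0
                else np.zeros_like(pos)
            )
            features = np.column_stack([z, spatial])
            assign = _two_means(features, max_iter=max_iter)
        if assign is None:
            idx = roi
            lbl = len(sizes)
            flat = coords[idx].astype(int)
            labels[flat[:, 0], flat[:, 1], flat[:, 2]] = lbl
            sizes.append(int(roi.size))
            stds.append(std)
        else:
            stack.append(roi[~assign])
            stack.append(roi[assign])
    return Decomposition(
        labels=labels,
        sizes=np.asarray(sizes),
        stds=np.asarray(stds),
        method="supervoxel",
        mask_size=total,
    )
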