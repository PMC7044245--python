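"""Per-voxel intratidal aeration, strain, and strain-rate metrics.

All metrics live in a single reference frame (default: phase 0).  Every
phase image is aligned to that frame through the pullback mapping
``T_{n->ref}``, after which:

* aeration change ``dI`` is the per-voxel intensity range over the cycle,
* regional volume is ``V_n = deltaV * det J_{n->ref}``,
* volumetric strain ``eps_n = (V_n - min_n V_n) / min_n V_n`` is referenced
  to the per-voxel minimum inflation state (so ``min_n eps_n == 0`` and the
  strain range ``d_eps = max_n eps_n``),
* strain rate uses periodic forward differences with ``dt = 1/(f0 N)``.

Spatial summaries report the mask mean, coefficient of variation, and
per-axis linear-regression gradients (signed and absolute, raw and
mean-normalized).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PeriodicImageSequence
from .transforms import (
    TransformSet,
    compose_pullback,
    identity_mapping,
    invert_transform,
    jacobian,
    warp_image,
)


def trim_mask(mask: np.ndarray, spacing, trim_mm: float = 6.0) -> np.ndarray:
    """Drop mask voxels within ``trim_mm`` of the axial (caudal-rostral)
    image boundaries, where tissue moving through the field of view corrupts
    registration."""
    if trim_mm < 0:
        raise ValueError("trim_mm must be non-negative")
    spacing = np.asarray(spacing, dtype=float)
    nz = mask.shape[2]
    z = np.arange(nz) * spacing[2]
    keep = (z >= trim_mm) & (z <= (nz - 1) * spacing[2] - trim_mm)
    out = mask.copy()
    out[:, :, ~keep] = False
    if not np.any(out):
        raise ValueError("boundary trim removed the entire mask")
    return out


def aeration_range(aligned: np.ndarray, valid: np.ndarray | None = None):
    """Per-voxel intensity range max_n - min_n over aligned phases.

    ``aligned`` has shape (N, nx, ny, nz); ``valid`` marks usable samples.
    Voxels with fewer than 2 valid samples get NaN and are reported in the
    returned count map.
    """
    aligned = np.asarray(aligned, dtype=float)
    if valid is None:
        valid = np.isfinite(aligned)
    data = np.where(valid, aligned, np.nan)
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        delta = np.nanmax(data, axis=0) - np.nanmin(data, axis=0)
    delta[n_valid < 2] = np.nan
    return delta, n_valid


def strain_series(volume_series: np.ndarray, mask: np.ndarray | None = None):
    """Volumetric strain referenced to the per-voxel minimum volume.

    Returns ``(eps, d_eps)`` where ``eps`` has shape (N, ...) and
    ``d_eps = max_n eps``.  Raises on non-positive minimum volume inside the
    mask (non-physical Jacobian).
    """
    v = np.asarray(volume_series, dtype=float)
    v_min = np.min(v, axis=0)
    check = v_min if mask is None else v_min[mask]
    if check.size and np.min(check) <= 0:
        raise ValueError("non-positive minimum volume inside mask")
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = (v - v_min[None]) / v_min[None]
    return eps, np.max(eps, axis=0)


def strain_rate_series(eps: np.ndarray, dt: float):
    """Periodic forward-difference strain rate and its range.

    ``eps_dot_n = (eps_{(n+1) mod N} - eps_n) / dt``;
    ``d_eps_dot = max_n eps_dot - min_n eps_dot`` (sum of the fastest
    inflation and deflation rates).
    """
    eps = np.asarray(eps, dtype=float)
    if eps.shape[0] < 2:
        raise ValueError("need at least 2 phases for strain rate")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rate = (np.roll(eps, -1, axis=0) - eps) / dt
    return rate, np.max(rate, axis=0) - np.min(rate, axis=0)


@dataclass
class SpatialSummary:
    """Mask mean, coefficient of variation, and per-axis linear gradients.

    Slopes are in field units per mm along (right-left, dorsal-ventral,
    caudal-rostral); normalized variants divide by the spatial mean (NaN when
    the mean is zero).
    """

    mean: float
    cov: float
    slope: np.ndarray  # (3,) signed, per mm
    slope_abs: np.ndarray
    slope_norm: np.ndarray
    slope_abs_norm: np.ndarray
    n_voxels: int


def spatial_summary(field: np.ndarray, mask: np.ndarray, spacing) -> SpatialSummary:
    """Summarise a scalar field over the analysis mask.

    Gradients come from three independent univariate ordinary-least-squares
    fits of field value against world coordinate along each principal
    anatomic axis, using every mask voxel as one observation.  The
    coefficient of variation uses the population standard deviation.
    """
    spacing = np.asarray(spacing, dtype=float)
    vals = np.asarray(field, dtype=float)[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    if not np.all(np.isfinite(vals)):
        raise ValueError("field must be finite on the mask")
    mean = float(np.mean(vals))
    cov = float(np.std(vals) / mean) if mean != 0 else np.nan
    idx = np.argwhere(mask)
    slope = np.empty(3)
    for axis in range(3):
        x = idx[:, axis] * spacing[axis]
        xc = x - x.mean()
        denom = np.sum(xc * xc)
        slope[axis] = np.sum(xc * (vals - mean)) / denom if denom > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = slope / mean if mean != 0 else np.full(3, np.nan)
    return SpatialSummary(
        mean=mean,
        cov=cov,
        slope=slope,
        slope_abs=np.abs(slope),
        slope_norm=norm,
        slope_abs_norm=np.abs(norm),
        n_voxels=int(vals.size),
    )


@dataclass
class VoxelMetricMaps:
    """Per-voxel metric maps in the reference frame."""

    delta_i: np.ndarray  # HU range
    eps: np.ndarray  # (N, ...) strain series
    delta_eps: np.ndarray  # strain range
    eps_rate: np.ndarray  # (N, ...) strain rate, s^-1
    delta_eps_rate: np.ndarray
    volume: np.ndarray  # (N, ...) mm^3
    det: np.ndarray  # (N, ...) det J_{n->ref}
    dt: float
    mask: np.ndarray  # analysis mask (trimmed, all phases valid)
    ref_phase: int


def compute_metric_maps(
    sequence: PeriodicImageSequence,
    transforms: TransformSet,
    ref_phase: int = 0,
    trim_mm: float = 6.0,
) -> VoxelMetricMaps:
    """Align every phase to ``ref_phase`` and compute all voxel metrics.

    The analysis mask is the reference-phase lung mask, boundary-trimmed,
    restricted to voxels whose pullback stays inside the image domain at
    every phase and whose numeric Jacobian stays positive.
    """
    N = sequence.n_phases
    if transforms.n_phases != N:
        raise ValueError("sequence and transforms disagree on phase count")
    spacing = sequence.spacing
    ref_phase = ref_phase % N
    u_ref = transforms[ref_phase]
    if np.max(np.abs(u_ref)) == 0:
        v_ref = np.zeros_like(u_ref)
    else:
        v_ref, _ = invert_transform(u_ref, spacing, mask=sequence.masks[ref_phase])

    shape = sequence.grid_shape
    aligned = np.empty((N,) + shape)
    valid = np.empty((N,) + shape, dtype=bool)
    det = np.empty((N,) + shape)
    for n in range(N):
        if n == ref_phase:
            mapping = identity_mapping(shape, spacing)
            ok = np.ones(shape, dtype=bool)
        else:
            mapping, ok = compose_pullback(transforms[n], v_ref, spacing)
        img, ok_w = warp_image(sequence.images[n], mapping, spacing)
        aligned[n] = img
        valid[n] = ok & ok_w
        det[n] = jacobian(mapping, spacing).det

    mask = trim_mask(sequence.masks[ref_phase], spacing, trim_mm)
    mask &= np.all(valid, axis=0)
    mask &= np.all(det > 0, axis=0)
    if not np.any(mask):
        raise ValueError("analysis mask is empty after validity filtering")

    delta_i, _ = aeration_range(aligned, valid)
    volume = sequence.voxel_volume * det
    eps, delta_eps = strain_series(volume, mask)
    rate, delta_rate = strain_rate_series(eps, sequence.dt)
    return VoxelMetricMaps(
        delta_i=delta_i,
        eps=eps,
        delta_eps=delta_eps,
        eps_rate=rate,
        delta_eps_rate=delta_rate,
        volume=volume,
        det=det,
        dt=sequence.dt,
        mask=mask,
        ref_phase=ref_phase,
    )


def summarize_maps(maps: VoxelMetricMaps, spacing) -> dict[str, SpatialSummary]:
    """Spatial summaries of the three range metrics over the analysis mask."""
    return {
        "delta_i": spatial_summary(maps.delta_i, maps.mask, spacing),
        "delta_eps": spatial_summary(maps.delta_eps, maps.mask, spacing),
        "delta_eps_rate": spatial_summary(maps.delta_eps_rate, maps.mask, spacing),
    }
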