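"""Periodic per-phase spatial transformations on regular 3D grids.

A ventilatory image sequence is modelled by ``N`` transformations
``phi_n(X) = X + u_n(X)`` mapping a common reference frame ``X`` (the grid of
the reference image) to each phase frame ``x_n``.  All fields are dense
displacement fields sampled on the reference grid, in millimetres, with axis
order (right-left, dorsal-ventral, caudal-rostral) and world coordinate =
0-based voxel index times spacing.

Alignment of two arbitrary phases ``n`` and ``m`` goes through the reference
frame: ``T_{n->m}(x_m) = phi_n(phi_m^{-1}(x_m))``.  The Jacobian of this
pullback mapping carries the local volume-change ratio: ``det J > 1`` is
expansion, ``det J < 1`` deflation, ``det J = 1`` isovolumetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates


@dataclass
class TransformSet:
    """Periodic set of N displacement fields on a common reference grid.

    Attributes
    ----------
    displacements : ndarray, shape (N, nx, ny, nz, 3)
        Displacement ``u_n`` in mm; ``phi_n(X) = X + u_n(X)``.
    spacing : ndarray, shape (3,)
        Voxel spacing in mm.
    f0 : float
        Fundamental ventilatory frequency in Hz.
    """

    displacements: np.ndarray
    spacing: np.ndarray
    f0: float

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.displacements.ndim != 5 or self.displacements.shape[-1] != 3:
            raise ValueError("displacements must have shape (N, nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacement fields must be finite")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive values (mm)")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")

    @property
    def n_phases(self) -> int:
        return self.displacements.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.displacements.shape[1:4])

    def __getitem__(self, n: int) -> np.ndarray:
        """Displacement field for phase ``n`` (periodic indexing mod N)."""
        return self.displacements[n % self.n_phases]


@dataclass
class JacobianField:
    """Per-voxel Jacobian matrices and determinants of a pullback mapping."""

    matrix: np.ndarray  # (nx, ny, nz, 3, 3)
    det: np.ndarray  # (nx, ny, nz)


def reference_grid_mm(shape, spacing) -> np.ndarray:
    """World coordinates (mm) of every voxel centre; shape (nx, ny, nz, 3)."""
    spacing = np.asarray(spacing, dtype=float)
    axes = [np.arange(s, dtype=float) * sp for s, sp in zip(shape, spacing)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return grid


def _sample_vector_field(field: np.ndarray, coords_vox: np.ndarray) -> np.ndarray:
    """Trilinear sampling of a vector field at fractional voxel coordinates.

    ``field`` has shape (nx, ny, nz, 3); ``coords_vox`` (..., 3) in voxel
    units.  Out-of-domain points use nearest-edge extension (the caller is
    responsible for validity masking).
    """
    pts = coords_vox.reshape(-1, 3).T
    out = np.empty((3, pts.shape[1]))
    for c in range(3):
        out[c] = map_coordinates(field[..., c], pts, order=1, mode="nearest")
    return out.T.reshape(coords_vox.shape)


def invert_transform(
    u: np.ndarray,
    spacing,
    tol_voxels: float = 0.01,
    max_iter: int = 50,
    mask: np.ndarray | None = None,
    fail_voxels: float = 0.5,
):
    """Invert ``phi(X) = X + u(X)`` by fixed-point iteration.

    Iterates ``v_{i+1}(x) = -u(x + v_i(x))`` from ``v_0 = 0`` until the max
    update is below ``tol_voxels`` (in voxel units) or ``max_iter`` is
    reached.  Returns ``(v, residual)`` where ``x + v(x)`` approximates
    ``phi^{-1}(x)`` and ``residual`` is the per-voxel round-trip error
    ``|phi(phi^{-1}(x)) - x|`` in voxel units.

    Raises RuntimeError if the residual exceeds ``fail_voxels`` anywhere in
    ``mask`` (whole grid when no mask is given).
    """
    spacing = np.asarray(spacing, dtype=float)
    u = np.asarray(u, dtype=float)
    u_vox = u / spacing
    grid_vox = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in u.shape[:3]], indexing="ij"),
        axis=-1,
    )
    v = np.zeros_like(u_vox)
    for _ in range(max_iter):
        v_new = -_sample_vector_field(u_vox, grid_vox + v)
        step = np.max(np.abs(v_new - v))
        v = v_new
        if step < tol_voxels:
            break
    # round-trip residual: phi(phi^{-1}(x)) - x = v(x) + u(x + v(x))
    residual = np.linalg.norm(v + _sample_vector_field(u_vox, grid_vox + v), axis=-1)
    check = residual if mask is None else residual[mask]
    if check.size and np.max(check) > fail_voxels:
        raise RuntimeError(
            f"displacement inversion did not converge: max round-trip residual "
            f"{np.max(check):.3f} voxels exceeds {fail_voxels}"
        )
    return v * spacing, residual


def compose_pullback(
    u_n: np.ndarray,
    v_m_inv: np.ndarray,
    spacing,
):
    """Pullback mapping ``T_{n->m}(x_m) = phi_n(phi_m^{-1}(x_m))`` on the m grid.

    Parameters
    ----------
    u_n : forward displacement of phase n (reference -> n), mm.
    v_m_inv : inverse displacement of phase m (``phi_m^{-1}(x) = x + v_m(x)``), mm.

    Returns
    -------
    mapping : ndarray (nx, ny, nz, 3)
        Target world coordinates (mm) in frame n for every m-grid voxel.
    valid : bool ndarray (nx, ny, nz)
        False where the intermediate or final point leaves the image domain.
    """
    spacing = np.asarray(spacing, dtype=float)
    if u_n.shape != v_m_inv.shape:
        raise ValueError("fields must share a grid")
    shape = u_n.shape[:3]
    grid_mm = reference_grid_mm(shape, spacing)
    ref_pts = grid_mm + v_m_inv  # X = phi_m^{-1}(x_m)
    ref_vox = ref_pts / spacing
    mapping = ref_pts + _sample_vector_field(u_n, ref_vox)  # phi_n(X)
    upper = (np.asarray(shape) - 1) * spacing
    valid = np.all((ref_pts >= 0) & (ref_pts <= upper), axis=-1)
    valid &= np.all((mapping >= 0) & (mapping <= upper), axis=-1)
    return mapping, valid


def warp_image(
    image: np.ndarray,
    mapping: np.ndarray,
    spacing,
    cval: float = np.nan,
):
    """Resample ``image`` at mapped points: ``I_{n->m}(x_m) = I_n(T(x_m))``.

    Points outside the domain receive ``cval`` and are reported invalid.
    """
    spacing = np.asarray(spacing, dtype=float)
    if mapping.shape[:3] != image.shape:
        raise ValueError("image and mapping grids differ")
    coords = (mapping / spacing).reshape(-1, 3).T
    out = map_coordinates(
        np.asarray(image, dtype=float), coords, order=1, mode="constant", cval=cval
    ).reshape(image.shape)
    upper = (np.asarray(image.shape) - 1) * spacing
    valid = np.all((mapping >= 0) & (mapping <= upper), axis=-1)
    return out, valid


def jacobian(mapping: np.ndarray, spacing) -> JacobianField:
    """Jacobian of a pullback mapping by finite differences.

    Central differences on the interior, one-sided at the grid boundaries,
    divided by the voxel spacing.  The identity mapping yields ``det == 1``.
    """
    spacing = np.asarray(spacing, dtype=float)
    if mapping.ndim != 4 or mapping.shape[-1] != 3:
        raise ValueError("mapping must have shape (nx, ny, nz, 3)")
    J = np.empty(mapping.shape[:3] + (3, 3))
    for comp in range(3):
        grads = np.gradient(mapping[..., comp], *spacing, edge_order=1)
        for axis in range(3):
            J[..., comp, axis] = grads[axis]
    det = np.linalg.det(J)
    return JacobianField(matrix=J, det=det)


def identity_mapping(shape, spacing) -> np.ndarray:
    """Identity pullback mapping (each voxel maps to itself)."""
    return reference_grid_mm(shape, spacing)
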