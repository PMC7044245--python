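"""Shared container types for periodic volumetric image data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PeriodicImageSequence:
    """N phase-binned 3D volumes over one ventilatory cycle.

    Attributes
    ----------
    images : ndarray (N, nx, ny, nz)
        CT intensities in HU; axis order (right-left, dorsal-ventral,
        caudal-rostral).
    masks : bool ndarray (N, nx, ny, nz)
        Per-phase lung masks.
    spacing : ndarray (3,)
        Voxel spacing in mm.
    f0 : float
        Fundamental ventilatory frequency (Hz).
    """

    images: np.ndarray
    masks: np.ndarray
    spacing: np.ndarray
    f0: float

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.masks = np.asarray(self.masks, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.images.ndim != 4:
            raise ValueError("images must have shape (N, nx, ny, nz)")
        if self.masks.shape != self.images.shape:
            raise ValueError("masks must match images in shape")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.n_phases < 3:
            raise ValueError("need at least 3 phases per cycle")

    @property
    def n_phases(self) -> int:
        return self.images.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.images.shape[1:])

    @property
    def dt(self) -> float:
        """Phase interval dt = 1 / (f0 N) in seconds."""
        return 1.0 / (self.f0 * self.n_phases)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume (mm^3)."""
        return float(np.prod(self.spacing))
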