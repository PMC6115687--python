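"""Grid-based containers shared across the pipeline.

All volumes use the axis convention ``array[i, j, k] -> (x, y, z)``: axis 0
of the array is the x axis, and vector fields store their components in the
same order.  Grids are isotropic; ``spacing_mm`` is the edge length of one
voxel in millimetres.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ImageVolume", "LabelVolume", "OrientationField"]


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid — the 'virtual micro-CT'."""

    data: np.ndarray
    spacing_mm: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"ImageVolume.data must be 3D, got ndim={self.data.ndim}")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelVolume:
    """A 3D integer region map sharing a grid with an ImageVolume."""

    data: np.ndarray
    spacing_mm: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LabelVolume.data must be 3D, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelVolume.data must be an integer array")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def labels_present(self) -> np.ndarray:
        return np.unique(self.data)


@dataclass
class OrientationField:
    """Per-voxel myocyte-chain direction (axial: f and -f are equivalent).

    ``vectors`` has shape (nx, ny, nz, 3) with unit norm on tissue voxels and
    zero elsewhere; ``coherence`` in [0, 1] scores how well defined the
    direction is (0 = isotropic structure tensor).
    """

    vectors: np.ndarray
    coherence: np.ndarray
    spacing_mm: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.coherence = np.asarray(self.coherence, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("OrientationField.vectors must have shape (nx,ny,nz,3)")
        if self.coherence.shape != self.vectors.shape[:3]:
            raise ValueError("coherence grid must match vectors grid")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    def tissue_mask(self, tol: float = 1e-8) -> np.ndarray:
        """Voxels carrying a (nonzero) direction vector."""
        return np.linalg.norm(self.vectors, axis=-1) > tol
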