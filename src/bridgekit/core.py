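"""Core spatial containers shared by every pipeline stage.

All grids use axis order ``(z, y, x)``; world coordinates are expressed in
micrometres (µm) in the same ``(z, y, x)`` component order.  Voxel indices are
0-based and refer to voxel *centers*: the world position of voxel ``(i, j, k)``
is ``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Volume",
    "BinaryMask",
    "LabelMask",
    "LandmarkSet",
    "GeometryError",
    "same_grid",
]


class GeometryError(ValueError):
    """Raised when grid geometry preconditions are violated."""


def _as_tuple3(value, name: str) -> tuple[float, float, float]:
    arr = np.asarray(value, dtype=float).ravel()
    if arr.size != 3:
        raise GeometryError(f"{name} must have 3 components, got {arr.size}")
    return tuple(arr.tolist())


@dataclass
class _Grid:
    """3D scalar grid with per-axis spacing and world origin (µm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(
                f"expected a 3D array (z, y, x); got ndim={self.data.ndim}"
            )
        self.spacing = _as_tuple3(self.spacing, "spacing")
        self.origin = _as_tuple3(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(np.prod(self.spacing))

    def world_extent(self) -> np.ndarray:
        """Edge-to-edge physical extent per axis in µm."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def index_to_world(self, indices) -> np.ndarray:
        """Map (fractional) voxel indices to world µm, voxel-center convention."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_index(self, points) -> np.ndarray:
        """Map world µm points to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (nz, ny, nx, 3)."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        return np.stack([zz, yy, xx], axis=-1)

    def with_data(self, data: np.ndarray):
        """Same geometry, new data array."""
        return replace(self, data=data)


@dataclass
class Volume(_Grid):
    """Scalar 3D volume.

    ``dtype_role`` documents the interpretation of the values:
    ``intensity`` (arbitrary units), ``density`` / ``probability`` (clamped to
    [0, 1] on construction).
    """

    dtype_role: str = "intensity"

    _ROLES = ("intensity", "density", "probability")

    def __post_init__(self):
        super().__post_init__()
        if self.dtype_role not in self._ROLES:
            raise GeometryError(f"unknown dtype_role {self.dtype_role!r}")
        if self.dtype_role in ("density", "probability"):
            self.data = np.clip(np.asarray(self.data, dtype=float), 0.0, 1.0)


@dataclass
class BinaryMask(_Grid):
    """Boolean 3D mask on the same grid contract as :class:`Volume`."""

    def __post_init__(self):
        super().__post_init__()
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelMask(_Grid):
    """Non-negative integer label grid; 0 is reserved for background."""

    def __post_init__(self):
        super().__post_init__()
        data = np.asarray(self.data)
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded):
                raise GeometryError("label data must be integer-valued")
            data = rounded.astype(np.int64)
        if data.min() < 0:
            raise GeometryError("labels must be non-negative (0 = background)")
        self.data = data.astype(np.int64, copy=False)

    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the mask."""
        values = np.unique(self.data)
        return values[values > 0]


def same_grid(a: _Grid, b: _Grid, atol: float = 1e-6) -> bool:
    """True when two grids share shape, spacing and origin (within ``atol`` µm)."""
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=atol)
        and np.allclose(a.origin, b.origin, atol=atol)
    )


@dataclass
class LandmarkSet:
    """Paired fixed/moving landmarks in world µm, (z, y, x) order.

    ``fixed_points[i]`` and ``moving_points[i]`` denote the same anatomical
    feature (typically a vessel bifurcation) in the two frames.
    """

    fixed_points: np.ndarray
    moving_points: np.ndarray
    names: Sequence[str] = field(default_factory=list)

    def __post_init__(self):
        self.fixed_points = np.atleast_2d(np.asarray(self.fixed_points, dtype=float))
        self.moving_points = np.atleast_2d(np.asarray(self.moving_points, dtype=float))
        if self.fixed_points.shape != self.moving_points.shape:
            raise ValueError(
                "fixed and moving point counts differ: "
                f"{self.fixed_points.shape[0]} vs {self.moving_points.shape[0]}"
            )
        if self.fixed_points.ndim != 2 or self.fixed_points.shape[1] not in (2, 3):
            raise ValueError("landmarks must be N×2 or N×3 arrays")
        if len(self) < 1:
            raise ValueError("at least one landmark pair is required")
        if not self.names:
            self.names = [f"L{i}" for i in range(len(self))]
        if len(self.names) != len(self):
            raise ValueError("names length must match landmark count")
        # duplicate fixed points make interpolating transforms singular
        from scipy.spatial.distance import pdist

        if len(self) > 1 and pdist(self.fixed_points).min() < 1e-6:
            raise ValueError("duplicate fixed points (within 1e-6 µm)")

    def __len__(self) -> int:
        return self.fixed_points.shape[0]

    @property
    def dim(self) -> int:
        return self.fixed_points.shape[1]

    def subset(self, indices) -> "LandmarkSet":
        idx = np.asarray(indices)
        return LandmarkSet(
            self.fixed_points[idx],
            self.moving_points[idx],
            [self.names[i] for i in np.atleast_1d(idx)],
        )

    def swapped(self) -> "LandmarkSet":
        """Exchange fixed and moving roles (used to refit inverse maps)."""
        return LandmarkSet(self.moving_points, self.fixed_points, list(self.names))
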