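"""Spatial transforms: rigid / similarity / affine maps, thin-plate splines,
displacement fields and sequential compositions.

A transform maps points (world µm, (z, y, x) order) from one frame into
another.  Throughout the registration pipeline transforms are fitted in the
*pull-back* direction — from the fixed/target frame into the moving frame —
because that is the direction volume resampling needs.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "SpatialTransform",
    "AffineTransform",
    "ThinPlateSplineTransform",
    "DisplacementFieldTransform",
    "ComposedTransform",
    "identity_transform",
    "rigid_from_euler",
    "compose_transforms",
    "transform_to_json",
    "transform_from_json",
]


class SpatialTransform:
    """Base class; concrete transforms implement :meth:`apply`."""

    kind: str = "abstract"
    dim: int = 3

    def apply(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.apply(points)

    def _check_points(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[-1] != self.dim:
            raise ValueError(
                f"dimension mismatch: transform is {self.dim}D, points are "
                f"{pts.shape[-1]}D"
            )
        return pts

    def to_dict(self) -> dict:
        raise NotImplementedError


class AffineTransform(SpatialTransform):
    """y = M x + t.  ``kind`` records the fitted model class.

    Invariants: for ``kind='rigid'`` M is a proper rotation (orthonormal,
    det +1); for ``kind='similarity'`` M = s·R with s > 0.
    """

    def __init__(self, matrix, translation, kind: str = "affine"):
        self.matrix = np.asarray(matrix, dtype=float)
        self.translation = np.asarray(translation, dtype=float).ravel()
        d = self.translation.size
        if self.matrix.shape != (d, d):
            raise ValueError("matrix/translation shape mismatch")
        self.dim = d
        self.kind = kind

    def apply(self, points):
        pts = self._check_points(points)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation, kind=self.kind)

    @property
    def scale(self) -> float:
        """Isotropic scale factor (meaningful for rigid/similarity kinds)."""
        return float(np.linalg.det(self.matrix)) ** (1.0 / self.dim)

    def to_dict(self):
        return {
            "type": "affine",
            "kind": self.kind,
            "dim": self.dim,
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
        }

    def __repr__(self):
        return f"AffineTransform(kind={self.kind!r}, dim={self.dim})"


def identity_transform(dim: int = 3) -> AffineTransform:
    return AffineTransform(np.eye(dim), np.zeros(dim), kind="rigid")


def rigid_from_euler(angles_deg, translation) -> AffineTransform:
    """3D rigid transform from extrinsic rotations about the z, y, x world
    axes (applied in that order) plus a translation, all in (z, y, x) order.

    Angles rotate within the coordinate planes of the (z, y, x) frame:
    ``angles_deg[0]`` rotates the (y, x) plane about the z axis, etc.
    """
    az, ay, ax = np.deg2rad(np.asarray(angles_deg, dtype=float))

    def _plane_rot(angle, fixed_axis):
        m = np.eye(3)
        other = [a for a in range(3) if a != fixed_axis]
        c, s = np.cos(angle), np.sin(angle)
        m[other[0], other[0]] = c
        m[other[0], other[1]] = -s
        m[other[1], other[0]] = s
        m[other[1], other[1]] = c
        return m

    rot = _plane_rot(ax, 2) @ _plane_rot(ay, 1) @ _plane_rot(az, 0)
    return AffineTransform(rot, translation, kind="rigid")


def _tps_kernel(r: np.ndarray, dim: int) -> np.ndarray:
    """Thin-plate radial kernel: U(r) = r for 3D, U(r) = r² log r for 2D."""
    if dim == 3:
        return r
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(r > 0, r * r * np.log(r), 0.0)
    return out


class ThinPlateSplineTransform(SpatialTransform):
    """Thin-plate spline interpolating source → target point pairs.

    With zero regularization the map is an exact interpolator at the source
    landmarks; a positive ``regularization`` trades exactness for smoothness
    (useful with noisy landmark clicks).
    """

    kind = "tps"

    def __init__(self, source_points, weights, affine, regularization: float = 0.0):
        self.source_points = np.asarray(source_points, dtype=float)
        self.weights = np.asarray(weights, dtype=float)
        self.affine = np.asarray(affine, dtype=float)  # (dim+1, dim): [t; M.T]
        self.regularization = float(regularization)
        self.dim = self.source_points.shape[1]

    @classmethod
    def fit(cls, source_points, target_points, regularization: float = 0.0):
        src = np.asarray(source_points, dtype=float)
        dst = np.asarray(target_points, dtype=float)
        n, d = src.shape
        if n < d + 2:
            raise ValueError(f"TPS needs at least {d + 2} landmarks in {d}D, got {n}")
        k = _tps_kernel(cdist(src, src), d) + regularization * np.eye(n)
        p = np.hstack([np.ones((n, 1)), src])
        lhs = np.zeros((n + d + 1, n + d + 1))
        lhs[:n, :n] = k
        lhs[:n, n:] = p
        lhs[n:, :n] = p.T
        rhs = np.zeros((n + d + 1, d))
        rhs[:n] = dst
        try:
            sol = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "degenerate landmark configuration for TPS (collinear/coplanar "
                "or duplicated points)"
            ) from exc
        return cls(src, sol[:n], sol[n:], regularization)

    def apply(self, points):
        pts = self._check_points(points)
        u = _tps_kernel(cdist(pts, self.source_points), self.dim)
        return u @ self.weights + np.hstack([np.ones((len(pts), 1)), pts]) @ self.affine

    @property
    def bending_energy(self) -> float:
        """Quadratic form wᵀ K w summed over output dimensions; zero iff the
        map is purely affine on the landmark set."""
        k = _tps_kernel(cdist(self.source_points, self.source_points), self.dim)
        return float(np.sum(self.weights * (k @ self.weights)))

    def to_dict(self):
        return {
            "type": "tps",
            "kind": "tps",
            "dim": self.dim,
            "source_points": self.source_points.tolist(),
            "weights": self.weights.tolist(),
            "affine": self.affine.tolist(),
            "regularization": self.regularization,
        }

    def __repr__(self):
        return (
            f"ThinPlateSplineTransform(dim={self.dim}, "
            f"n_landmarks={len(self.source_points)})"
        )


class DisplacementFieldTransform(SpatialTransform):
    """x ↦ x + u(x) with u interpolated from a coarse control grid.

    The control grid covers the field of view; displacements between control
    points are linearly interpolated (and linearly extrapolated outside),
    which guarantees max‖u‖ over space never exceeds the max over control
    points.
    """

    kind = "displacement"

    def __init__(self, grid_axes: Sequence[np.ndarray], displacements: np.ndarray):
        from scipy.interpolate import RegularGridInterpolator

        self.grid_axes = [np.asarray(a, dtype=float) for a in grid_axes]
        self.displacements = np.asarray(displacements, dtype=float)
        self.dim = len(self.grid_axes)
        if self.displacements.shape != tuple(len(a) for a in self.grid_axes) + (
            self.dim,
        ):
            raise ValueError("displacement grid shape mismatch")
        self._interp = RegularGridInterpolator(
            self.grid_axes,
            self.displacements,
            method="linear",
            bounds_error=False,
            fill_value=None,
        )

    def apply(self, points):
        pts = self._check_points(points)
        return pts + self._interp(pts)

    @property
    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.displacements, axis=-1).max())

    def to_dict(self):
        return {
            "type": "displacement",
            "kind": "displacement",
            "dim": self.dim,
            "grid_axes": [a.tolist() for a in self.grid_axes],
            "displacements": self.displacements.tolist(),
        }


class ComposedTransform(SpatialTransform):
    """Sequential application: ``apply`` runs transforms[0], then [1], ..."""

    kind = "composed"

    def __init__(self, transforms: Sequence[SpatialTransform]):
        transforms = list(transforms)
        if not transforms:
            raise ValueError("cannot compose an empty transform list")
        dims = {t.dim for t in transforms}
        if len(dims) != 1:
            raise ValueError(f"incompatible dimensionalities in chain: {dims}")
        self.transforms = transforms
        self.dim = transforms[0].dim

    def apply(self, points):
        pts = self._check_points(points)
        for t in self.transforms:
            pts = t.apply(pts)
        return pts

    def to_dict(self):
        return {
            "type": "composed",
            "kind": "composed",
            "dim": self.dim,
            "transforms": [t.to_dict() for t in self.transforms],
        }


def compose_transforms(transforms: Iterable[SpatialTransform]) -> SpatialTransform:
    """Compose a chain; contiguous affine members are folded into one matrix.

    The result maps points as sequential application, first element first.
    """
    transforms = list(transforms)
    if not transforms:
        raise ValueError("cannot compose an empty transform list")
    if all(isinstance(t, AffineTransform) for t in transforms):
        combined = transforms[0]
        for t in transforms[1:]:
            matrix = t.matrix @ combined.matrix
            translation = t.matrix @ combined.translation + t.translation
            kind = (
                combined.kind
                if combined.kind == t.kind
                else "affine"
            )
            combined = AffineTransform(matrix, translation, kind=kind)
        return combined
    if len(transforms) == 1:
        return transforms[0]
    return ComposedTransform(transforms)


# ---------------------------------------------------------------------------
# JSON serialization.  Files state the direction convention explicitly so a
# transform re-read months later is unambiguous.

_DIRECTION_NOTE = (
    "pull-back: maps fixed/target frame points (world um, z-y-x order) "
    "into the moving frame"
)


def transform_to_json(transform: SpatialTransform, path=None) -> str:
    payload = transform.to_dict()
    payload["direction"] = _DIRECTION_NOTE
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def _from_dict(payload: dict) -> SpatialTransform:
    t = payload["type"]
    if t == "affine":
        return AffineTransform(
            payload["matrix"], payload["translation"], kind=payload["kind"]
        )
    if t == "tps":
        return ThinPlateSplineTransform(
            payload["source_points"],
            payload["weights"],
            payload["affine"],
            payload.get("regularization", 0.0),
        )
    if t == "displacement":
        return DisplacementFieldTransform(
            payload["grid_axes"], np.asarray(payload["displacements"])
        )
    if t == "composed":
        return ComposedTransform([_from_dict(p) for p in payload["transforms"]])
    raise ValueError(f"unknown transform type {t!r}")


def transform_from_json(source) -> SpatialTransform:
    """Load a transform from a JSON string or file path."""
    text = source
    if not str(source).lstrip().startswith("{"):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    return _from_dict(json.loads(text))
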