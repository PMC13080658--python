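"""Landmark-based multimodal registration and volume resampling.

Fits rigid, similarity, affine and thin-plate-spline (elastic) maps to paired
landmarks, resamples volumes through pull-back transforms, reslices volumes to
an arbitrary plane (e.g. the cranial-window glass as a shared reference
plane), aligns longitudinal acquisitions with a rotation+translation model and
quantifies registration error with landmark RMSE, including a grid-based
inter-rater protocol.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage, optimize

from .core import BinaryMask, LandmarkSet, Volume, _Grid
from .transforms import (
    AffineTransform,
    ComposedTransform,
    SpatialTransform,
    ThinPlateSplineTransform,
    compose_transforms,
    identity_transform,
    rigid_from_euler,
)

__all__ = [
    "fit_landmark_transform",
    "apply_transform_to_points",
    "resample_volume",
    "resample_to_spacing",
    "reslice_to_plane",
    "match_grid_xy",
    "register_longitudinal",
    "compose_transforms",
    "landmark_rmse",
    "make_rater_grid",
    "interrater_rmse",
    "heldout_rmse",
    "RegistrationError",
]


class RegistrationError(RuntimeError):
    """Raised when an optimization-based registration fails."""


# ---------------------------------------------------------------------------
# Landmark fits

def _check_degeneracy(points: np.ndarray, need_rank: int) -> None:
    centered = points - points.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    scale = svals[0] if svals[0] > 0 else 1.0
    rank = int(np.sum(svals > 1e-9 * scale))
    if rank < need_rank:
        shape = {0: "coincident", 1: "collinear", 2: "coplanar"}.get(rank, "degenerate")
        raise ValueError(
            f"degenerate landmark configuration: points are {shape} "
            f"(rank {rank}, need {need_rank})"
        )


def _fit_orthogonal(fixed, moving, with_scale: bool):
    """Closed-form least-squares rigid/similarity fit (Kabsch/Umeyama),
    mapping fixed → moving."""
    mu_f = fixed.mean(axis=0)
    mu_m = moving.mean(axis=0)
    x = fixed - mu_f
    y = moving - mu_m
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.ones(fixed.shape[1])
    corr[-1] = d
    rot = vt.T @ np.diag(corr) @ u.T
    if with_scale:
        var = np.sum(x * x)
        scale = np.sum(s * corr) / var
    else:
        scale = 1.0
    matrix = scale * rot
    translation = mu_m - matrix @ mu_f
    return matrix, translation


def fit_landmark_transform(
    landmarks: LandmarkSet,
    kind: str,
    regularization: float = 0.0,
    min_tps_landmarks: int = 5,
) -> SpatialTransform:
    """Fit a transform mapping fixed-frame points onto moving-frame points.

    This is the pull-back direction used for resampling: with the MRI as
    fixed volume and the microscopy stack as moving volume, the fitted map
    carries MRI voxel centers into microscopy coordinates.

    kind : {'rigid', 'similarity', 'affine', 'tps'}
        'tps' is the elastic mode; with ``regularization=0`` (default) it
        interpolates the landmark pairs exactly.
    """
    fixed = landmarks.fixed_points
    moving = landmarks.moving_points
    n, d = fixed.shape
    if kind in ("rigid", "similarity"):
        if n < d:
            raise ValueError(f"{kind} fit needs ≥ {d} landmarks in {d}D, got {n}")
        _check_degeneracy(fixed, 2 if d == 3 else 1)
        matrix, translation = _fit_orthogonal(fixed, moving, kind == "similarity")
        return AffineTransform(matrix, translation, kind=kind)
    if kind == "affine":
        if n < d + 1:
            raise ValueError(f"affine fit needs ≥ {d + 1} landmarks in {d}D, got {n}")
        _check_degeneracy(fixed, d)
        design = np.hstack([fixed, np.ones((n, 1))])
        sol, *_ = np.linalg.lstsq(design, moving, rcond=None)
        return AffineTransform(sol[:d].T, sol[d], kind="affine")
    if kind == "tps":
        if n < max(min_tps_landmarks, d + 2):
            raise ValueError(
                f"tps fit needs ≥ {max(min_tps_landmarks, d + 2)} landmarks, got {n}"
            )
        _check_degeneracy(fixed, d)
        return ThinPlateSplineTransform.fit(fixed, moving, regularization)
    raise ValueError(f"unknown transform kind {kind!r}")


def apply_transform_to_points(transform: SpatialTransform, points) -> np.ndarray:
    """Forward-map points (world µm) through a transform."""
    return transform.apply(points)


# ---------------------------------------------------------------------------
# Resampling

def resample_volume(
    moving: Volume | BinaryMask,
    transform: SpatialTransform,
    target: _Grid,
    interpolation: str = "linear",
    fill: float = 0.0,
):
    """Resample ``moving`` onto the grid of ``target``.

    ``transform`` must map target-frame world coordinates into moving-frame
    world coordinates (pull-back convention).  Out-of-field voxels are set to
    ``fill``.  Masks should use nearest interpolation.
    """
    orders = {"linear": 1, "nearest": 0}
    if interpolation not in orders:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    centers = target.voxel_centers().reshape(-1, 3)
    mapped = transform.apply(centers)
    idx = moving.world_to_index(mapped).T  # (3, N) fractional indices
    is_mask = isinstance(moving, BinaryMask)
    data = moving.data.astype(float) if is_mask else np.asarray(moving.data, float)
    out = ndimage.map_coordinates(
        data, idx, order=orders[interpolation], mode="constant", cval=fill
    ).reshape(target.shape)
    if is_mask:
        return BinaryMask(out > 0.5, target.spacing, target.origin)
    role = getattr(moving, "dtype_role", "intensity")
    return Volume(out, target.spacing, target.origin, dtype_role=role)


def _edge_aligned_grid(volume: _Grid, new_spacing) -> tuple:
    """Shape/origin of a grid with ``new_spacing`` covering the same
    edge-to-edge world extent (voxel-center convention)."""
    new_spacing = np.asarray(new_spacing, dtype=float)
    extent = volume.world_extent()
    shape = np.maximum(1, np.rint(extent / new_spacing).astype(int))
    edge = np.asarray(volume.origin) - np.asarray(volume.spacing) / 2.0
    origin = edge + new_spacing / 2.0
    return tuple(shape), tuple(origin.tolist())


def resample_to_spacing(
    volume: Volume | BinaryMask, new_spacing, interpolation: str = "linear"
):
    """Resample onto a grid of the requested spacing covering the same
    physical extent (identity transform)."""
    shape, origin = _edge_aligned_grid(volume, new_spacing)
    target = Volume(np.zeros(shape), tuple(np.asarray(new_spacing, float)), origin)
    return resample_volume(volume, identity_transform(3), target, interpolation)


def reslice_to_plane(volume: Volume, point, normal):
    """Reslice a volume so its z-axis is parallel to ``normal``.

    The reslicing plane (e.g. the cranial window glass shared by MRI and
    microscopy) is given by a point on the plane and its normal, both in
    world µm (z, y, x).  Returns the resliced volume and the rigid transform
    mapping new-frame world coordinates back into the old frame.
    """
    point = np.asarray(point, dtype=float)
    normal = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        raise ValueError("plane normal must be nonzero")
    e_z = normal / norm
    # helper axis: keep old y when possible so an axis-aligned normal yields
    # a pure axis permutation
    helper = np.array([0.0, 1.0, 0.0])
    if abs(e_z @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e_y = helper - (helper @ e_z) * e_z
    e_y /= np.linalg.norm(e_y)
    e_x = np.cross(e_z, e_y)
    rot = np.stack([e_z, e_y, e_x])  # rows: new axes in old coordinates

    corners = np.array(list(itertools.product(*[(0, s - 1) for s in volume.shape])))
    corners_w = volume.index_to_world(corners)
    corners_new = (corners_w - point) @ rot.T
    spacing_new = np.sqrt(rot**2 @ np.asarray(volume.spacing, float) ** 2)
    lo = corners_new.min(axis=0)
    hi = corners_new.max(axis=0)
    shape = np.maximum(1, np.rint((hi - lo) / spacing_new).astype(int) + 1)
    new_to_old = AffineTransform(rot.T, point, kind="rigid")
    target = Volume(np.zeros(tuple(shape)), tuple(spacing_new), tuple(lo))
    resliced = resample_volume(volume, new_to_old, target, "linear")
    resliced.dtype_role = volume.dtype_role
    return resliced, new_to_old


def match_grid_xy(mri: Volume, target_xy_spacing: float) -> Volume:
    """Upscale the in-plane (y, x) resolution of an MRI volume to match the
    microscopy pixel size; the z axis is untouched.

    Linear interpolation with linear extrapolation at the borders, so linear
    intensity ramps are reproduced exactly; the world extent is preserved to
    within one target voxel.
    """
    from scipy.interpolate import RegularGridInterpolator

    target_xy_spacing = float(target_xy_spacing)
    new_spacing = (mri.spacing[0], target_xy_spacing, target_xy_spacing)
    shape, origin = _edge_aligned_grid(mri, new_spacing)
    shape = (mri.shape[0], shape[1], shape[2])
    origin = (mri.origin[0], origin[1], origin[2])

    y_old = mri.origin[1] + np.arange(mri.shape[1]) * mri.spacing[1]
    x_old = mri.origin[2] + np.arange(mri.shape[2]) * mri.spacing[2]
    y_new = origin[1] + np.arange(shape[1]) * new_spacing[1]
    x_new = origin[2] + np.arange(shape[2]) * new_spacing[2]
    yy, xx = np.meshgrid(y_new, x_new, indexing="ij")
    query = np.stack([yy.ravel(), xx.ravel()], axis=-1)

    out = np.empty(shape, dtype=float)
    for z in range(mri.shape[0]):
        if mri.shape[1] == 1 or mri.shape[2] == 1:
            # degenerate in-plane axis: constant continuation
            interp = RegularGridInterpolator(
                (y_old, x_old), np.asarray(mri.data[z], float),
                method="nearest", bounds_error=False, fill_value=None,
            )
        else:
            interp = RegularGridInterpolator(
                (y_old, x_old), np.asarray(mri.data[z], float),
                method="linear", bounds_error=False, fill_value=None,
            )
        out[z] = interp(query).reshape(shape[1:])
    return Volume(out, new_spacing, origin, dtype_role=mri.dtype_role)


# ---------------------------------------------------------------------------
# Longitudinal (rotation + translation) registration

def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    a = a[mask]
    b = b[mask]
    if a.size < 10:
        return -1.0
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def register_longitudinal(
    moving: Volume,
    reference: Volume,
    landmarks: LandmarkSet | None = None,
    max_rotation_deg: float = 10.0,
    n_starts: int = 7,
) -> AffineTransform:
    """Align a follow-up acquisition to the first timepoint with a rigid
    rotation+translation model (no scaling).

    With ``landmarks`` the fit is closed-form.  Otherwise a multi-start local
    search maximizes normalized cross-correlation of the resampled moving
    volume against the reference; among equally good optima the
    lowest-parameter-norm solution wins, so the output is deterministic.
    The returned transform is the pull-back map (reference frame → moving
    frame) ready for :func:`resample_volume`.
    """
    if landmarks is not None:
        return fit_landmark_transform(landmarks, "rigid")

    center = np.asarray(reference.origin) + (
        (np.asarray(reference.shape) - 1) / 2.0 * np.asarray(reference.spacing)
    )

    def _transform_from(params):
        angles = params[:3]
        shift = params[3:]
        rot = rigid_from_euler(angles, (0.0, 0.0, 0.0))
        # rotate about the reference center, then translate
        translation = center - rot.matrix @ center + shift
        return AffineTransform(rot.matrix, translation, kind="rigid")

    ones = Volume(np.ones(moving.shape), moving.spacing, moving.origin)

    def _cost(params):
        t = _transform_from(params)
        res = resample_volume(moving, t, reference, "linear", fill=0.0)
        support = resample_volume(ones, t, reference, "linear", fill=0.0)
        mask = support.data > 0.5
        if mask.mean() < 0.5:
            return 2.0  # < 50% overlap: reject
        return -_ncc(res.data, reference.data, mask)

    rng_starts = [np.zeros(6)]
    span = np.asarray(reference.world_extent())
    for axis in range(3):
        for sign in (1.0, -1.0):
            p = np.zeros(6)
            p[axis] = sign * max_rotation_deg / 2.0
            rng_starts.append(p)
    rng_starts = rng_starts[:n_starts]

    best = None
    scale = np.array([1.0] * 3 + list(span / 20.0))
    for start in rng_starts:
        res = optimize.minimize(
            lambda q: _cost(q * scale),
            start / scale,
            method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 2000},
        )
        params = res.x * scale
        key = (round(float(res.fun), 9), float(np.linalg.norm(res.x)))
        if best is None or key < best[0]:
            best = (key, params, res)
    if best is None or best[0][0] >= 1.0:
        raise RegistrationError(
            "intensity-based registration failed: no parameter set achieved "
            "positive correlation with ≥ 50% overlap "
            f"(best cost {None if best is None else best[0][0]})"
        )
    return _transform_from(best[1])


# ---------------------------------------------------------------------------
# Registration-error metrics

def landmark_rmse(points_a, points_b) -> float:
    """Root mean square distance between paired points, in µm."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("point sets must have equal shape")
    if a.shape[0] == 0:
        raise ValueError("RMSE of zero points is undefined")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def make_rater_grid(geometry: _Grid, rows: int = 50, cols: int = 50) -> np.ndarray:
    """World coordinates of a rows×cols in-plane grid on every slice of a
    volume, the coordinate system used for inter-rater comparison."""
    nz = geometry.shape[0]
    z = np.arange(nz)
    j = np.linspace(0, geometry.shape[1] - 1, rows)
    i = np.linspace(0, geometry.shape[2] - 1, cols)
    zz, jj, ii = np.meshgrid(z, j, i, indexing="ij")
    idx = np.stack([zz.ravel(), jj.ravel(), ii.ravel()], axis=-1)
    return geometry.index_to_world(idx)


def interrater_rmse(
    grid_points: np.ndarray,
    chain_rater1: SpatialTransform,
    chain_rater2: SpatialTransform,
    sample_n: int | None = None,
    seed: int = 0,
) -> float:
    """Average RMSE between two raters' transform chains evaluated on a
    shared coordinate grid.

    ``sample_n`` draws a random subset of grid coordinates (deterministic
    under ``seed``); None evaluates the full grid.
    """
    pts = np.atleast_2d(np.asarray(grid_points, dtype=float))
    if sample_n is not None and sample_n < len(pts):
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(len(pts), size=sample_n, replace=False)]
    a = chain_rater1.apply(pts)
    b = chain_rater2.apply(pts)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("transform chains produced non-finite coordinates "
                         "(disjoint domains?)")
    return landmark_rmse(a, b)


def heldout_rmse(
    landmarks: LandmarkSet,
    kind: str,
    leave_out: int = 1,
    regularization: float = 0.0,
    min_tps_landmarks: int = 5,
) -> float:
    """Leave-k-out cross-validated landmark RMSE for one transform kind.

    Each round drops ``leave_out`` consecutive landmarks, fits on the rest
    and evaluates the prediction error at the held-out pairs; errors are
    pooled into a single RMSE (µm).
    """
    n = len(landmarks)
    if n <= leave_out:
        raise ValueError("not enough landmarks to hold any out")
    errors = []
    for start in range(0, n, leave_out):
        held = np.arange(start, min(start + leave_out, n))
        kept = np.setdiff1d(np.arange(n), held)
        try:
            t = fit_landmark_transform(
                landmarks.subset(kept), kind,
                regularization=regularization,
                min_tps_landmarks=min_tps_landmarks,
            )
        except ValueError:
            continue
        pred = t.apply(landmarks.fixed_points[held])
        errors.append(pred - landmarks.moving_points[held])
    if not errors:
        raise ValueError("no valid held-out folds")
    diff = np.vstack(errors)
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
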