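"""Synthetic co-registered microscopy/MRI scenes with known ground truth.

Every downstream stage of the pipeline is validated against scenes generated
here: random branching vessel trees with known centerlines, radii and flow
velocities; tumor density fields; sequence-specific MRI contrast with known
sign conventions; known rigid/affine/smooth deformations with exact landmark
pairs; streaked kymographs with known streak slope; and longitudinal tumor
series with a known growth rate.

Every generator is a pure function of its parameters and an explicit integer
seed; no global random state is touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BinaryMask, LandmarkSet, Volume
from .transforms import (
    AffineTransform,
    DisplacementFieldTransform,
    SpatialTransform,
    rigid_from_euler,
)
from .vessels import Kymograph

__all__ = [
    "VesselSegment",
    "PhantomScene",
    "generate_vessel_tree",
    "make_tumor_field",
    "rasterize_microscopy",
    "simulate_mri",
    "apply_synthetic_deformation",
    "generate_kymograph",
    "generate_longitudinal_series",
]


@dataclass
class VesselSegment:
    """One vessel branch: a centerline polyline (world µm), a linearly
    tapering radius and a flow velocity."""

    points: np.ndarray  # (M, 3) world µm, (z, y, x)
    radius_start: float  # µm
    radius_end: float  # µm
    flow_velocity: float  # mm/s
    root_id: int = 0
    depth: int = 0

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2:
            raise ValueError("segment polyline needs at least 2 points")
        if self.radius_start <= 0 or self.radius_end <= 0:
            raise ValueError("segment radius must be positive")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def mean_radius(self) -> float:
        return 0.5 * (self.radius_start + self.radius_end)


@dataclass
class PhantomScene:
    """Ground-truth scene: vessel segments, optional tumor density field,
    optional applied deformation, and the seed that generated it."""

    segments: list
    extent: tuple[float, float, float]
    tumor_field: Volume | None = None
    deformation: SpatialTransform | None = None
    seed: int = 0
    bifurcations: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def segment_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "root_id": [s.root_id for s in self.segments],
                "depth": [s.depth for s in self.segments],
                "radius_start_um": [s.radius_start for s in self.segments],
                "radius_end_um": [s.radius_end for s in self.segments],
                "length_um": [s.length for s in self.segments],
                "velocity_mm_s": [s.flow_velocity for s in self.segments],
            }
        )


# ---------------------------------------------------------------------------
# Vessel tree generation

def _unit(v):
    return v / np.linalg.norm(v)


def _perpendicular(direction, rng):
    trial = rng.normal(size=3)
    trial -= trial @ direction * direction
    return _unit(trial)


def generate_vessel_tree(
    extent,
    n_roots: int = 2,
    max_depth: int = 3,
    radius_range=(10.0, 60.0),
    murray_exponent: float = 3.0,
    branch_angle_deg: float = 35.0,
    velocity_max: float = 8.0,
    points_per_segment: int = 6,
    wiggle: float = 0.06,
    seed: int = 0,
) -> PhantomScene:
    """Random binary branching vessel trees inside a box of ``extent`` µm.

    Roots enter through the z=0 face; at each bifurcation child radii decay
    with a Murray-type rule r_child = r_parent · 2^(−1/murray_exponent)
    (clamped to ``radius_range``), and branch directions deviate by
    ``branch_angle_deg`` around the parent direction.  Flow velocity scales
    linearly with radius up to ``velocity_max`` mm/s — larger vessels carry
    faster flow, which gives the TOF phantom its known monotone contrast.
    Deterministic under ``seed``; each root yields one connected tree.
    """
    extent = np.asarray(extent, dtype=float) * np.ones(3)
    if np.any(extent <= 0):
        raise ValueError("extent must be positive on every axis")
    r_min, r_max = float(radius_range[0]), float(radius_range[1])
    if not (0 < r_min <= r_max <= extent.min() / 4.0):
        raise ValueError(
            f"radius range {radius_range} must lie within (0, extent/4] "
            f"= (0, {extent.min() / 4.0}]"
        )
    rng = np.random.default_rng(seed)
    decay = 2.0 ** (-1.0 / murray_exponent)
    segments: list[VesselSegment] = []
    bifurcations: list[np.ndarray] = []
    base_length = extent.min() / 2.5
    margin = r_max

    def _grow(start, direction, radius, depth, root_id):
        length = base_length * (0.75**depth) * rng.uniform(0.8, 1.2)
        radius_end = max(r_min, radius * rng.uniform(0.9, 1.0))
        ts = np.linspace(0.0, 1.0, points_per_segment)
        pts = start + np.outer(ts * length, direction)
        perp = _perpendicular(direction, rng)
        pts += np.outer(
            np.sin(ts * np.pi) * length * wiggle * rng.uniform(-1, 1), perp
        )
        pts = np.clip(pts, margin, extent - margin)
        seg = VesselSegment(pts, radius, radius_end, 0.0, root_id, depth)
        seg.flow_velocity = velocity_max * seg.mean_radius / r_max
        segments.append(seg)
        end = pts[-1]
        child_r = max(r_min, radius_end * decay)
        if depth + 1 > max_depth or radius_end * decay < r_min:
            return
        bifurcations.append(end.copy())
        axis = _perpendicular(direction, rng)
        angle = np.deg2rad(branch_angle_deg * rng.uniform(0.7, 1.3))
        for sign in (1.0, -1.0):
            child_dir = _unit(
                np.cos(sign * angle) * direction + np.sin(sign * angle) * axis
            )
            _grow(end, child_dir, child_r, depth + 1, root_id)

    for root in range(n_roots):
        start = np.array(
            [
                margin,
                rng.uniform(0.25, 0.75) * extent[1],
                rng.uniform(0.25, 0.75) * extent[2],
            ]
        )
        direction = _unit(np.array([1.0, rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.3)]))
        _grow(start, direction, r_max, 0, root)

    return PhantomScene(
        segments=segments,
        extent=tuple(extent.tolist()),
        seed=seed,
        bifurcations=np.asarray(bifurcations) if bifurcations else np.zeros((0, 3)),
    )


def make_tumor_field(
    extent, spacing, kind: str = "gradient", max_density: float = 1.0, seed: int = 0
) -> Volume:
    """Tumor density field on a grid covering ``extent``.

    'gradient' keeps the first quarter of the x axis tumor-free (normal
    parenchyma adjacent to the lesion) and ramps density linearly to
    ``max_density`` across the rest, covering every density bin; 'blob' is a
    Gaussian focus in the box center, emulating a bulky lesion.
    """
    extent = np.asarray(extent, dtype=float) * np.ones(3)
    spacing = np.asarray(spacing, dtype=float) * np.ones(3)
    shape = np.maximum(1, np.rint(extent / spacing).astype(int))
    origin = spacing / 2.0
    centers_x = origin[2] + np.arange(shape[2]) * spacing[2]
    if kind == "gradient":
        frac = centers_x / extent[2]
        profile = np.clip((frac - 0.25) / 0.75, 0.0, 1.0) * max_density
        data = np.broadcast_to(profile, tuple(shape)).copy()
    elif kind == "blob":
        zz, yy, xx = np.meshgrid(
            *[origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)],
            indexing="ij",
        )
        center = extent / 2.0
        sigma = extent / 5.0
        data = max_density * np.exp(
            -(
                (zz - center[0]) ** 2 / (2 * sigma[0] ** 2)
                + (yy - center[1]) ** 2 / (2 * sigma[1] ** 2)
                + (xx - center[2]) ** 2 / (2 * sigma[2] ** 2)
            )
        )
    else:
        raise ValueError(f"unknown tumor field kind {kind!r}")
    return Volume(data, tuple(spacing), tuple(origin), dtype_role="density")


# ---------------------------------------------------------------------------
# Rasterization

def _scene_grid(scene: PhantomScene, spacing):
    spacing = np.asarray(spacing, dtype=float) * np.ones(3)
    extent = np.asarray(scene.extent, dtype=float)
    shape = np.maximum(1, np.rint(extent / spacing).astype(int))
    origin = spacing / 2.0
    return tuple(shape), tuple(spacing.tolist()), tuple(origin.tolist())


def _rasterize_segments(scene: PhantomScene, shape, spacing, origin):
    """Binary tube indicator + per-voxel flow velocity map (max over
    overlapping segments)."""
    spacing = np.asarray(spacing)
    origin = np.asarray(origin)
    mask = np.zeros(shape, dtype=bool)
    flow = np.zeros(shape, dtype=float)
    shape_arr = np.asarray(shape)
    for seg in scene.segments:
        radii = np.linspace(seg.radius_start, seg.radius_end, len(seg.points))
        for a in range(len(seg.points) - 1):
            p0, p1 = seg.points[a], seg.points[a + 1]
            r0, r1 = radii[a], radii[a + 1]
            rmax = max(r0, r1)
            lo_w = np.minimum(p0, p1) - rmax - spacing
            hi_w = np.maximum(p0, p1) + rmax + spacing
            lo = np.maximum(np.floor((lo_w - origin) / spacing).astype(int), 0)
            hi = np.minimum(np.ceil((hi_w - origin) / spacing).astype(int) + 1, shape_arr)
            if np.any(lo >= hi):
                continue
            axes = [origin[i] + np.arange(lo[i], hi[i]) * spacing[i] for i in range(3)]
            zz, yy, xx = np.meshgrid(*axes, indexing="ij")
            pts = np.stack([zz, yy, xx], axis=-1)
            d = p1 - p0
            dd = d @ d
            if dd == 0:
                continue
            t = np.clip(((pts - p0) @ d) / dd, 0.0, 1.0)
            closest = p0 + t[..., None] * d
            dist2 = np.sum((pts - closest) ** 2, axis=-1)
            radius_here = r0 + (r1 - r0) * t
            inside = dist2 <= radius_here**2
            window = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
            mask[window] |= inside
            np.maximum(
                flow[window], np.where(inside, seg.flow_velocity, 0.0),
                out=flow[window],
            )
    return mask, flow


def rasterize_microscopy(
    scene: PhantomScene,
    spacing,
    channels=("vessel",),
    noise_sigma: float = 0.0,
    psf_sigma: float = 0.0,
    seed: int = 0,
) -> dict:
    """Render microscopy channels of a scene at the given spacing (µm).

    The vessel channel is the tube indicator blurred by a Gaussian PSF of
    ``psf_sigma`` µm with additive Gaussian noise; the tumor channel resamples
    the scene's density field.  Pre-noise binary ground-truth masks are
    emitted alongside (keys ``<channel>_mask``).  With zero noise and zero
    PSF the vessel channel equals the indicator exactly.
    """
    shape, spacing_t, origin = _scene_grid(scene, spacing)
    min_radius = min((s.mean_radius for s in scene.segments), default=np.inf)
    if np.asarray(spacing_t).max() > min_radius / 2.0:
        warnings.warn(
            f"spacing {spacing_t} exceeds half the smallest vessel radius "
            f"({min_radius:.1f} µm); rasterization will be coarse"
        )
    rng = np.random.default_rng(seed)
    out: dict = {}
    for channel in channels:
        if channel == "vessel":
            mask, _ = _rasterize_segments(scene, shape, spacing_t, origin)
            image = mask.astype(float)
            out["vessel_mask"] = BinaryMask(mask, spacing_t, origin)
        elif channel == "tumor":
            if scene.tumor_field is None:
                raise ValueError("scene has no tumor field")
            from .registration import resample_volume
            from .transforms import identity_transform

            target = Volume(np.zeros(shape), spacing_t, origin)
            image = resample_volume(
                scene.tumor_field, identity_transform(3), target, "linear"
            ).data
            out["tumor_mask"] = BinaryMask(image > 0.5, spacing_t, origin)
        else:
            raise ValueError(f"unknown channel {channel!r}")
        if psf_sigma > 0:
            image = ndimage.gaussian_filter(
                image, sigma=np.asarray(psf_sigma) / np.asarray(spacing_t)
            )
        if noise_sigma > 0:
            image = image + rng.normal(0.0, noise_sigma, size=image.shape)
        out[channel] = Volume(image, spacing_t, origin)
    return out


# ---------------------------------------------------------------------------
# MRI simulation

def simulate_mri(
    scene: PhantomScene,
    spacing,
    sequence: str,
    baseline: float = 100.0,
    k_vessel: float = 40.0,
    k_tumor: float = 30.0,
    k_flow: float = 20.0,
    noise_sigma: float = 0.0,
    subdivision: int = 4,
    seed: int = 0,
) -> tuple[Volume, dict]:
    """Simulate an MRI volume with the contrast directions observed in vivo.

    T2w/T2*w: intensity = baseline − k_vessel·(vessel volume fraction)
    + k_tumor·(tumor density) + noise — blood vessels are hypointense,
    tumor is hyperintense.  TOF: baseline + k_flow·(flow-weighted vessel
    fraction) + noise — faster flow, brighter voxel.  Per-voxel fractions
    are computed by rasterizing at ``spacing/subdivision`` and
    block-averaging, and are returned as ground truth alongside the image.
    """
    if sequence not in ("t2w", "t2star", "tof"):
        raise ValueError(f"unknown MRI sequence {sequence!r}")
    shape, spacing_t, origin = _scene_grid(scene, spacing)
    fine_spacing = np.asarray(spacing_t) / subdivision
    fine_shape = tuple(int(s * subdivision) for s in shape)
    fine_origin = fine_spacing / 2.0
    mask, flow = _rasterize_segments(scene, fine_shape, fine_spacing, fine_origin)

    def _block_mean(arr):
        view = arr.reshape(
            shape[0], subdivision, shape[1], subdivision, shape[2], subdivision
        )
        return view.mean(axis=(1, 3, 5))

    vessel_fraction = _block_mean(mask.astype(float))
    flow_weighted = _block_mean(flow)
    if scene.tumor_field is not None:
        from .registration import resample_volume
        from .transforms import identity_transform

        target = Volume(np.zeros(shape), spacing_t, origin)
        tumor = resample_volume(
            scene.tumor_field, identity_transform(3), target, "linear"
        ).data
    else:
        tumor = np.zeros(shape)

    if sequence in ("t2w", "t2star"):
        image = baseline - k_vessel * vessel_fraction + k_tumor * tumor
    else:
        image = baseline + k_flow * flow_weighted
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    truth = {
        "vessel_fraction": Volume(
            vessel_fraction, spacing_t, origin, dtype_role="density"
        ),
        "flow_weighted": Volume(flow_weighted, spacing_t, origin),
        "tumor_density": Volume(tumor, spacing_t, origin, dtype_role="density"),
    }
    return Volume(image, spacing_t, origin), truth


# ---------------------------------------------------------------------------
# Synthetic deformation

def apply_synthetic_deformation(
    volume: Volume,
    spec: dict,
    seed: int = 0,
    landmark_points=None,
    n_landmarks: int = 10,
):
    """Deform a volume by a known transform and emit exact landmark pairs.

    ``spec['kind']``:
      * 'rigid'  — rotation_deg (z, y, x) + translation µm
      * 'affine' — explicit matrix + translation
      * 'smooth' — random smooth displacement with ``amplitude`` µm (max
        vector norm, enforced exactly) from a coarse control grid
        (``control_spacing`` µm, default extent/3)

    The transform is the pull-back map (deformed frame → source frame), so
    the deformed volume and the returned (fixed, moving) landmark pairs are
    exactly consistent: ``moving = T(fixed)``.  ``landmark_points`` (e.g.
    scene bifurcations) define the fixed points; without them, random
    interior points are drawn.

    Returns ``(deformed_volume, landmarks, transform)``.
    """
    from .registration import resample_volume

    rng = np.random.default_rng(seed)
    extent = volume.world_extent()
    kind = spec.get("kind")
    if kind == "rigid":
        transform = rigid_from_euler(
            spec.get("rotation_deg", (0.0, 0.0, 0.0)),
            spec.get("translation", (0.0, 0.0, 0.0)),
        )
    elif kind == "affine":
        transform = AffineTransform(
            spec["matrix"], spec.get("translation", (0, 0, 0)), kind="affine"
        )
    elif kind == "smooth":
        amplitude = float(spec["amplitude"])
        if amplitude > extent.min() / 2.0:
            raise ValueError(
                f"amplitude {amplitude} µm exceeds half the smallest extent "
                f"({extent.min() / 2.0} µm); the warp would not be invertible"
            )
        control_spacing = float(spec.get("control_spacing", extent.min() / 3.0))
        axes = []
        for a in range(3):
            lo = volume.origin[a] - volume.spacing[a]
            hi = volume.origin[a] + extent[a] + volume.spacing[a]
            n = max(2, int(np.ceil((hi - lo) / control_spacing)) + 1)
            axes.append(np.linspace(lo, hi, n))
        disp = rng.normal(size=tuple(len(a) for a in axes) + (3,))
        norms = np.linalg.norm(disp, axis=-1)
        if amplitude > 0 and norms.max() > 0:
            disp *= amplitude / norms.max()
        else:
            disp[:] = 0.0
        transform = DisplacementFieldTransform(axes, disp)
    else:
        raise ValueError(f"unknown deformation kind {kind!r}")

    deformed = resample_volume(volume, transform, volume, "linear")
    deformed.dtype_role = volume.dtype_role
    if landmark_points is None or len(landmark_points) == 0:
        lo = np.asarray(volume.origin) + 0.15 * extent
        hi = np.asarray(volume.origin) + 0.85 * extent
        landmark_points = rng.uniform(lo, hi, size=(n_landmarks, 3))
    fixed = np.atleast_2d(np.asarray(landmark_points, dtype=float))
    moving = transform.apply(fixed)
    landmarks = LandmarkSet(fixed, moving)
    return deformed, landmarks, transform


# ---------------------------------------------------------------------------
# Kymograph phantom

def generate_kymograph(
    velocity: float,
    pixel_size: float,
    line_interval: float,
    n_lines: int,
    width_px: int = 128,
    n_streaks: int = 5,
    streak_width_px: float = 1.5,
    streak_depth: float = 0.8,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Kymograph:
    """Synthetic line-scan kymograph with dark streaks of exact slope.

    A cell moving at ``velocity`` mm/s advances
    ``velocity · line_interval / pixel_size`` pixels per scan line; streaks
    wrap around the scanned line.  Background intensity is 1, streaks dip by
    ``streak_depth``; optional additive Gaussian noise.
    """
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    if n_lines < 2:
        raise ValueError("need at least 2 scan lines")
    rng = np.random.default_rng(seed)
    slope = velocity * line_interval / pixel_size  # px per line
    t = np.arange(n_lines)[:, None]
    x = np.arange(width_px)[None, :]
    image = np.ones((n_lines, width_px), dtype=float)
    offsets = (np.arange(n_streaks) + rng.uniform(0, 1, n_streaks)) * (
        width_px / n_streaks
    )
    for x0 in offsets:
        center = (x0 + slope * t) % width_px
        delta = np.abs(x - center)
        delta = np.minimum(delta, width_px - delta)
        image -= streak_depth * np.exp(-(delta**2) / (2 * streak_width_px**2))
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    return Kymograph(image, pixel_size, line_interval)


# ---------------------------------------------------------------------------
# Longitudinal series

def generate_longitudinal_series(
    base_scene: PhantomScene,
    growth_rate_pct_per_day: float,
    days,
) -> list[PhantomScene]:
    """Longitudinal tumor series sharing one geometry.

    Per-voxel density at day t is clamp(density(0) + rate/100 · t, 0, 1);
    clamping is reported with a warning.  Vessels and deformation are shared
    across timepoints.
    """
    days = list(days)
    if not days:
        raise ValueError("days list must not be empty")
    if base_scene.tumor_field is None:
        raise ValueError("base scene has no tumor field to grow")
    d0 = np.asarray(base_scene.tumor_field.data, dtype=float)
    scenes = []
    clamped = False
    for t in days:
        raw = d0 + growth_rate_pct_per_day / 100.0 * float(t)
        if raw.min() < -1e-12 or raw.max() > 1.0 + 1e-12:
            clamped = True
        field_t = Volume(
            np.clip(raw, 0.0, 1.0),
            base_scene.tumor_field.spacing,
            base_scene.tumor_field.origin,
            dtype_role="density",
        )
        scenes.append(
            PhantomScene(
                segments=base_scene.segments,
                extent=base_scene.extent,
                tumor_field=field_t,
                deformation=base_scene.deformation,
                seed=base_scene.seed,
                bifurcations=base_scene.bifurcations,
            )
        )
    if clamped:
        warnings.warn("tumor densities clamped to [0, 1] at some timepoints")
    return scenes
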