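"""Vessel geometry and flow analysis.

Local vessel diameters from binary angiogram masks (maximal inscribed
sphere), the 30 µm minimum-diameter filter used before network training,
diameter distributions with equivalence-margin stability checks, contrast
uptake QC (percent signal enhancement) and kymograph line-scan velocimetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinaryMask, Volume

__all__ = [
    "Kymograph",
    "EquivalenceReport",
    "estimate_local_diameter",
    "filter_by_diameter",
    "diameter_distribution",
    "equivalence_stability",
    "percent_signal_enhancement",
    "cohort_cv",
    "kymograph_velocity",
    "auto_streak_angle",
    "StreakResult",
]


# ---------------------------------------------------------------------------
# Local thickness

def estimate_local_diameter(mask: BinaryMask) -> Volume:
    """Per-voxel local vessel diameter (µm) of a binary mask.

    The local thickness of a foreground voxel x is the diameter of the
    largest sphere that is fully inscribed in the foreground and contains x.
    Computed exactly from the definition: the Euclidean distance transform
    (in world units, so anisotropic spacing is handled) gives the inscribed
    sphere radius at every candidate center c; each candidate sphere is then
    painted onto the voxels it covers, keeping the per-voxel maximum of 2·r.
    Background voxels are 0.
    """
    data = mask.data
    if not data.any():
        raise ValueError("local diameter of an empty mask is undefined")
    spacing = np.asarray(mask.spacing, dtype=float)
    edt = ndimage.distance_transform_edt(data, sampling=spacing)
    centers = np.argwhere(data)
    radii = edt[data]
    order = np.argsort(radii)[::-1]
    centers = centers[order]
    radii = radii[order]

    thickness = np.zeros(data.shape, dtype=float)
    shape = np.asarray(data.shape)
    for c, r in zip(centers, radii):
        d = 2.0 * r
        if thickness[tuple(c)] >= d:
            # the voxel is already inside an equal-or-larger sphere; its own
            # sphere can still raise neighbors, so only skip when the sphere
            # degenerates to the voxel itself
            if r <= spacing.min() / 2.0 + 1e-12:
                continue
        half = np.ceil(r / spacing).astype(int)
        lo = np.maximum(c - half, 0)
        hi = np.minimum(c + half + 1, shape)
        window = tuple(slice(l, h) for l, h in zip(lo, hi))
        axes = [
            (np.arange(lo[a], hi[a]) - c[a]) * spacing[a] for a in range(3)
        ]
        dz, dy, dx = np.meshgrid(*axes, indexing="ij")
        inside = dz * dz + dy * dy + dx * dx <= r * r + 1e-9
        sub = thickness[window]
        np.maximum(sub, np.where(inside, d, 0.0), out=sub)
    thickness[~data] = 0.0
    return Volume(thickness, mask.spacing, mask.origin)


def filter_by_diameter(
    mask: BinaryMask, min_diameter: float = 30.0, diameter_map: Volume | None = None
) -> BinaryMask:
    """Remove foreground voxels whose local diameter is below ``min_diameter``
    (µm, default 30 — the visibility threshold of vessels on T2w).

    Never adds voxels; idempotent on masks of well-separated structures.
    """
    if min_diameter <= 0 or not mask.data.any():
        return BinaryMask(mask.data.copy(), mask.spacing, mask.origin)
    if diameter_map is None:
        diameter_map = estimate_local_diameter(mask)
    keep = mask.data & (diameter_map.data >= min_diameter)
    return BinaryMask(keep, mask.spacing, mask.origin)


def diameter_distribution(
    mask: BinaryMask, bin_edges, diameter_map: Volume | None = None
) -> pd.DataFrame:
    """Proportion of foreground voxels per diameter bin.

    Bins are half-open [lo, hi) with the last bin closed; proportions sum
    to 1 over voxels falling inside the covered range.
    """
    if not mask.data.any():
        raise ValueError("diameter distribution of an empty mask is undefined")
    if diameter_map is None:
        diameter_map = estimate_local_diameter(mask)
    values = diameter_map.data[mask.data]
    edges = np.asarray(bin_edges, dtype=float)
    counts, _ = np.histogram(values, bins=edges)
    total = counts.sum()
    if total == 0:
        raise ValueError("no foreground voxel falls inside the given bins")
    labels = [f"{lo:g}-{hi:g}" for lo, hi in zip(edges[:-1], edges[1:])]
    return pd.DataFrame(
        {"bin": labels, "count": counts, "proportion": counts / total}
    )


# ---------------------------------------------------------------------------
# Equivalence-margin stability

@dataclass
class EquivalenceReport:
    """Stability of per-category proportions across timepoints against a
    pre-specified equivalence margin (default ±5 %)."""

    categories: list
    proportions: np.ndarray  # (timepoints, categories)
    reference_index: int
    margin: float
    max_deviation: np.ndarray = field(init=False)
    stable: np.ndarray = field(init=False)

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        deviations = np.abs(p - p[self.reference_index])
        self.max_deviation = deviations.max(axis=0)
        self.stable = self.max_deviation <= self.margin

    @property
    def all_stable(self) -> bool:
        return bool(self.stable.all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": self.categories,
                "max_abs_deviation": self.max_deviation,
                "stable": self.stable,
            }
        )


def equivalence_stability(
    proportions, reference_index: int = 0, margin: float = 0.05, categories=None
) -> EquivalenceReport:
    """Flag per-category proportion changes that exceed the equivalence
    margin relative to a reference timepoint.

    ``proportions`` is (timepoints × categories); every row must sum to 1.
    """
    p = np.atleast_2d(np.asarray(proportions, dtype=float))
    if p.shape[0] < 2:
        raise ValueError("need at least 2 timepoints")
    sums = p.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError(f"proportions per timepoint must sum to 1; got {sums}")
    if categories is None:
        categories = [f"cat{i}" for i in range(p.shape[1])]
    return EquivalenceReport(list(categories), p, reference_index, margin)


# ---------------------------------------------------------------------------
# Contrast-uptake QC

def percent_signal_enhancement(si_pre: float, si_post: float) -> float:
    """PSE = (SI_post − SI_pre) / SI_pre × 100 %."""
    si_pre = float(si_pre)
    if si_pre <= 0:
        raise ValueError("pre-contrast signal must be positive")
    return (float(si_post) - si_pre) / si_pre * 100.0


def cohort_cv(values) -> tuple[float, float, float]:
    """Cohort mean, sample SD (n−1) and coefficient of variation (%)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("coefficient of variation needs ≥ 2 values")
    mean = float(v.mean())
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    sd = float(v.std(ddof=1))
    return mean, sd, sd / mean * 100.0


# ---------------------------------------------------------------------------
# Kymograph velocimetry

@dataclass
class Kymograph:
    """Space-time line-scan image: rows = scan lines (time), columns =
    position along the scanned line."""

    data: np.ndarray
    pixel_size: float  # µm per position pixel
    line_interval: float  # ms per line

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph must be a 2D array (lines × position)")
        if self.pixel_size <= 0 or self.line_interval <= 0:
            raise ValueError("pixel_size and line_interval must be positive")

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]


def kymograph_velocity(kymo: Kymograph, lines) -> tuple[float, float, np.ndarray]:
    """Blood flow speed from manually drawn streak segments.

    ``lines`` is a list of 2-point segments ((px0, line0), (px1, line1)) in
    pixel/line coordinates drawn along streaks.  Per segment,
    v = (|Δpx|·pixel_size) / (|Δline|·line_interval); µm/ms ≡ mm/s.
    Returns (mean, sample SD, per-segment speeds); the sign (flow direction)
    is discarded.
    """
    speeds = []
    for (px0, l0), (px1, l1) in lines:
        dlines = abs(float(l1) - float(l0))
        if dlines == 0:
            raise ValueError(
                "segment spans zero scan lines (infinite velocity); segments "
                "must cover ≥ 2 lines in time"
            )
        dpx = abs(float(px1) - float(px0))
        speeds.append(dpx * kymo.pixel_size / (dlines * kymo.line_interval))
    speeds = np.asarray(speeds)
    sd = float(speeds.std(ddof=1)) if speeds.size > 1 else 0.0
    return float(speeds.mean()), sd, speeds


@dataclass
class StreakResult:
    velocity: float  # mm/s; nan when indeterminate
    slope_px_per_line: float
    score: float
    contrast_ratio: float
    indeterminate: bool


def _shear_score(data: np.ndarray, slope: float) -> float:
    """Variance of the column profile after shearing rows by ``slope``
    px/line; maximal when streaks are aligned vertically."""
    n_lines, width = data.shape
    t = np.arange(n_lines)[:, None]
    x = np.arange(width)[None, :]
    pos = (x + slope * t) % width
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    i1 = (i0 + 1) % width
    rows = np.broadcast_to(t, pos.shape)
    sheared = data[rows, i0] * (1 - frac) + data[rows, i1] * frac
    return float(sheared.mean(axis=0).var())


def auto_streak_angle(
    kymo: Kymograph,
    velocity_range=(0.05, 50.0),
    n_coarse: int = 80,
    max_lines: int = 600,
    contrast_threshold: float = 2.0,
) -> StreakResult:
    """Automatic dominant streak orientation → blood flow speed (mm/s).

    Sweeps candidate slopes (projection-maximization: shear the image until
    streaks are vertical, score by the variance of the time-averaged
    profile), then refines around the best candidate.  When the angular
    response is flat — no dominant orientation — the result is flagged
    indeterminate rather than reporting a meaningless number.
    """
    data = kymo.data[: max_lines]
    data = data - data.mean()
    to_slope = kymo.line_interval / kymo.pixel_size  # (mm/s) → px/line
    v_lo, v_hi = velocity_range
    candidates = np.geomspace(v_lo, v_hi, n_coarse) * to_slope
    scores = np.array([_shear_score(data, s) for s in candidates])
    best = int(np.argmax(scores))
    fine = np.linspace(
        candidates[max(best - 1, 0)], candidates[min(best + 1, n_coarse - 1)], 41
    )
    fine_scores = np.array([_shear_score(data, s) for s in fine])
    top = int(np.argmax(fine_scores))
    slope = float(fine[top])
    score = float(fine_scores[top])
    baseline = float(np.median(scores)) + 1e-30
    ratio = score / baseline
    indeterminate = ratio < contrast_threshold
    velocity = float("nan") if indeterminate else slope / to_slope
    return StreakResult(velocity, slope, score, ratio, indeterminate)
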