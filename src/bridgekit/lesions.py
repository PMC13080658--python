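"""Lesion-level quantification: metastatic / erythrocyte cluster statistics
per ROI, lesion-class comparisons, colocalization counting, and
signal-based lesion classification."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import BinaryMask, GeometryError, LabelMask, Volume, same_grid

__all__ = [
    "ClusterStats",
    "quantify_clusters",
    "compare_lesion_groups",
    "copositivity_fraction",
    "classify_lesions_by_signal",
]


@dataclass
class ClusterStats:
    """Connected-component statistics of one ROI."""

    roi_id: int
    lesion_class: str
    n_clusters: int
    cluster_volumes: np.ndarray  # µm³, one per cluster
    total_volume: float = field(init=False)  # µm³

    def __post_init__(self):
        self.cluster_volumes = np.asarray(self.cluster_volumes, dtype=float)
        if self.n_clusters != self.cluster_volumes.size:
            raise ValueError("n_clusters must match the per-cluster list")
        self.total_volume = float(self.cluster_volumes.sum())


def _structure(connectivity: int, ndim3: bool):
    if ndim3:
        if connectivity == 26:
            return np.ones((3, 3, 3), dtype=int)
        if connectivity == 6:
            return ndimage.generate_binary_structure(3, 1)
        if connectivity == 18:
            return ndimage.generate_binary_structure(3, 2)
    else:
        if connectivity == 8:
            return np.ones((1, 3, 3), dtype=int)
        if connectivity == 4:
            s = np.zeros((1, 3, 3), dtype=int)
            s[0] = ndimage.generate_binary_structure(2, 1)
            return s
    raise ValueError(f"unsupported connectivity {connectivity}")


def quantify_clusters(
    image: Volume,
    rois: LabelMask,
    threshold: float,
    min_size_voxels: int = 1,
    connectivity: int | None = None,
    lesion_classes: dict | None = None,
) -> list[ClusterStats]:
    """Count and measure signal clusters within each labeled ROI.

    Per ROI: threshold the image (≥), find connected components inside the
    ROI (default 26-connectivity in 3D, 8 for single-slice data), drop
    components smaller than ``min_size_voxels``, and report the count and
    per-cluster world volumes (µm³).  Components are evaluated within each
    ROI separately, so subdividing an ROI along component boundaries
    conserves the summed statistics.
    """
    if not same_grid(image, rois):
        raise GeometryError("ROI mask geometry does not match the image")
    is3d = image.shape[0] > 1
    if connectivity is None:
        connectivity = 26 if is3d else 8
    structure = _structure(connectivity, is3d)
    foreground = np.asarray(image.data) >= threshold
    voxel_volume = image.voxel_volume
    out = []
    for roi in rois.labels():
        region = foreground & (rois.data == roi)
        labeled, n = ndimage.label(region, structure=structure)
        if n:
            sizes = np.bincount(labeled.ravel())[1:]
            sizes = sizes[sizes >= min_size_voxels]
        else:
            sizes = np.array([], dtype=int)
        out.append(
            ClusterStats(
                int(roi),
                (lesion_classes or {}).get(int(roi), ""),
                int(sizes.size),
                sizes * voxel_volume,
            )
        )
    return out


def compare_lesion_groups(
    cluster_stats, metric: str = "count", classes: tuple[str, str] | None = None
) -> dict:
    """Two-sample comparison (Mann-Whitney U, two-sided) of per-ROI cluster
    counts or total volumes between two lesion classes.

    Ties are handled by scipy's rank-based normal approximation (exact when
    sample sizes permit and no ties); identical groups give p = 1.
    """
    if metric not in ("count", "total_volume"):
        raise ValueError(f"unknown metric {metric!r}")
    values: dict[str, list[float]] = {}
    for cs in cluster_stats:
        v = cs.n_clusters if metric == "count" else cs.total_volume
        values.setdefault(cs.lesion_class, []).append(float(v))
    if classes is None:
        classes = tuple(sorted(values))
    if len(classes) != 2:
        raise ValueError(f"need exactly two lesion classes, got {classes}")
    a = np.asarray(values.get(classes[0], []), dtype=float)
    b = np.asarray(values.get(classes[1], []), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both lesion groups must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")

    def _summary(v):
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return {"n": int(v.size), "median": float(med), "iqr": (float(q1), float(q3))}

    return {
        "metric": metric,
        "groups": {classes[0]: _summary(a), classes[1]: _summary(b)},
        "U": float(res.statistic),
        "pvalue": float(res.pvalue),
    }


def copositivity_fraction(
    nuclei: LabelMask | None, marker_a_positive, marker_b_positive
) -> float:
    """Fraction of marker-A-positive nuclei that are also marker-B-positive:
    |A⁺ ∩ B⁺| / |A⁺|.

    With a nuclei label mask supplied, both id sets must be subsets of its
    labels.  The same call answers sensitivity/specificity framings by
    choosing which marker is the reference.
    """
    a = set(int(i) for i in marker_a_positive)
    b = set(int(i) for i in marker_b_positive)
    if not a:
        raise ValueError("reference marker set A⁺ is empty")
    if nuclei is not None:
        known = set(int(l) for l in nuclei.labels())
        stray = (a | b) - known
        if stray:
            raise ValueError(f"ids not present in the nuclei mask: {sorted(stray)}")
    return len(a & b) / len(a)


def classify_lesions_by_signal(
    rois: LabelMask,
    signal: Volume,
    shell_width: float = 100.0,
    threshold: float = -1.0,
    rule: str = "hypointense",
) -> pd.DataFrame:
    """Classify each ROI as signal-positive or -negative from a
    perimetastatic shell statistic.

    The shell contains voxels within ``shell_width`` µm (world metric) of
    the ROI but outside every ROI.  The mean signal in the shell is compared
    to ``threshold``: with rule 'hypointense' a mean ≤ threshold is
    'positive' (e.g. a T2*-dark rim), with 'hyperintense' a mean ≥ threshold
    is.  Thresholds are recorded in the output; the classification is
    invariant to ROI relabeling.
    """
    if not same_grid(rois, signal):
        raise GeometryError("ROI mask geometry does not match the signal volume")
    if rule not in ("hypointense", "hyperintense"):
        raise ValueError(f"unknown rule {rule!r}")
    any_roi = rois.data > 0
    rows = []
    for roi in rois.labels():
        region = rois.data == roi
        dist = ndimage.distance_transform_edt(~region, sampling=rois.spacing)
        shell = (dist <= shell_width + 1e-9) & ~any_roi
        if not shell.any():
            raise ValueError(f"empty perimetastatic shell for ROI {int(roi)}")
        mean_signal = float(np.asarray(signal.data, float)[shell].mean())
        if rule == "hypointense":
            positive = mean_signal <= threshold
        else:
            positive = mean_signal >= threshold
        rows.append(
            {
                "roi_id": int(roi),
                "shell_mean": mean_signal,
                "threshold": threshold,
                "rule": rule,
                "classification": "positive" if positive else "negative",
            }
        )
    return pd.DataFrame(rows)
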